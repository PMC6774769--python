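"""Growing neural gas (GNG) topology learning in 2D and 3D.

GNG incrementally builds a graph of "neurons" (prototype vectors in the
input space) connected by unweighted, aged edges.  For every input
signal the nearest neuron accumulates its squared quantisation error and
moves towards the signal (its topological neighbours move less); the
winner and runner-up are linked by a Hebbian edge whose age resets to
zero while the winner's other edges age, and over-aged edges — and the
neurons they strand — are pruned.  Every ``lambda_insert`` signals a new
neuron is inserted halfway between the highest-error neuron and its
highest-error neighbour, so capacity concentrates where quantisation
error is largest.  Learning parameters are constant in time.

The same machinery serves two inputs: the foreground pixels of a binary
skin mask (d = 2, learning the planar topology of faces/hands) and
coloured 3D point clouds (d = 3, producing an open coloured mesh whose
faces are the 3-cliques of the learned edge graph).

Utilities for structured-light depth data are included: the sensor's
raw disparity is normalised as d = (d_off − kd)/8 and depth images are
back-projected to point clouds through a pinhole model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cc

logger = logging.getLogger(__name__)

__all__ = [
    "GNGConfig",
    "TopologyGraph",
    "ColouredMesh",
    "init_graph",
    "adapt_step",
    "insert_node",
    "learn",
    "learn_from_mask",
    "learn_pointcloud",
    "normalise_disparity",
    "depth_to_pointcloud",
    "GrowingNeuralGas",
    "GNGResults",
]


@dataclass
class GNGConfig:
    """Learning parameters of the growing neural gas (constant in time).

    max_nodes      network capacity (insertion stops here)
    lambda_insert  signals between node insertions
    eps_b          winner adaptation step
    eps_n          topological-neighbour adaptation step
    alpha          error decay applied to the two parents at insertion
    beta           global per-signal error decay (errors ×= 1 − beta)
    age_max        edges older than this are removed
    seed           PRNG seed for initial positions and signal sampling
    """

    max_nodes: int = 200
    lambda_insert: int = 100
    eps_b: float = 0.1
    eps_n: float = 0.005
    alpha: float = 0.5
    beta: float = 0.0005
    age_max: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.eps_n <= self.eps_b < 1):
            raise ValueError("require 0 < eps_n <= eps_b < 1")
        if not (0 < self.alpha < 1 and 0 < self.beta < 1):
            raise ValueError("alpha and beta must lie in (0, 1)")
        if min(self.max_nodes, self.lambda_insert, self.age_max) <= 0:
            raise ValueError("max_nodes, lambda_insert and age_max must be positive")


class TopologyGraph:
    """The topology-preserving graph ⟨N, C⟩.

    Storage is slot-based: ``pos``/``error``/``colour`` are preallocated
    for ``max_nodes`` slots with an ``alive`` mask, and edges live in a
    symmetric age matrix (−1 = no edge, ≥ 0 = edge age) so that the inner
    learning loop is pure array arithmetic.
    """

    def __init__(self, max_nodes: int, dim: int, track_colour: bool = False):
        self.max_nodes = int(max_nodes)
        self.dim = int(dim)
        self.pos = np.zeros((max_nodes, dim))
        self.error = np.zeros(max_nodes)
        self.alive = np.zeros(max_nodes, dtype=bool)
        self.age = np.full((max_nodes, max_nodes), -1, dtype=np.int32)
        self.colour = np.zeros((max_nodes, 3)) if track_colour else None
        self.active = np.empty(0, dtype=np.intp)  # sorted alive slot indices

    # -- basic queries ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.active)

    @property
    def positions(self) -> np.ndarray:
        return self.pos[self.active]

    @property
    def errors(self) -> np.ndarray:
        return self.error[self.active]

    @property
    def colours(self) -> np.ndarray | None:
        return None if self.colour is None else self.colour[self.active]

    def edges(self) -> list[tuple[int, int, int]]:
        """(i, j, age) triples with i < j, in slot indices."""
        ii, jj = np.nonzero(np.triu(self.age, 1) + 1)
        return [(int(i), int(j), int(self.age[i, j])) for i, j in zip(ii, jj)]

    def neighbours(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.age[i] >= 0)

    def n_edges(self) -> int:
        return int((self.age >= 0).sum() // 2)

    def connected_components(self) -> int:
        if self.n_nodes == 0:
            return 0
        sub = self.age[np.ix_(self.active, self.active)] >= 0
        return int(_cc(csr_matrix(sub), directed=False)[0])

    def quantisation_error(self, samples: np.ndarray) -> float:
        """Mean squared distance from samples to their nearest neuron."""
        samples = np.asarray(samples, dtype=float)
        pos = self.positions
        d2 = ((samples[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
        return float(d2.min(axis=1).mean())

    def validate(self, age_max: int | None = None) -> None:
        """Raise AssertionError on any structural invariant violation."""
        a = self.age
        assert np.array_equal(a, a.T), "edge age matrix must be symmetric"
        assert np.all(np.diag(a) == -1), "self-loops are forbidden"
        edge_rows = np.any(a >= 0, axis=1)
        assert not np.any(edge_rows & ~self.alive), "edges on dead slots"
        assert np.all(self.error >= 0), "accumulated errors must be non-negative"
        assert np.all(np.isfinite(self.pos[self.alive])), "positions must be finite"
        if age_max is not None:
            assert a.max(initial=-1) <= age_max, "edge age exceeds age_max"
        assert np.array_equal(self.active, np.flatnonzero(self.alive))
        assert self.n_nodes >= 2, "graph must keep at least two neurons"

    # -- mutation helpers ------------------------------------------------
    def _add_node(self, slot: int, w: np.ndarray, error: float, colour=None) -> None:
        self.pos[slot] = w
        self.error[slot] = error
        self.alive[slot] = True
        if self.colour is not None and colour is not None:
            self.colour[slot] = colour
        k = np.searchsorted(self.active, slot)
        self.active = np.insert(self.active, k, slot)

    def _remove_node(self, slot: int) -> None:
        self.alive[slot] = False
        self.error[slot] = 0.0
        self.age[slot, :] = -1
        self.age[:, slot] = -1
        self.active = self.active[self.active != slot]

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        nodes = []
        for slot in self.active:
            node = {
                "id": int(slot),
                "position": self.pos[slot].tolist(),
                "error": float(self.error[slot]),
            }
            if self.colour is not None:
                node["colour"] = self.colour[slot].tolist()
            nodes.append(node)
        return {
            "dim": self.dim,
            "max_nodes": self.max_nodes,
            "nodes": nodes,
            "edges": [[i, j, a] for i, j, a in self.edges()],
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, doc: dict) -> "TopologyGraph":
        has_colour = any("colour" in n for n in doc["nodes"])
        g = cls(doc["max_nodes"], doc["dim"], track_colour=has_colour)
        for node in doc["nodes"]:
            g._add_node(node["id"], np.asarray(node["position"]), node["error"],
                        node.get("colour"))
        for i, j, a in doc["edges"]:
            g.age[i, j] = g.age[j, i] = a
        return g


def init_graph(
    samples: np.ndarray,
    cfg: GNGConfig,
    rng: np.random.Generator | None = None,
    colours: np.ndarray | None = None,
) -> TopologyGraph:
    """Two neurons at seeded-random sample positions; empty edge set."""
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or len(samples) < 2:
        raise ValueError("need at least two input samples to initialise")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    idx = rng.choice(len(samples), size=2, replace=False)
    g = TopologyGraph(cfg.max_nodes, samples.shape[1], track_colour=colours is not None)
    for slot, i in enumerate(idx):
        g._add_node(slot, samples[i], 0.0,
                    colours[i] if colours is not None else None)
    return g


def adapt_step(
    g: TopologyGraph,
    signal: np.ndarray,
    cfg: GNGConfig,
    colour: np.ndarray | None = None,
) -> TopologyGraph:
    """One Hebbian adaptation step for a single input signal.

    Winner and runner-up are the two nearest neurons (ties broken by
    lowest slot index).  The winner accumulates the squared distance,
    moves by eps_b, its neighbours by eps_n; the winner–runner-up edge is
    created/reset, the winner's other edges age, over-aged edges and the
    neurons they strand are removed.
    """
    act = g.active
    diff = g.pos[act] - signal
    d2 = np.einsum("ij,ij->i", diff, diff)
    order = np.argsort(d2, kind="stable")
    w = int(act[order[0]])
    r = int(act[order[1]])

    g.error[w] += d2[order[0]]
    g.pos[w] += cfg.eps_b * (signal - g.pos[w])
    nb = np.flatnonzero(g.age[w] >= 0)
    if nb.size:
        g.pos[nb] += cfg.eps_n * (signal - g.pos[nb])
        g.age[w, nb] += 1
        g.age[nb, w] += 1
    if g.colour is not None and colour is not None:
        g.colour[w] += cfg.eps_b * (colour - g.colour[w])
    g.age[w, r] = g.age[r, w] = 0

    over = nb[g.age[w, nb] > cfg.age_max]
    if over.size:
        g.age[w, over] = -1
        g.age[over, w] = -1
        for i in over:
            if not np.any(g.age[i] >= 0):
                g._remove_node(int(i))
    return g


def insert_node(g: TopologyGraph, cfg: GNGConfig) -> TopologyGraph:
    """Insert a neuron between the highest-error neuron q and its
    highest-error neighbour f; the q–f edge is replaced by q–r and f–r,
    parents' errors decay by alpha and r inherits q's decayed error."""
    if g.n_nodes >= g.max_nodes:
        raise ValueError("graph already at capacity")
    act = g.active
    err = g.error[act]
    q = int(act[int(np.argmax(err))])
    nb = np.flatnonzero(g.age[q] >= 0)
    if nb.size:
        f = int(nb[int(np.argmax(g.error[nb]))])
    else:
        # Degenerate: q is isolated; pair it with the globally
        # second-highest-error neuron so learning never aborts.
        rest = act[act != q]
        f = int(rest[int(np.argmax(g.error[rest]))])
    slot = int(np.flatnonzero(~g.alive)[0])
    g.age[q, f] = g.age[f, q] = -1
    g.error[q] *= cfg.alpha
    g.error[f] *= cfg.alpha
    colour = None
    if g.colour is not None:
        colour = 0.5 * (g.colour[q] + g.colour[f])
    g._add_node(slot, 0.5 * (g.pos[q] + g.pos[f]), g.error[q], colour)
    g.age[q, slot] = g.age[slot, q] = 0
    g.age[f, slot] = g.age[slot, f] = 0
    return g


def learn(
    samples: np.ndarray,
    cfg: GNGConfig,
    colours: np.ndarray | None = None,
    n_signals: int | None = None,
    callback=None,
) -> TopologyGraph:
    """Run GNG over seeded uniform with-replacement draws from ``samples``.

    Every ``lambda_insert``-th signal triggers a node insertion while
    capacity remains; after each signal all accumulated errors decay by
    (1 − beta).  Without an explicit ``n_signals`` budget, learning runs
    until the network reaches ``max_nodes`` (with a generous safety cap).
    ``callback(graph, signal_index)`` is invoked after every signal.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or len(samples) == 0:
        raise ValueError("input distribution must be a non-empty (n, d) array")
    rng = np.random.default_rng(cfg.seed)
    g = init_graph(samples, cfg, rng=rng, colours=colours)
    if n_signals is None:
        budget = cfg.lambda_insert * (cfg.max_nodes + 2) * 5
        stop_at_capacity = True
    else:
        budget = int(n_signals)
        stop_at_capacity = False

    decay = 1.0 - cfg.beta
    count = 0
    chunk = 4096
    while count < budget:
        draws = rng.integers(0, len(samples), size=min(chunk, budget - count))
        for i in draws:
            sig = samples[i]
            col = colours[i] if colours is not None else None
            adapt_step(g, sig, cfg, colour=col)
            count += 1
            if count % cfg.lambda_insert == 0 and g.n_nodes < g.max_nodes:
                insert_node(g, cfg)
            g.error[g.active] *= decay
            if callback is not None:
                callback(g, count)
            if stop_at_capacity and g.n_nodes >= g.max_nodes:
                return g
    if stop_at_capacity and g.n_nodes < g.max_nodes:
        logger.warning("signal budget exhausted before reaching max_nodes")
    return g


def learn_from_mask(mask: np.ndarray, cfg: GNGConfig, **kwargs) -> TopologyGraph:
    """Learn the 2D topology of a binary mask's foreground.

    The input distribution is uniform over foreground pixel coordinates
    normalised to [0, 1]² as (x, y) = (col/(W−1), row/(H−1)).
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if len(rows) < 2:
        raise ValueError("mask must contain at least two foreground pixels")
    h, w = mask.shape
    pts = np.stack(
        [cols / max(w - 1, 1), rows / max(h - 1, 1)], axis=1
    ).astype(float)
    return learn(pts, cfg, **kwargs)


@dataclass
class ColouredMesh:
    """Open coloured mesh: neuron positions/colours, edges, 3-clique faces."""

    vertices: np.ndarray
    vertex_colours: np.ndarray
    edges: np.ndarray
    faces: np.ndarray

    def to_trimesh(self):
        import trimesh

        mesh = trimesh.Trimesh(
            vertices=self.vertices,
            faces=self.faces.reshape(-1, 3) if len(self.faces) else np.zeros((0, 3), int),
            process=False,
        )
        rgba = np.hstack(
            [
                np.clip(self.vertex_colours * 255, 0, 255).astype(np.uint8),
                np.full((len(self.vertices), 1), 255, dtype=np.uint8),
            ]
        )
        mesh.visual.vertex_colors = rgba
        return mesh

    def save(self, path) -> None:
        path = str(path)
        mesh = self.to_trimesh()
        if path.endswith(".ply"):
            with open(path, "wb") as fh:
                fh.write(mesh.export(file_type="ply", encoding="ascii"))
        else:
            mesh.export(path)


def graph_to_mesh(g: TopologyGraph) -> ColouredMesh:
    """Extract vertices, edges and all triangles formed by mutually
    connected neuron triples (no hole filling; the mesh may be open)."""
    act = g.active
    remap = {int(s): k for k, s in enumerate(act)}
    adj = g.age[np.ix_(act, act)] >= 0
    n = len(act)
    edges, faces = [], []
    for i in range(n):
        for j in np.flatnonzero(adj[i][i + 1:]) + i + 1:
            edges.append((i, int(j)))
            common = np.flatnonzero(adj[i] & adj[j])
            for k in common[common > j]:
                faces.append((i, int(j), int(k)))
    colours = g.colours
    if colours is None:
        colours = np.full((n, 3), 0.7)
    return ColouredMesh(
        vertices=g.positions.copy(),
        vertex_colours=colours.copy(),
        edges=np.asarray(edges, dtype=int).reshape(-1, 2),
        faces=np.asarray(faces, dtype=int).reshape(-1, 3),
    )


def learn_pointcloud(
    points: np.ndarray,
    cfg: GNGConfig,
    colours: np.ndarray | None = None,
    n_signals: int | None = None,
) -> ColouredMesh:
    """Learn a 3D coloured mesh from a point cloud.

    Each neuron's colour is an exponential running average (rate eps_b)
    of the colours of the signals it won.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("point cloud must have shape (n, 3)")
    if colours is None:
        colours = np.full((len(points), 3), 0.7)
    g = learn(points, cfg, colours=np.asarray(colours, dtype=float), n_signals=n_signals)
    return graph_to_mesh(g)


# ---------------------------------------------------------------------------
# depth-sensor utilities


def normalise_disparity(kd, d_off: float = 1090.0):
    """Normalised disparity d = (d_off − kd)/8 for a structured-light sensor.

    ``d_off`` is a device-specific calibration offset (default 1090,
    configurable)."""
    return (d_off - np.asarray(kd, dtype=float)) / 8.0


@dataclass(frozen=True)
class PinholeIntrinsics:
    fx: float
    fy: float
    cx: float
    cy: float

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")


def depth_to_pointcloud(
    depth: np.ndarray,
    intrinsics: PinholeIntrinsics,
    rgb: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Pinhole back-projection of a depth image to a 3D point cloud.

    Pixels with zero depth (and outside ``mask``, if given) are dropped;
    colours are attached per point when ``rgb`` is supplied.
    """
    depth = np.asarray(depth, dtype=float)
    valid = depth > 0
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    if not np.any(valid):
        logger.warning("depth image contains no valid pixels; returning empty cloud")
        return np.zeros((0, 3)), (np.zeros((0, 3)) if rgb is not None else None)
    vv, uu = np.nonzero(valid)
    z = depth[vv, uu]
    x = (uu - intrinsics.cx) * z / intrinsics.fx
    y = (vv - intrinsics.cy) * z / intrinsics.fy
    pts = np.stack([x, y, z], axis=1)
    cols = np.asarray(rgb, dtype=float)[vv, uu] if rgb is not None else None
    return pts, cols


# ---------------------------------------------------------------------------
# model / results objects


class GrowingNeuralGas:
    """Growing-neural-gas model over a fixed input distribution.

    Parameters
    ----------
    samples : (n, d) array
        The input distribution (pixel coordinates or 3D points); signals
        are uniform with-replacement draws from it.
    config : GNGConfig, optional
        Learning parameters (Fritzke-style defaults).
    colours : (n, 3) array, optional
        Per-sample RGB, tracked per neuron by running average.
    """

    def __init__(self, samples, config: GNGConfig | None = None, colours=None):
        self.samples = np.asarray(samples, dtype=float)
        self.config = config if config is not None else GNGConfig()
        self.colours = None if colours is None else np.asarray(colours, dtype=float)

    @classmethod
    def from_mask(cls, mask: np.ndarray, config: GNGConfig | None = None):
        mask = np.asarray(mask, dtype=bool)
        rows, cols = np.nonzero(mask)
        if len(rows) < 2:
            raise ValueError("mask must contain at least two foreground pixels")
        h, w = mask.shape
        pts = np.stack([cols / max(w - 1, 1), rows / max(h - 1, 1)], axis=1)
        return cls(pts, config)

    def fit(self, n_signals: int | None = None, callback=None) -> "GNGResults":
        graph = learn(
            self.samples,
            self.config,
            colours=self.colours,
            n_signals=n_signals,
            callback=callback,
        )
        return GNGResults(self, graph)


class GNGResults:
    """Fitted GNG: the learned topology graph plus diagnostics."""

    def __init__(self, model: GrowingNeuralGas, graph: TopologyGraph):
        self.model = model
        self.graph = graph

    @property
    def n_nodes(self) -> int:
        return self.graph.n_nodes

    @property
    def n_edges(self) -> int:
        return self.graph.n_edges()

    @property
    def n_components(self) -> int:
        return self.graph.connected_components()

    def quantisation_error(self, samples: np.ndarray | None = None) -> float:
        return self.graph.quantisation_error(
            self.model.samples if samples is None else samples
        )

    def mesh(self) -> ColouredMesh:
        return graph_to_mesh(self.graph)

    def summary(self) -> str:
        cfg = self.model.config
        return "\n".join(
            [
                "Growing neural gas topology",
                "=" * 40,
                f"input samples:       {len(self.model.samples)} (d = {self.model.samples.shape[1]})",
                f"neurons:             {self.n_nodes} (capacity {cfg.max_nodes})",
                f"edges:               {self.n_edges}",
                f"connected components: {self.n_components}",
                f"mean quantisation error: {self.quantisation_error():.6g}",
                f"parameters: lambda={cfg.lambda_insert} eps_b={cfg.eps_b} "
                f"eps_n={cfg.eps_n} alpha={cfg.alpha} beta={cfg.beta} "
                f"age_max={cfg.age_max} seed={cfg.seed}",
            ]
        )
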