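"""Synthetic fixtures with exact ground truth.

Every stage of the pipeline can be exercised without external data:

* :func:`sample_mixture` draws labelled chrominance observations from a
  known Gaussian mixture (ground truth for EM recovery checks);
* :func:`render_scene` rasterises face/hand-shaped foreground blobs over
  cluttered backgrounds, colouring each region by draws from known skin
  and background chrominance mixtures lifted back to RGB at a fixed
  luminance, and returns the exact foreground mask;
* :func:`sample_shape3d` samples coloured points on analytic 3D surfaces
  (sphere, ellipsoid "face", cylinder-union "hand") with controllable
  surface noise and outlier contamination, returning the surface itself
  for distance oracles.

All generators are seed-deterministic and every ground truth is exact by
construction (analytic shapes and formulas, no hand labelling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import color as _skcolor
from skimage import draw as _skdraw

from .colorspace import RGB_TO_XYZ_MATRIX, D65, WhitePoint, lab_to_rgb
from .skinmodel import GMMParams

__all__ = [
    "sample_mixture",
    "chrominance_to_rgb",
    "EllipseShape",
    "HandShape",
    "SceneSpec",
    "default_skin_mixture",
    "default_background_mixture",
    "default_scene",
    "render_scene",
    "ShapeSpec3D",
    "PointCloudSample",
    "sample_shape3d",
]


def sample_mixture(
    g: GMMParams, n: int, seed: int | None = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` observations from a Gaussian mixture.

    Returns (X, labels) where labels are the generating component
    indices, retained for oracle checks.
    """
    rng = np.random.default_rng(seed)
    labels = rng.choice(g.n_components, size=n, p=g.priors)
    X = np.empty((n, g.d))
    for j in range(g.n_components):
        idx = np.flatnonzero(labels == j)
        if idx.size:
            chol = np.linalg.cholesky(g.covariances[j])
            X[idx] = g.means[j] + rng.standard_normal((idx.size, g.d)) @ chol.T
    return X, labels


def chrominance_to_rgb(
    samples: np.ndarray,
    space_tag: str,
    luminance: float = 62.0,
    wp: WhitePoint = D65,
) -> np.ndarray:
    """Lift two-channel chrominance samples to RGB at a fixed luminance.

    Inverts the relevant chrominance transform with the intensity degree
    of freedom pinned: L* for lab, value V for hsv, the channel sum for
    nrgb (luminance/100 scaled to a sum of 1.5), and Y for xyz.  Output
    is clipped to the unit cube.
    """
    s = np.asarray(samples, dtype=float)
    tag = space_tag.lower()
    if tag == "lab":
        return lab_to_rgb(np.full(s.shape[:-1], luminance), s[..., 0], s[..., 1], wp)
    if tag == "nrgb":
        total = 3.0 * luminance / 100.0
        r, gch = s[..., 0], s[..., 1]
        rgb = np.stack([r, gch, 1.0 - r - gch], axis=-1) * total
        return np.clip(rgb, 0.0, 1.0)
    if tag == "hsv":
        v = np.full(s.shape[:-1], luminance / 100.0)
        hsv = np.stack([s[..., 0], s[..., 1], v], axis=-1)
        return _skcolor.hsv2rgb(np.atleast_3d(hsv).reshape(-1, 1, 3)).reshape(s.shape[:-1] + (3,))
    if tag == "xyz":
        x, y = s[..., 0], s[..., 1]
        Y = np.full(s.shape[:-1], luminance / 100.0)
        safe_y = np.where(y > 1e-9, y, 1e-9)
        X = x / safe_y * Y
        Z = (1.0 - x - y) / safe_y * Y
        xyz = np.stack([X, Y, Z], axis=-1)
        return np.clip(xyz @ np.linalg.inv(RGB_TO_XYZ_MATRIX).T, 0.0, 1.0)
    raise ValueError(f"unknown colour space tag {space_tag!r}")


# ---------------------------------------------------------------------------
# 2D scenes


@dataclass
class EllipseShape:
    """An ellipse blob (the "face"); centre/radii in pixel units."""

    center: tuple[float, float]
    radii: tuple[float, float]
    rotation: float = 0.0

    @property
    def area(self) -> float:
        return float(np.pi * self.radii[0] * self.radii[1])

    @property
    def perimeter(self) -> float:
        a, b = self.radii
        h = ((a - b) / (a + b)) ** 2
        return float(np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h))))

    def rasterise(self, shape: tuple[int, int]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        rr, cc = _skdraw.ellipse(
            self.center[0], self.center[1], self.radii[0], self.radii[1],
            shape=shape, rotation=self.rotation,
        )
        mask[rr, cc] = True
        return mask


@dataclass
class HandShape:
    """A stylised hand: palm disc plus five finger quadrilaterals.

    Not biologically realistic — it provides the elongated, branched
    foreground topology that planar GNG graphs should trace.
    """

    center: tuple[float, float]
    palm_radius: float
    finger_length: float | None = None
    finger_width: float | None = None
    rotation: float = 0.0

    def __post_init__(self) -> None:
        if self.finger_length is None:
            self.finger_length = 1.6 * self.palm_radius
        if self.finger_width is None:
            self.finger_width = 0.38 * self.palm_radius

    def rasterise(self, shape: tuple[int, int]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        rr, cc = _skdraw.disk(self.center, self.palm_radius, shape=shape)
        mask[rr, cc] = True
        cy, cx = self.center
        # five fingers fanned over 100 degrees, pointing "up" before rotation
        for k, ang in enumerate(np.deg2rad(np.linspace(-50, 50, 5)) + self.rotation):
            length = self.finger_length * (0.75 if k in (0, 4) else 1.0)
            dy, dx = -np.cos(ang), np.sin(ang)
            py, px = dx, dy  # unit vector across the finger
            base_y = cy + dy * self.palm_radius * 0.8
            base_x = cx + dx * self.palm_radius * 0.8
            tip_y, tip_x = base_y + dy * length, base_x + dx * length
            hw = self.finger_width / 2
            poly_r = [base_y - py * hw, base_y + py * hw, tip_y + py * hw, tip_y - py * hw]
            poly_c = [base_x - px * hw, base_x + px * hw, tip_x + px * hw, tip_x - px * hw]
            rr, cc = _skdraw.polygon(poly_r, poly_c, shape=shape)
            mask[rr, cc] = True
        return mask


def default_skin_mixture() -> GMMParams:
    """A two-lobe skin chrominance mixture in the (a*, b*) plane."""
    return GMMParams(
        priors=[0.5, 0.5],
        means=[[15.0, 19.0], [22.0, 27.0]],
        covariances=[np.eye(2) * 9.0, np.eye(2) * 9.0],
    )


def default_background_mixture() -> GMMParams:
    """Background chrominance: foliage green, sky blue and neutral grey."""
    return GMMParams(
        priors=[0.4, 0.3, 0.3],
        means=[[-26.0, 22.0], [2.0, -30.0], [-6.0, 2.0]],
        covariances=[np.eye(2) * 16.0, np.eye(2) * 16.0, np.eye(2) * 12.0],
    )


@dataclass
class SceneSpec:
    """Parameters of one synthetic labelled scene."""

    size: tuple[int, int] = (160, 200)
    shapes: list = field(default_factory=list)
    clutter: int = 0
    noise_sigma: float = 0.01
    skin_mixture: GMMParams = field(default_factory=default_skin_mixture)
    background_mixture: GMMParams = field(default_factory=default_background_mixture)
    space_tag: str = "lab"
    luminance: float = 62.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.size
        if h <= 0 or w <= 0:
            raise ValueError("scene dimensions must be positive")
        for shape in self.shapes:
            cy, cx = shape.center
            if not (0 <= cy < h and 0 <= cx < w):
                raise ValueError("shape centre lies outside the image")


def default_scene(
    clutter: int = 2,
    seed: int = 0,
    size: tuple[int, int] = (160, 200),
    noise_sigma: float = 0.01,
) -> SceneSpec:
    """Canonical test scene: one elliptical face and one hand blob."""
    h, w = size
    return SceneSpec(
        size=size,
        shapes=[
            EllipseShape(center=(0.38 * h, 0.30 * w), radii=(0.22 * h, 0.16 * w)),
            HandShape(center=(0.62 * h, 0.74 * w), palm_radius=0.11 * min(h, w)),
        ],
        clutter=clutter,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Rasterise a scene; returns (RGB image in [0,1], exact boolean mask).

    Background pixels draw chrominance from the background mixture;
    clutter blobs are ellipses coloured from a single background
    component with reduced spread (solid distractors); foreground pixels
    draw from the skin mixture.  All chrominance is lifted to RGB at the
    fixed luminance, then i.i.d. Gaussian RGB noise is added.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    mask = np.zeros((h, w), dtype=bool)
    for shape in spec.shapes:
        mask |= shape.rasterise((h, w))

    bg = spec.background_mixture
    chrom, _ = sample_mixture(bg, h * w, seed=rng.integers(2**31))
    chrom = chrom.reshape(h, w, 2)

    for _ in range(spec.clutter):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        ry, rx = rng.uniform(0.05, 0.18, size=2) * min(h, w)
        blob = EllipseShape((cy, cx), (ry, rx), rotation=rng.uniform(0, np.pi))
        bmask = blob.rasterise((h, w)) & ~mask
        j = rng.integers(bg.n_components)
        tight = GMMParams([1.0], [bg.means[j]], [bg.covariances[j] / 16.0])
        cl, _ = sample_mixture(tight, int(bmask.sum()), seed=rng.integers(2**31))
        chrom[bmask] = cl

    fg, _ = sample_mixture(spec.skin_mixture, int(mask.sum()), seed=rng.integers(2**31))
    chrom[mask] = fg

    rgb = chrominance_to_rgb(chrom, spec.space_tag, spec.luminance)
    if spec.noise_sigma > 0:
        rgb = rgb + rng.normal(0.0, spec.noise_sigma, size=rgb.shape)
    return np.clip(rgb, 0.0, 1.0), mask


# ---------------------------------------------------------------------------
# 3D shapes


class SphereSurface:
    def __init__(self, radius: float = 1.0, center=(0.0, 0.0, 0.0)):
        self.radius = radius
        self.center = np.asarray(center, dtype=float)

    def distance(self, points: np.ndarray) -> np.ndarray:
        r = np.linalg.norm(np.asarray(points, dtype=float) - self.center, axis=-1)
        return np.abs(r - self.radius)

    def bounding_box(self) -> np.ndarray:
        r = self.radius
        return np.array([self.center - r, self.center + r])


class EllipsoidSurface:
    """Axis-aligned ellipsoid; distance is the first-order implicit
    estimate |f|/|∇f| with f = Σ (x_i/a_i)² − 1 (adequate for adherence
    oracles at moderate eccentricity)."""

    def __init__(self, axes=(1.0, 0.8, 1.3)):
        self.axes = np.asarray(axes, dtype=float)

    def distance(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        f = ((p / self.axes) ** 2).sum(axis=-1) - 1.0
        grad = 2.0 * p / self.axes**2
        gnorm = np.maximum(np.linalg.norm(grad, axis=-1), 1e-12)
        return np.abs(f) / gnorm

    def bounding_box(self) -> np.ndarray:
        return np.array([-self.axes, self.axes])


@dataclass
class _Cylinder:
    center: np.ndarray
    radius: float
    half_length: float  # along z

    def lateral_area(self) -> float:
        return 2 * np.pi * self.radius * 2 * self.half_length

    def contains(self, p: np.ndarray, margin: float = 1e-9) -> np.ndarray:
        d = p - self.center
        radial = np.hypot(d[..., 0], d[..., 1])
        return (radial < self.radius - margin) & (np.abs(d[..., 2]) < self.half_length - margin)

    def surface_distance(self, p: np.ndarray) -> np.ndarray:
        d = p - self.center
        radial = np.hypot(d[..., 0], d[..., 1]) - self.radius
        axial = np.abs(d[..., 2]) - self.half_length
        outside = np.hypot(np.maximum(radial, 0), np.maximum(axial, 0))
        inside = -np.minimum(np.maximum(radial, axial), 0)
        return outside + inside


class CylinderUnionSurface:
    """Union of z-aligned cylinders (a palm and finger stubs)."""

    def __init__(self, cylinders: list[_Cylinder] | None = None):
        if cylinders is None:
            cylinders = [_Cylinder(np.array([0.0, 0.0, 0.0]), 0.5, 0.5)]
            for x in (-0.3, 0.0, 0.3):
                cylinders.append(_Cylinder(np.array([x, 0.0, 0.9]), 0.12, 0.4))
        self.cylinders = cylinders

    def distance(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return np.min([c.surface_distance(p) for c in self.cylinders], axis=0)

    def bounding_box(self) -> np.ndarray:
        los = [c.center - [c.radius, c.radius, c.half_length] for c in self.cylinders]
        his = [c.center + [c.radius, c.radius, c.half_length] for c in self.cylinders]
        return np.array([np.min(los, axis=0), np.max(his, axis=0)])


@dataclass
class ShapeSpec3D:
    """Parameters of one synthetic coloured point cloud."""

    shape: str = "sphere"  # sphere | ellipsoid | cylinder_union
    n: int = 2000
    noise_sigma: float = 0.0
    outlier_fraction: float = 0.0
    colour_rule: str = "height"  # height | constant
    colour: tuple[float, float, float] = (0.85, 0.6, 0.5)
    radius: float = 1.0
    axes: tuple[float, float, float] = (1.0, 0.8, 1.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.outlier_fraction < 0.5:
            raise ValueError("outlier fraction must lie in [0, 0.5)")
        if self.n < 10:
            raise ValueError("sample count must be at least 10")
        if self.shape not in ("sphere", "ellipsoid", "cylinder_union"):
            raise ValueError(f"unknown 3D shape {self.shape!r}")


@dataclass
class PointCloudSample:
    points: np.ndarray
    colours: np.ndarray
    is_outlier: np.ndarray
    surface: object
    spec: ShapeSpec3D


def _sample_cylinder_union(surface: CylinderUnionSurface, n: int, rng) -> tuple[np.ndarray, np.ndarray]:
    areas = np.array([c.lateral_area() for c in surface.cylinders])
    probs = areas / areas.sum()
    pts = np.empty((0, 3))
    normals = np.empty((0, 3))
    while len(pts) < n:
        k = n - len(pts)
        which = rng.choice(len(surface.cylinders), size=k, p=probs)
        theta = rng.uniform(0, 2 * np.pi, size=k)
        z = rng.uniform(-1, 1, size=k)
        batch = np.empty((k, 3))
        nrm = np.stack([np.cos(theta), np.sin(theta), np.zeros(k)], axis=1)
        for idx, c in enumerate(surface.cylinders):
            sel = which == idx
            batch[sel, 0] = c.center[0] + c.radius * np.cos(theta[sel])
            batch[sel, 1] = c.center[1] + c.radius * np.sin(theta[sel])
            batch[sel, 2] = c.center[2] + c.half_length * z[sel]
        # keep only points on the union boundary (not inside a sibling)
        inside_other = np.zeros(k, dtype=bool)
        for idx, c in enumerate(surface.cylinders):
            inside_other |= (which != idx) & c.contains(batch)
        pts = np.vstack([pts, batch[~inside_other]])
        normals = np.vstack([normals, nrm[~inside_other]])
    return pts[:n], normals[:n]


def sample_shape3d(spec: ShapeSpec3D) -> PointCloudSample:
    """Sample a coloured point cloud from an analytic surface.

    Surface points receive Gaussian displacement along the outward
    normal (``noise_sigma``); each point independently becomes a
    uniform-box outlier with probability ``outlier_fraction`` (box = the
    surface bounding box scaled ×2).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.shape == "sphere":
        surface = SphereSurface(spec.radius)
        dirs = rng.standard_normal((spec.n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = dirs * spec.radius
        normals = dirs
    elif spec.shape == "ellipsoid":
        surface = EllipsoidSurface(spec.axes)
        dirs = rng.standard_normal((spec.n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = dirs * surface.axes
        normals = pts / surface.axes**2
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    else:
        surface = CylinderUnionSurface()
        pts, normals = _sample_cylinder_union(surface, spec.n, rng)

    if spec.noise_sigma > 0:
        pts = pts + normals * rng.normal(0.0, spec.noise_sigma, size=(spec.n, 1))

    is_outlier = rng.random(spec.n) < spec.outlier_fraction
    if np.any(is_outlier):
        lo, hi = surface.bounding_box()
        c, half = (lo + hi) / 2, (hi - lo)  # box scaled x2 about its centre
        k = int(is_outlier.sum())
        pts[is_outlier] = rng.uniform(c - half, c + half, size=(k, 3))

    if spec.colour_rule == "constant":
        colours = np.tile(np.asarray(spec.colour, dtype=float), (spec.n, 1))
    elif spec.colour_rule == "height":
        z = pts[:, 2]
        t = (z - z.min()) / max(np.ptp(z), 1e-12)
        base = np.asarray(spec.colour, dtype=float)
        colours = np.clip(base * (0.6 + 0.4 * t[:, None]), 0.0, 1.0)
    else:
        raise ValueError(f"unknown colour rule {spec.colour_rule!r}")

    return PointCloudSample(pts, colours, is_outlier, surface, spec)
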