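"""End-to-end orchestration: image → chrominance → skin probability →
mask → planar GNG graph, or depth/cloud → coloured 3D mesh, plus batch
evaluation.  These functions are the library surface behind the CLI and
log one record per executed stage."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fileio, metrics
from .colorspace import D65, WhitePoint, convert
from .gng import GNGConfig, GrowingNeuralGas, learn_pointcloud
from .skinmodel import (
    GaussianMixtureModel,
    SingleGaussianModel,
    load_results,
    threshold_map,
)

logger = logging.getLogger(__name__)

__all__ = ["RunLog", "run_fit", "run_segment", "run_reconstruct", "run_evaluate"]

_SAMPLE_CAP = 500_000


@dataclass
class RunLog:
    """Stage-granular execution log (one record per stage run)."""

    records: list[dict] = field(default_factory=list)

    def record(self, stage: str, **fields) -> dict:
        rec = {"stage": stage, "time": time.strftime("%Y-%m-%dT%H:%M:%S"), **fields}
        self.records.append(rec)
        logger.info("stage %s: %s", stage, fields)
        return rec

    def save(self, path) -> None:
        fileio.save_yaml(path, {"records": self.records})


def _white_point(wp) -> WhitePoint:
    if wp is None:
        return D65
    if isinstance(wp, WhitePoint):
        return wp
    return WhitePoint(*wp)


def collect_training_samples(
    image_paths,
    mask_paths,
    space_tag: str,
    seed: int = 0,
    wp=None,
    invert_mask: bool = False,
    cap: int = _SAMPLE_CAP,
) -> np.ndarray:
    """Chrominance observations under the mask of each image/mask pair.

    ``invert_mask=True`` collects background (non-skin) pixels instead.
    The pooled set is capped (seeded subsampling) at 500,000 pixels.
    """
    wp = _white_point(wp)
    chunks = []
    for img_path, mask_path in zip(image_paths, mask_paths, strict=True):
        img = fileio.load_rgb(img_path)
        mask = fileio.load_mask(mask_path)
        if invert_mask:
            mask = ~mask
        chunks.append(convert(img, space_tag, wp).samples(mask))
    X = np.concatenate(chunks, axis=0)
    if len(X) > cap:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(len(X), size=cap, replace=False)]
    return X


def run_fit(
    image_paths,
    mask_paths,
    space_tag: str,
    model_kind: str = "gmm",
    n_components: int = 3,
    out_path=None,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
    wp=None,
    invert_mask: bool = False,
    runlog: RunLog | None = None,
):
    """Fit a skin (or background) colour model from masked images."""
    X = collect_training_samples(
        image_paths, mask_paths, space_tag, seed=seed, wp=wp, invert_mask=invert_mask
    )
    min_needed = 3 * (n_components if model_kind == "gmm" else 1)
    if len(X) < min_needed:
        raise ValueError(
            f"insufficient training pixels: got {len(X)}, need at least {min_needed}"
        )
    if model_kind == "sgm":
        res = SingleGaussianModel(X, space_tag=space_tag).fit()
        trace = [res.loglike]
    elif model_kind == "gmm":
        res = GaussianMixtureModel(X, n_components, space_tag=space_tag).fit(
            max_iter=max_iter, tol=tol, seed=seed
        )
        trace = res.loglike_trace.tolist()
    else:
        raise ValueError(f"unknown model kind {model_kind!r}; expected 'sgm' or 'gmm'")
    if out_path is not None:
        res.save(out_path)
    if runlog is not None:
        runlog.record(
            "fit",
            kind=model_kind,
            space=space_tag,
            pixels=len(X),
            loglike_trace=[float(v) for v in trace],
        )
    return res


def run_segment(
    image_path,
    model_path,
    out_dir,
    tau: float = metrics.DEFAULT_THRESHOLD,
    background_model_path=None,
    wp=None,
    runlog: RunLog | None = None,
) -> dict:
    """Segment one image with a serialised model.

    Writes ``<stem>_prob.png`` (16-bit probability map) and
    ``<stem>_mask.png`` (8-bit binary mask) into ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img = fileio.load_rgb(image_path)
    model = load_results(model_path)
    background = (
        load_results(background_model_path) if background_model_path else None
    )
    chrom = convert(img, model.space_tag, _white_point(wp))
    pm = model.probability_map(chrom, background)
    mask = threshold_map(pm, tau)
    stem = Path(image_path).stem
    prob_path = out_dir / f"{stem}_prob.png"
    mask_path = out_dir / f"{stem}_mask.png"
    fileio.save_probability_map(prob_path, pm.values)
    fileio.save_mask(mask_path, mask)
    info = {
        "prob_path": str(prob_path),
        "mask_path": str(mask_path),
        "skin_pixels": int(mask.sum()),
        "total_pixels": int(mask.size),
        "tau": tau,
        "map_kind": pm.kind,
    }
    if runlog is not None:
        runlog.record("segment", image=str(image_path), **info)
    return info


def run_reconstruct(
    input_path,
    out_path,
    config: GNGConfig | None = None,
    runlog: RunLog | None = None,
) -> dict:
    """Learn a topology from a mask (2D → JSON graph) or PLY cloud (3D →
    coloured PLY/OBJ mesh), chosen by the input extension."""
    config = config if config is not None else GNGConfig()
    input_path = Path(input_path)
    if input_path.suffix.lower() == ".ply":
        points, colours = fileio.load_ply(input_path)
        mesh = learn_pointcloud(points, config, colours=colours)
        mesh.save(out_path)
        d2 = ((points[:, None, :] - mesh.vertices[None, :, :]) ** 2).sum(axis=2)
        info = {
            "mode": "3d",
            "nodes": len(mesh.vertices),
            "edges": len(mesh.edges),
            "faces": len(mesh.faces),
            "mean_quantisation_error": float(d2.min(axis=1).mean()),
        }
    else:
        mask = fileio.load_mask(input_path)
        res = GrowingNeuralGas.from_mask(mask, config).fit()
        res.graph.save_json(out_path)
        info = {
            "mode": "2d",
            "nodes": res.n_nodes,
            "edges": res.n_edges,
            "components": res.n_components,
            "mean_quantisation_error": res.quantisation_error(),
        }
    info["out_path"] = str(out_path)
    if runlog is not None:
        runlog.record("reconstruct", input=str(input_path), **info)
    return info


def _match_pairs(pred_dir: Path, truth_dir: Path) -> list[tuple[Path, Path]]:
    preds = {p.stem.replace("_mask", "").replace("_prob", ""): p
             for p in sorted(pred_dir.iterdir()) if p.suffix == ".png"}
    truths = {p.stem.replace("_mask", ""): p
              for p in sorted(truth_dir.iterdir()) if p.suffix == ".png"}
    unmatched = sorted(set(preds) ^ set(truths))
    if unmatched:
        raise ValueError(f"unmatched prediction/truth pairs: {unmatched}")
    return [(preds[k], truths[k]) for k in sorted(preds)]


def run_evaluate(
    pred_dir,
    truth_dir,
    out_csv=None,
    tau: float = metrics.DEFAULT_THRESHOLD,
    thresholds=None,
    roc_dir=None,
    runlog: RunLog | None = None,
) -> pd.DataFrame:
    """Evaluate predicted masks/maps against ground-truth masks.

    Predictions may be binary masks (``*_mask.png``) or 16-bit
    probability maps (``*_prob.png``, thresholded at ``tau``); one CSV
    row per image with tpr/fpr/iou/dice.  With ``roc_dir`` set,
    probability maps additionally produce per-image ROC CSVs.
    """
    pairs = _match_pairs(Path(pred_dir), Path(truth_dir))
    rows = []
    for pred_path, truth_path in pairs:
        truth = fileio.load_mask(truth_path)
        if pred_path.stem.endswith("_prob"):
            pm = fileio.load_probability_map(pred_path)
            pred = pm >= tau
            if roc_dir is not None:
                roc_dir = Path(roc_dir)
                roc_dir.mkdir(parents=True, exist_ok=True)
                curve = metrics.roc(pm, truth, thresholds)
                curve.to_frame().to_csv(
                    roc_dir / f"{pred_path.stem}_roc.csv", index=False
                )
        else:
            pred = fileio.load_mask(pred_path)
        report = metrics.evaluate_masks(pred, truth)
        rows.append({"image": pred_path.stem, **report.to_dict()})
    frame = pd.DataFrame(rows)
    if out_csv is not None:
        frame.to_csv(out_csv, index=False)
    if runlog is not None:
        runlog.record("evaluate", images=len(frame), tau=tau)
    return frame
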