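"""File formats used by the pipeline.

Images are PNG/PPM (8-bit RGB in, masks as 8-bit single-channel PNG with
0 = background / 255 = skin, probability maps as 16-bit PNG scaled by
65535 to preserve threshold fidelity).  Point clouds and meshes travel
as ASCII PLY (x, y, z, red, green, blue), topology graphs as JSON and
model parameters / configs as YAML.
"""

from __future__ import annotations

import json

import imageio.v3 as iio
import numpy as np
import trimesh
import yaml

__all__ = [
    "load_rgb",
    "save_rgb",
    "load_mask",
    "save_mask",
    "load_probability_map",
    "save_probability_map",
    "save_channel_png",
    "load_depth",
    "load_ply",
    "save_ply",
    "load_graph_json",
    "load_yaml",
    "save_yaml",
]


def load_rgb(path) -> np.ndarray:
    """Read an 8-bit RGB image to float (H, W, 3) in [0, 1]."""
    img = np.asarray(iio.imread(path))
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[2] == 4:
        img = img[..., :3]
    if img.dtype == np.uint8:
        return img.astype(float) / 255.0
    if img.dtype == np.uint16:
        return img.astype(float) / 65535.0
    return np.clip(img.astype(float), 0.0, 1.0)


def save_rgb(path, img: np.ndarray) -> None:
    iio.imwrite(path, (np.clip(img, 0, 1) * 255).round().astype(np.uint8))


def load_mask(path) -> np.ndarray:
    """Read a binary mask (any non-zero pixel counts as foreground)."""
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., 0]
    return img > 0


def save_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(path, np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def save_probability_map(path, values: np.ndarray) -> None:
    """Probability map in [0, 1] stored as 16-bit PNG (scaled by 65535)."""
    iio.imwrite(path, (np.clip(values, 0, 1) * 65535).round().astype(np.uint16))


def load_probability_map(path) -> np.ndarray:
    return np.asarray(iio.imread(path)).astype(float) / 65535.0


def save_channel_png(path, channel: np.ndarray) -> None:
    """Greyscale visualisation of one chrominance channel (min-max scaled)."""
    c = np.asarray(channel, dtype=float)
    rng = np.ptp(c)
    scaled = (c - c.min()) / rng if rng > 0 else np.zeros_like(c)
    iio.imwrite(path, (scaled * 255).round().astype(np.uint8))


def load_depth(path) -> np.ndarray:
    """16-bit single-channel depth image, returned as float."""
    return np.asarray(iio.imread(path)).astype(float)


def load_ply(path) -> tuple[np.ndarray, np.ndarray | None]:
    """ASCII PLY point cloud: returns (points, colours in [0,1] or None)."""
    loaded = trimesh.load(str(path), process=False)
    if isinstance(loaded, trimesh.points.PointCloud):
        pts = np.asarray(loaded.vertices, dtype=float)
        cols = np.asarray(loaded.colors, dtype=float)
    else:
        pts = np.asarray(loaded.vertices, dtype=float)
        cols = np.asarray(getattr(loaded.visual, "vertex_colors", None), dtype=float)
    colours = cols[:, :3] / 255.0 if cols is not None and cols.size else None
    return pts, colours


def save_ply(path, points: np.ndarray, colours: np.ndarray | None = None) -> None:
    cloud = trimesh.points.PointCloud(
        np.asarray(points, dtype=float),
        colors=None
        if colours is None
        else np.hstack(
            [
                (np.clip(colours, 0, 1) * 255).astype(np.uint8),
                np.full((len(points), 1), 255, np.uint8),
            ]
        ),
    )
    with open(path, "wb") as fh:
        fh.write(cloud.export(file_type="ply", encoding="ascii"))


def load_graph_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_yaml(path, doc: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
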