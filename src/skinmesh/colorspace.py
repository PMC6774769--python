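"""Chrominance colour representations for skin modelling.

Skin colour clusters much more tightly once pixel intensity is separated
from chromaticity, so the statistical skin models operate on two-channel
chrominance planes rather than raw RGB.  Four representations are
supported:

``nrgb``
    normalised RGB chromaticities ``(r, g)`` with ``r = R/(R+G+B)``.
``hsv``
    hexcone hue/saturation ``(H, S)``, both scaled to ``[0, 1]``.
``xyz``
    CIE xy chromaticities ``(x, y)`` of the tristimulus values obtained
    from a fixed linear RGB→XYZ matrix.
``lab``
    the opponent chrominance pair ``(a*, b*)`` of CIE L*a*b*, via the
    standard nonlinear transform from XYZ with a configurable white
    point (D65 by default).

All conversions are pixel-wise maps on float images with channels in
``[0, 1]`` (8-bit input is divided by 255 at load time).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import color as _skcolor

__all__ = [
    "RGB_TO_XYZ_MATRIX",
    "D65",
    "WhitePoint",
    "ChrominanceImage",
    "SPACE_TAGS",
    "rgb_to_nrgb",
    "rgb_to_hsv",
    "rgb_to_xyz_raw",
    "rgb_to_xyz",
    "xyz_to_lab",
    "lab_f",
    "lab_f_inv",
    "rgb_to_lab",
    "lab_to_rgb",
    "convert",
]

#: Linear RGB -> CIE XYZ matrix (unit-range RGB in, tristimulus out).
RGB_TO_XYZ_MATRIX = np.array(
    [
        [0.433910, 0.376220, 0.189860],
        [0.212649, 0.715169, 0.072182],
        [0.017756, 0.109478, 0.872915],
    ]
)

_LAB_THRESHOLD = 0.008856
_LAB_SLOPE = 7.7867
_LAB_OFFSET = 16.0 / 116.0

#: The neutral chromaticity used for zero-intensity pixels.
_NEUTRAL = (1.0 / 3.0, 1.0 / 3.0)


@dataclass(frozen=True)
class WhitePoint:
    """Reference white tristimulus (Xn, Yn, Zn) for the L*a*b* transform."""

    Xn: float
    Yn: float
    Zn: float

    def __post_init__(self) -> None:
        if min(self.Xn, self.Yn, self.Zn) <= 0:
            raise ValueError("white point components must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.Xn, self.Yn, self.Zn])


#: CIE D65 daylight reference white.
D65 = WhitePoint(0.95047, 1.0, 1.08883)

_CHANNEL_NAMES = {
    "nrgb": ("r", "g"),
    "hsv": ("H", "S"),
    "xyz": ("x", "y"),
    "lab": ("a*", "b*"),
}

SPACE_TAGS = tuple(_CHANNEL_NAMES)


@dataclass
class ChrominanceImage:
    """An H×W image of two-channel chrominance vectors.

    ``values`` has shape (H, W, 2); ``space_tag`` identifies the colour
    space and fixes the channel names.
    """

    values: np.ndarray
    space_tag: str
    channel_names: tuple[str, str] = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != 2:
            raise ValueError("chrominance image must have shape (H, W, 2)")
        if self.space_tag not in _CHANNEL_NAMES:
            raise ValueError(f"unknown space tag {self.space_tag!r}")
        self.channel_names = _CHANNEL_NAMES[self.space_tag]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    def samples(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Flatten to a (T, 2) observation matrix, optionally masked."""
        if mask is None:
            return self.values.reshape(-1, 2)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.shape:
            raise ValueError("mask shape does not match image shape")
        return self.values[mask]


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("RGB image must have shape (H, W, 3)")
    return img


def _chromaticity(channels: np.ndarray) -> np.ndarray:
    """First two channels divided by the channel sum, neutral at zero sum."""
    total = channels.sum(axis=-1)
    zero = total == 0
    safe = np.where(zero, 1.0, total)
    out = channels[..., :2] / safe[..., None]
    out[zero] = _NEUTRAL
    return out


def rgb_to_nrgb(img: np.ndarray) -> ChrominanceImage:
    """Normalised-RGB chromaticities (r, g); black pixels map to (1/3, 1/3)."""
    return ChrominanceImage(_chromaticity(_check_rgb(img)), "nrgb")


def rgb_to_hsv(img: np.ndarray) -> ChrominanceImage:
    """Hexcone (H, S) in [0, 1]; achromatic pixels get H = 0, S = 0."""
    hsv = _skcolor.rgb2hsv(_check_rgb(img))
    return ChrominanceImage(hsv[..., :2], "hsv")


def rgb_to_xyz_raw(img: np.ndarray) -> np.ndarray:
    """Apply the fixed linear RGB→XYZ matrix; returns (H, W, 3) tristimulus."""
    return _check_rgb(img) @ RGB_TO_XYZ_MATRIX.T


def rgb_to_xyz(img: np.ndarray) -> ChrominanceImage:
    """CIE xy chromaticities of the linear XYZ transform."""
    return ChrominanceImage(_chromaticity(rgb_to_xyz_raw(img)), "xyz")


def lab_f(r: np.ndarray) -> np.ndarray:
    """The L*a*b* compression function: cube root above 0.008856, linear below."""
    r = np.asarray(r, dtype=float)
    return np.where(r > _LAB_THRESHOLD, np.cbrt(r), _LAB_SLOPE * r + _LAB_OFFSET)


def lab_f_inv(f: np.ndarray) -> np.ndarray:
    """Inverse of :func:`lab_f` (used when lifting synthetic chrominance to RGB)."""
    f = np.asarray(f, dtype=float)
    knee = lab_f(np.array(_LAB_THRESHOLD))
    return np.where(f > knee, f**3, (f - _LAB_OFFSET) / _LAB_SLOPE)


def xyz_to_lab(X, Y, Z, wp: WhitePoint = D65):
    """CIE L*a*b* from tristimulus values relative to a white point."""
    fx = lab_f(np.asarray(X, dtype=float) / wp.Xn)
    fy = lab_f(np.asarray(Y, dtype=float) / wp.Yn)
    fz = lab_f(np.asarray(Z, dtype=float) / wp.Zn)
    L = 116.0 * fy - 16.0
    a = 500.0 * (fx - fy)
    b = 200.0 * (fy - fz)
    return L, a, b


def rgb_to_lab(img: np.ndarray, wp: WhitePoint = D65) -> ChrominanceImage:
    """The (a*, b*) opponent chrominance plane of CIE L*a*b*."""
    xyz = rgb_to_xyz_raw(img)
    _, a, b = xyz_to_lab(xyz[..., 0], xyz[..., 1], xyz[..., 2], wp)
    return ChrominanceImage(np.stack([a, b], axis=-1), "lab")


def lab_to_rgb(L, a, b, wp: WhitePoint = D65) -> np.ndarray:
    """Invert L*a*b* back to unit-range RGB (clipped); synthesis helper."""
    L = np.asarray(L, dtype=float)
    fy = (L + 16.0) / 116.0
    fx = fy + np.asarray(a, dtype=float) / 500.0
    fz = fy - np.asarray(b, dtype=float) / 200.0
    xyz = np.stack(
        [lab_f_inv(fx) * wp.Xn, lab_f_inv(fy) * wp.Yn, lab_f_inv(fz) * wp.Zn],
        axis=-1,
    )
    rgb = xyz @ np.linalg.inv(RGB_TO_XYZ_MATRIX).T
    return np.clip(rgb, 0.0, 1.0)


def convert(img: np.ndarray, space_tag: str, wp: WhitePoint = D65) -> ChrominanceImage:
    """Dispatch to the conversion named by ``space_tag``."""
    tag = space_tag.lower()
    if tag == "nrgb":
        return rgb_to_nrgb(img)
    if tag == "hsv":
        return rgb_to_hsv(img)
    if tag == "xyz":
        return rgb_to_xyz(img)
    if tag == "lab":
        return rgb_to_lab(img, wp)
    raise ValueError(f"unknown colour space tag {space_tag!r}; expected one of {SPACE_TAGS}")
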