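"""Gel-image loading and non-destructive quality enhancement.

A :class:`GelImage` carries the working pixel raster (float in ``[0, 1]``),
the raster as it came off disk, and an ordered history of every operation
applied since load. Operations never touch the stored source: each one is a
pure function of (pixels, parameters), so replaying the history on the
source reproduces the working pixels bit-for-bit. This is the provenance
contract the rest of the pipeline relies on.

Internally bands are assumed BRIGHT on a dark background; gels photographed
with a light background are brought into this convention with
:func:`invert`. Coordinates are 0-based, row-major, row 0 at the wells
(migration increases downward); crop rectangles are half-open.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
from PIL import Image
from scipy import ndimage
from skimage import restoration
from skimage import transform as _sktransform

from .errors import DomainError, FormatError

SUPPORTED_EXTENSIONS = (".tif", ".tiff", ".png", ".jpg", ".jpeg", ".gif", ".bmp")

# ITU-R BT.601 luminance weights for colour -> grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclasses.dataclass(frozen=True)
class GelImage:
    """A grayscale gel raster plus the provenance of its processing.

    Attributes
    ----------
    pixels : ndarray
        Working intensities, float64 in [0, 1].
    source : ndarray
        Intensities as loaded from disk (same scale), never modified.
    history : tuple
        Ordered ``(operation_name, params_dict)`` descriptors.
    """

    pixels: np.ndarray
    source: np.ndarray
    history: tuple = ()

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "GelImage":
        """Wrap an in-memory float array in [0, 1] (e.g. a synthetic gel)."""
        a = np.asarray(arr, dtype=np.float64)
        if a.ndim != 2:
            raise DomainError(f"expected a 2-D array, got shape {a.shape}")
        if not np.all(np.isfinite(a)) or a.min() < 0 or a.max() > 1:
            raise DomainError("intensities must be finite and in [0, 1]")
        return cls(pixels=a.copy(), source=a.copy(), history=())

    def replay(self) -> np.ndarray:
        """Re-apply ``history`` to ``source``; equals ``pixels`` bit-for-bit."""
        return replay_history(self.source, self.history)


def _to_unit_gray(arr: np.ndarray) -> np.ndarray:
    """Rescale a raw raster to float64 [0, 1] by its bit depth; colour -> luma."""
    a = np.asarray(arr)
    if a.ndim == 3:  # RGB(A): luminance on the unit-scaled channels
        rgb = np.stack([_to_unit_gray(a[..., k]) for k in range(3)], axis=-1)
        return rgb @ _LUMA
    if a.dtype == np.uint8:
        return a.astype(np.float64) / 255.0
    if a.dtype == np.uint16:
        return a.astype(np.float64) / 65535.0
    if a.dtype == np.int32 or a.dtype == np.uint32:
        return a.astype(np.float64) / float(max(a.max(), 1))
    if np.issubdtype(a.dtype, np.floating):
        return np.clip(a.astype(np.float64), 0.0, 1.0)
    if a.dtype == bool:
        return a.astype(np.float64)
    raise FormatError(f"unsupported pixel dtype {a.dtype}")


def load_image(path: str | Path) -> GelImage:
    """Load a gel image (tiff/jpeg/png/gif/bmp), grayscale, unit-scaled.

    Colour images are converted to grayscale by luminance; 8- and 16-bit
    integer rasters are divided by the full range of their bit depth.
    """
    p = Path(path)
    ext = p.suffix.lower()
    if ext not in SUPPORTED_EXTENSIONS:
        raise FormatError(
            f"unsupported image format {ext!r} for {p}; "
            f"supported: {', '.join(SUPPORTED_EXTENSIONS)}"
        )
    if not p.exists():
        raise OSError(f"cannot read image file: {p}")
    try:
        if ext in (".tif", ".tiff"):
            raw = tifffile.imread(p)
        else:
            with Image.open(p) as im:
                if im.mode == "P":
                    im = im.convert("RGB")
                raw = np.array(im)
    except OSError:
        raise
    except Exception as exc:  # decoder errors vary by format
        raise OSError(f"cannot read image file: {p}: {exc}") from exc
    unit = _to_unit_gray(raw)
    return GelImage(pixels=unit.copy(), source=unit.copy(), history=())


def save_image(img: GelImage, path: str | Path, bit_depth: int = 8) -> None:
    """Write the working pixels to disk (8- or 16-bit grayscale)."""
    p = Path(path)
    ext = p.suffix.lower()
    if ext not in SUPPORTED_EXTENSIONS:
        raise FormatError(f"unsupported output format {ext!r}")
    if bit_depth == 8:
        arr = np.round(img.pixels * 255.0).astype(np.uint8)
    elif bit_depth == 16:
        arr = np.round(img.pixels * 65535.0).astype(np.uint16)
    else:
        raise DomainError("bit_depth must be 8 or 16")
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(p, arr)
    else:
        if bit_depth == 16:
            raise FormatError("16-bit output only supported for TIFF")
        Image.fromarray(arr, mode="L").save(p)


# ---------------------------------------------------------------------------
# pixel-level operations (pure; registered for history replay)
# ---------------------------------------------------------------------------


def _px_crop(px, r0: int, r1: int, c0: int, c1: int):
    h, w = px.shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise DomainError(
            f"crop rectangle [{r0},{r1})x[{c0},{c1}) outside {h}x{w} image"
        )
    return px[r0:r1, c0:c1].copy()


def _px_invert(px):
    return 1.0 - px


def _px_flip(px, axis: str):
    if axis == "horizontal":  # mirror left-right
        return px[:, ::-1].copy()
    if axis == "vertical":
        return px[::-1, :].copy()
    raise DomainError(f"flip axis must be 'horizontal' or 'vertical', got {axis!r}")


def _px_rotate(px, angle_deg: float):
    a = float(angle_deg) % 360.0
    if a % 90.0 == 0.0:  # lossless quarter-turns
        return np.rot90(px, k=int(a // 90)).copy()
    out = _sktransform.rotate(
        px, angle_deg, resize=True, order=1, mode="constant", cval=0.0,
        preserve_range=True,
    )
    return np.clip(out, 0.0, 1.0)


def _px_window(px, lo: float, hi: float):
    if not (0.0 <= lo < hi <= 1.0):
        raise DomainError(f"require 0 <= lo < hi <= 1, got lo={lo}, hi={hi}")
    return np.clip((px - lo) / (hi - lo), 0.0, 1.0)


def _px_autocontrast(px, saturation_fraction: float):
    if not (0.0 <= saturation_fraction < 0.5):
        raise DomainError("saturation_fraction must lie in [0, 0.5)")
    lo = float(np.quantile(px, saturation_fraction))
    hi = float(np.quantile(px, 1.0 - saturation_fraction))
    if hi - lo < 1e-12:  # flat image: nothing to stretch
        return px.copy()
    return np.clip((px - lo) / (hi - lo), 0.0, 1.0)


_RANK_FILTERS = {
    "median": ndimage.median_filter,
    "minimum": ndimage.minimum_filter,
    "maximum": ndimage.maximum_filter,
}


def _px_filter(px, kind: str, radius_or_sigma: float):
    if kind == "gaussian":
        if radius_or_sigma <= 0:
            raise DomainError("gaussian sigma must be > 0")
        out = ndimage.gaussian_filter(px, sigma=radius_or_sigma, mode="reflect")
        return np.clip(out, 0.0, 1.0)
    r = int(radius_or_sigma)
    if r < 1 or r != radius_or_sigma:
        raise DomainError("filter radius must be a positive integer")
    size = 2 * r + 1
    if kind in _RANK_FILTERS:
        return _RANK_FILTERS[kind](px, size=size, mode="reflect")
    if kind == "mean":
        return ndimage.uniform_filter(px, size=size, mode="reflect")
    if kind == "variance":
        m = ndimage.uniform_filter(px, size=size, mode="reflect")
        m2 = ndimage.uniform_filter(px * px, size=size, mode="reflect")
        return np.clip(m2 - m * m, 0.0, 1.0)
    raise DomainError(f"unknown filter kind {kind!r}")


def _px_rolling_ball(px, ball_radius_px: int, light_background: bool = False):
    r = int(ball_radius_px)
    if r < 1:
        raise DomainError("ball_radius_px must be >= 1")
    work = 1.0 - px if light_background else px
    # ball geometry in 8-bit gray levels, as in the classic implementation:
    # on a unit-intensity image the ball would otherwise be near-flat in
    # intensity and swallow narrow bands
    background = restoration.rolling_ball(work * 255.0, radius=r) / 255.0
    out = np.clip(work - background, 0.0, 1.0)
    return 1.0 - out if light_background else out


def _px_gamma(px, gamma: float):
    if gamma <= 0:
        raise DomainError(f"gamma must be > 0, got {gamma}")
    return np.power(px, gamma)


_REGISTRY = {
    "crop": _px_crop,
    "invert": _px_invert,
    "flip": _px_flip,
    "rotate": _px_rotate,
    "window": _px_window,
    "autocontrast": _px_autocontrast,
    "filter": _px_filter,
    "rolling_ball": _px_rolling_ball,
    "gamma": _px_gamma,
}


def replay_history(source: np.ndarray, history) -> np.ndarray:
    px = np.asarray(source, dtype=np.float64).copy()
    for name, params in history:
        px = _REGISTRY[name](px, **params)
    return px


def _applied(img: GelImage, name: str, **params: Any) -> GelImage:
    out = _REGISTRY[name](img.pixels, **params)
    return GelImage(pixels=out, source=img.source,
                    history=img.history + ((name, dict(params)),))


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def crop(img: GelImage, r0: int, r1: int, c0: int, c1: int) -> GelImage:
    """Crop to the half-open rectangle [r0, r1) x [c0, c1)."""
    return _applied(img, "crop", r0=int(r0), r1=int(r1), c0=int(c0), c1=int(c1))


def invert(img: GelImage) -> GelImage:
    """Map every intensity v -> 1 - v (light-background <-> dark-background)."""
    return _applied(img, "invert")


def flip(img: GelImage, axis: str) -> GelImage:
    """Mirror the gel ('horizontal' = left-right, 'vertical' = top-bottom)."""
    return _applied(img, "flip", axis=axis)


def rotate(img: GelImage, angle_deg: float) -> GelImage:
    """Rotate counter-clockwise; quarter-turns are lossless, otherwise
    bilinear on an expanded zero-filled canvas."""
    return _applied(img, "rotate", angle_deg=float(angle_deg))


def adjust_brightness_contrast(
    img: GelImage,
    lo: float | None = None,
    hi: float | None = None,
    saturation_fraction: float | None = None,
) -> GelImage:
    """Linear window/level contrast stretch.

    Manual mode: supply ``lo < hi``; v -> clip((v - lo)/(hi - lo), 0, 1).
    Auto mode: supply ``saturation_fraction`` f in [0, 0.5); the window is the
    [f, 1-f] intensity quantile pair, saturating f of the pixels at each end.
    """
    manual = lo is not None or hi is not None
    if manual == (saturation_fraction is not None):
        raise DomainError("give either (lo, hi) or saturation_fraction, not both")
    if manual:
        return _applied(img, "window", lo=float(lo), hi=float(hi))
    return _applied(img, "autocontrast",
                    saturation_fraction=float(saturation_fraction))


def apply_filter(img: GelImage, kind: str, radius_or_sigma: float) -> GelImage:
    """Windowed filter: median/mean/minimum/maximum/variance (integer radius,
    window 2r+1) or gaussian (sigma). Boundaries are handled by reflection."""
    return _applied(img, "filter", kind=kind,
                    radius_or_sigma=float(radius_or_sigma)
                    if kind == "gaussian" else int(radius_or_sigma))


def subtract_background(img: GelImage, ball_radius_px: int,
                        light_background: bool = False) -> GelImage:
    """Rolling-ball background removal (grayscale morphological opening with a
    ball structuring element); result clipped to [0, 1]."""
    return _applied(img, "rolling_ball", ball_radius_px=int(ball_radius_px),
                    light_background=bool(light_background))


def gamma_correct(img: GelImage, gamma: float) -> GelImage:
    """Pointwise power law v -> v**gamma."""
    return _applied(img, "gamma", gamma=float(gamma))
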