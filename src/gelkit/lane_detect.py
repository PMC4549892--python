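"""Lane segmentation from the vertical projection profile.

Lanes hold biological material and are brighter than the background between
them, so the column-wise mean intensity of the gel shows one local peak per
lane. Lanes are represented by a centerline (a cubic spline through control
points, straight for freshly detected lanes), a thickness, an optional
reference flag (ladder lanes used for normalization) and an open metadata
map (genus, species, strain number, ...).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import make_interp_spline

from .errors import DomainError
from .preprocess import GelImage, _px_window

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class ProjectionProfile:
    """1-D mean-intensity profile: per image column (axis='columns') or per
    lane row (axis='rows', a densitometric curve). ``start`` is the image
    index of the first profile sample."""

    values: np.ndarray
    axis: str
    start: int = 0

    def __post_init__(self):
        object.__setattr__(self, "values",
                           np.asarray(self.values, dtype=np.float64))
        if self.axis not in ("columns", "rows"):
            raise DomainError("axis must be 'columns' or 'rows'")


@dataclasses.dataclass(frozen=True)
class Lane:
    """A geometric strip of the gel.

    ``centerline`` is a tuple of (row, column) control points with strictly
    increasing rows; between control points the column is interpolated by a
    spline of degree min(3, n_points - 1), so a 2-point centerline is a
    straight line and control points are always interpolated exactly.
    """

    centerline: tuple
    thickness_px: int
    is_reference: bool = False
    info: dict = dataclasses.field(default_factory=dict)
    local_adjust: dict | None = None
    band_threshold: float | None = None

    def __post_init__(self):
        pts = tuple((float(r), float(c)) for r, c in self.centerline)
        object.__setattr__(self, "centerline", pts)
        rows = [r for r, _ in pts]
        if len(pts) < 2:
            raise DomainError("centerline needs >= 2 control points")
        if any(b <= a for a, b in zip(rows, rows[1:])):
            raise DomainError("centerline rows must be strictly increasing")
        if self.thickness_px < 1:
            raise DomainError("thickness_px must be >= 1")

    @property
    def row_span(self) -> tuple[float, float]:
        return self.centerline[0][0], self.centerline[-1][0]

    def column_at(self, rows) -> np.ndarray:
        """Interpolated centerline column at the given row(s)."""
        r = np.atleast_1d(np.asarray(rows, dtype=np.float64))
        cr = np.array([p[0] for p in self.centerline])
        cc = np.array([p[1] for p in self.centerline])
        k = min(3, len(cr) - 1)
        spl = make_interp_spline(cr, cc, k=k)
        out = spl(np.clip(r, cr[0], cr[-1]))
        return out if np.ndim(rows) else float(out[0])

    def center_column(self) -> float:
        """Mean centerline column — the lane's x-position for shift fields."""
        r0, r1 = self.row_span
        rows = np.linspace(r0, r1, 50)
        return float(np.mean(self.column_at(rows)))


# ---------------------------------------------------------------------------
# profiles and peaks
# ---------------------------------------------------------------------------


def vertical_profile(img: GelImage) -> ProjectionProfile:
    """Mean intensity of each pixel column."""
    if img.pixels.size == 0:
        raise DomainError("empty image")
    return ProjectionProfile(values=img.pixels.mean(axis=0), axis="columns")


def find_profile_peaks(profile: ProjectionProfile | np.ndarray,
                       min_height: float,
                       min_separation_px: int) -> list[int]:
    """Strict local maxima >= min_height, greedily thinned.

    Thinning keeps peaks in decreasing height order (ties: leftmost first)
    and discards any candidate closer than ``min_separation_px`` to an
    already-kept peak. The result is sorted ascending and deterministic.
    """
    if min_separation_px < 1:
        raise DomainError("min_separation_px must be >= 1")
    v = profile.values if isinstance(profile, ProjectionProfile) else \
        np.asarray(profile, dtype=np.float64)
    n = len(v)
    cand = [i for i in range(1, n - 1)
            if v[i] > v[i - 1] and v[i] > v[i + 1] and v[i] >= min_height]
    kept: list[int] = []
    for i in sorted(cand, key=lambda i: (-v[i], i)):
        if all(abs(i - j) >= min_separation_px for j in kept):
            kept.append(i)
    return sorted(kept)


# ---------------------------------------------------------------------------
# lane detection and editing
# ---------------------------------------------------------------------------


def detect_lanes(img: GelImage,
                 expected_lane_count: int | None = None,
                 min_height: float | None = None,
                 min_separation_px: int | None = None) -> list[Lane]:
    """Segment lanes as straight vertical strips through profile peaks.

    Defaults (used when arguments are None): ``min_height`` = profile mean +
    0.5 * profile std; ``min_separation_px`` = width / (4 + expected lanes)
    when the count is known, else 10 px. Thickness is 0.8x the median
    inter-peak gap (>= 3 px). With ``expected_lane_count`` set and more peaks
    found, the highest-valued peaks are kept.
    """
    prof = vertical_profile(img)
    v = prof.values
    if min_height is None:
        min_height = float(v.mean() + 0.5 * v.std())
    if min_separation_px is None:
        if expected_lane_count:
            min_separation_px = max(1, img.width_px // (4 + expected_lane_count))
        else:
            min_separation_px = 10
    if img.width_px <= 3 * min_separation_px:
        raise DomainError("image too narrow for the requested lane separation")
    peaks = find_profile_peaks(prof, min_height, min_separation_px)
    if not peaks:
        logger.warning("no lane peaks found; returning empty lane list")
        return []
    if expected_lane_count is not None and len(peaks) > expected_lane_count:
        best = sorted(peaks, key=lambda i: (-v[i], i))[:expected_lane_count]
        peaks = sorted(best)
    elif expected_lane_count is not None and len(peaks) < expected_lane_count:
        logger.warning("found %d lanes, expected %d; caller may add lanes",
                       len(peaks), expected_lane_count)
    if len(peaks) >= 2:
        thickness = max(3, int(round(0.8 * float(np.median(np.diff(peaks))))))
    else:
        thickness = max(3, int(min_separation_px))
    h = img.height_px
    return [Lane(centerline=((0.0, float(c)), (float(h - 1), float(c))),
                 thickness_px=thickness)
            for c in peaks]


_EDITS = ("add", "remove", "set_thickness", "shift", "set_curvature",
          "set_local_adjust", "set_reference", "set_info", "set_band_threshold")


def edit_lanes(lanes: Sequence[Lane], op: str, **kwargs) -> list[Lane]:
    """Apply one lane edit, returning a new list (inputs untouched).

    Supported ops: ``add(centerline, thickness_px)``, ``remove(index)``,
    ``set_thickness(index, px)``, ``shift(index, delta_col)``,
    ``set_curvature(index, control_points)``, ``set_local_adjust(index,
    window=None, background_radius=None)``, ``set_reference(index, flag)``,
    ``set_info(index, key, value)``, ``set_band_threshold(index, value)``.
    """
    out = list(lanes)
    if op == "add":
        out.append(Lane(centerline=tuple(kwargs["centerline"]),
                        thickness_px=int(kwargs["thickness_px"])))
        return out
    if op not in _EDITS:
        raise DomainError(f"unknown lane edit {op!r}")
    i = int(kwargs["index"])
    if not 0 <= i < len(out):
        raise DomainError(f"lane index {i} out of range 0..{len(out) - 1}")
    lane = out[i]
    if op == "remove":
        del out[i]
    elif op == "set_thickness":
        out[i] = dataclasses.replace(lane, thickness_px=int(kwargs["px"]))
    elif op == "shift":
        d = float(kwargs["delta_col"])
        moved = tuple((r, c + d) for r, c in lane.centerline)
        out[i] = dataclasses.replace(lane, centerline=moved)
    elif op == "set_curvature":
        out[i] = dataclasses.replace(
            lane, centerline=tuple(kwargs["control_points"]))
    elif op == "set_local_adjust":
        adj = {}
        if kwargs.get("window") is not None:
            lo, hi = kwargs["window"]
            if not (0.0 <= lo < hi <= 1.0):
                raise DomainError("window must satisfy 0 <= lo < hi <= 1")
            adj["window"] = (float(lo), float(hi))
        if kwargs.get("background_radius") is not None:
            adj["background_radius"] = int(kwargs["background_radius"])
        out[i] = dataclasses.replace(lane, local_adjust=adj or None)
    elif op == "set_reference":
        out[i] = dataclasses.replace(lane, is_reference=bool(kwargs["flag"]))
    elif op == "set_info":
        info = dict(lane.info)
        info[str(kwargs["key"])] = str(kwargs["value"])
        out[i] = dataclasses.replace(lane, info=info)
    elif op == "set_band_threshold":
        out[i] = dataclasses.replace(
            lane, band_threshold=float(kwargs["value"]))
    return out


def extract_lane_profile(img: GelImage, lane: Lane) -> ProjectionProfile:
    """Densitometric curve: per spanned row, the mean intensity across the
    lane's thickness centered on the (possibly curved) centerline.

    Sampling is nearest-pixel: at each row the window covers ``thickness``
    columns centered at the rounded spline column (clipped at the image
    edge). The lane's ``local_adjust`` window and 1-D background-removal
    radius, if set, are applied to the curve.
    """
    r0, r1 = lane.row_span
    rows = np.arange(int(np.ceil(r0)), int(np.floor(r1)) + 1)
    if rows.size == 0:
        raise DomainError("lane spans no rows")
    cols = np.round(lane.column_at(rows.astype(np.float64))).astype(int)
    t = lane.thickness_px
    offsets = np.arange(t) - t // 2
    idx = np.clip(cols[:, None] + offsets[None, :], 0, img.width_px - 1)
    strip = img.pixels[np.clip(rows, 0, img.height_px - 1)[:, None], idx]
    if lane.local_adjust and "window" in lane.local_adjust:
        lo, hi = lane.local_adjust["window"]
        strip = _px_window(strip, lo, hi)
    values = strip.mean(axis=1)
    if lane.local_adjust and "background_radius" in lane.local_adjust:
        from scipy.ndimage import grey_opening
        r = int(lane.local_adjust["background_radius"])
        values = np.clip(values - grey_opening(values, size=2 * r + 1), 0.0, 1.0)
    return ProjectionProfile(values=values, axis="rows", start=int(rows[0]))
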