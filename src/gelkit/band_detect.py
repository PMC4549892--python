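"""Densitometric band calling.

Bands appear as local maxima of a lane's densitometric curve. A light
Gaussian pre-smoothing (sigma = 1 px by default, 0 disables) suppresses
single-pixel noise peaks; a minimum-height criterion separates real bands
from noise, with a global threshold that every lane may override. Manual
band picking is supported through an undoable edit history that survives
serialization.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import DomainError, GelKitError
from .lane_detect import Lane, ProjectionProfile, find_profile_peaks
from .normalize import MigrationModel, ShiftField, normalized_row

DEFAULT_SMOOTH_SIGMA = 1.0
DEFAULT_MIN_BAND_SEPARATION = 5


@dataclasses.dataclass(frozen=True)
class Band:
    """One detected band on a lane."""

    lane_index: int
    row_px: float
    height: float
    origin: str = "auto"  # 'auto' or 'manual'
    normalized_row_px: float | None = None
    molecular_weight: float | None = None


@dataclasses.dataclass(frozen=True)
class BandPattern:
    """A lane's band list plus its densitometric curve — the unit of
    comparison. ``marker_name`` records the normalization context; two
    patterns are comparable only if it matches.

    ``curve_weights`` (filled by :func:`weigh_bands`) maps every curve
    sample to a molecular weight, letting curve-based similarity align
    densitometric curves from different gels.
    """

    lane_index: int
    bands: tuple
    curve: ProjectionProfile
    marker_name: str = ""
    curve_weights: np.ndarray | None = None
    edits: tuple = ()       # net manual-edit descriptors
    edit_cursor: int = 0    # edits[:edit_cursor] are in effect
    base_bands: tuple | None = None  # auto-detected bands before any edit

    def __post_init__(self):
        object.__setattr__(self, "bands", tuple(
            sorted(self.bands, key=lambda b: b.row_px)))

    @property
    def rows(self) -> np.ndarray:
        return np.array([b.row_px for b in self.bands])

    @property
    def weights(self) -> np.ndarray:
        return np.array([b.molecular_weight for b in self.bands], dtype=float)


def default_global_threshold(curve: ProjectionProfile) -> float:
    """Heuristic height threshold: curve median + 0.3 * (max - median).

    The optimal threshold varies between gels and is normally user-set;
    this default keeps headless runs sensible.
    """
    v = curve.values
    med = float(np.median(v))
    return med + 0.3 * (float(v.max()) - med)


def detect_bands(curve: ProjectionProfile,
                 global_threshold: float | None = None,
                 lane_threshold: float | None = None,
                 min_separation_px: int = DEFAULT_MIN_BAND_SEPARATION,
                 smooth_sigma: float = DEFAULT_SMOOTH_SIGMA) -> list[int]:
    """Band rows (image coordinates) from a densitometric curve.

    The curve is Gaussian-smoothed (``smooth_sigma``; 0 disables), strict
    local maxima at or above the effective threshold (the lane override if
    set, else the global threshold) are kept, then thinned so no two bands
    are closer than ``min_separation_px``. Output is deterministic.
    """
    thr = lane_threshold if lane_threshold is not None else global_threshold
    if thr is None:
        thr = default_global_threshold(curve)
    if not (0.0 <= thr <= 1.0):
        raise DomainError(f"threshold must lie in [0, 1], got {thr}")
    v = curve.values
    if smooth_sigma > 0:
        v = gaussian_filter1d(v, sigma=smooth_sigma, mode="reflect")
    idx = find_profile_peaks(v, min_height=thr,
                             min_separation_px=min_separation_px)
    return [int(i + curve.start) for i in idx]


def pattern_from_curve(curve: ProjectionProfile, lane_index: int,
                       marker_name: str = "", **detect_kwargs) -> BandPattern:
    """Detect bands on a curve and wrap them in a BandPattern."""
    rows = detect_bands(curve, **detect_kwargs)
    v = curve.values
    bands = tuple(Band(lane_index=lane_index, row_px=float(r),
                       height=float(v[int(r) - curve.start]))
                  for r in rows)
    return BandPattern(lane_index=lane_index, bands=bands, curve=curve,
                       marker_name=marker_name)


# ---------------------------------------------------------------------------
# manual editing with undo/redo
# ---------------------------------------------------------------------------


def _curve_height(curve: ProjectionProfile, row: float) -> float:
    i = int(round(row)) - curve.start
    if not 0 <= i < len(curve.values):
        raise DomainError(f"row {row} outside lane span")
    return float(curve.values[i])


def _apply_edit(bands: tuple, curve: ProjectionProfile, lane_index: int,
                edit: tuple) -> tuple:
    kind, row = edit
    if kind == "add":
        b = Band(lane_index=lane_index, row_px=float(row),
                 height=_curve_height(curve, row), origin="manual")
        return tuple(sorted(bands + (b,), key=lambda x: x.row_px))
    if kind == "remove":
        hits = [b for b in bands if abs(b.row_px - row) <= 1.0]
        if not hits:
            raise GelKitError(f"no band within 1 px of row {row}")
        victim = min(hits, key=lambda b: (abs(b.row_px - row), b.row_px))
        return tuple(b for b in bands if b is not victim)
    raise DomainError(f"unknown band edit {kind!r}")


def edit_bands(pattern: BandPattern, op: str,
               row: float | None = None) -> BandPattern:
    """Apply ``add(row)``/``remove(row)``/``undo``/``redo`` to a pattern.

    Edits live on a linear history: a new edit truncates any redo branch.
    The band list is always the replay of the active edit prefix over the
    auto-detected bands, so undo/redo are exact.
    """
    if op in ("add", "remove"):
        if row is None:
            raise DomainError(f"{op} needs a row")
        edits = pattern.edits[:pattern.edit_cursor] + ((op, float(row)),)
        cursor = len(edits)
    elif op == "undo":
        if pattern.edit_cursor == 0:
            return pattern
        edits, cursor = pattern.edits, pattern.edit_cursor - 1
    elif op == "redo":
        if pattern.edit_cursor >= len(pattern.edits):
            return pattern
        edits, cursor = pattern.edits, pattern.edit_cursor + 1
    else:
        raise DomainError(f"unknown band edit op {op!r}")
    base = pattern.base_bands if pattern.base_bands is not None \
        else pattern.bands
    # replay: the visible state is a pure function of (base, edit prefix)
    bands = base
    for e in edits[:cursor]:
        bands = _apply_edit(bands, pattern.curve, pattern.lane_index, e)
    return dataclasses.replace(pattern, bands=bands, edits=edits,
                               edit_cursor=cursor, base_bands=base)


# ---------------------------------------------------------------------------
# molecular-weight assignment
# ---------------------------------------------------------------------------


def weigh_bands(pattern: BandPattern, model: MigrationModel,
                field: ShiftField | None, lane: Lane) -> BandPattern:
    """Attach shift-corrected rows and molecular weights to every band and
    to the densitometric curve samples.

    ``field=None`` means zero shift (single-gel, already-canonical case).
    """
    new_bands = []
    for b in pattern.bands:
        nrow = normalized_row(field, lane, b.row_px) if field is not None \
            else float(b.row_px)
        mw = float(model.predict(nrow))
        new_bands.append(dataclasses.replace(
            b, normalized_row_px=nrow, molecular_weight=mw))
    curve = pattern.curve
    rows = np.arange(len(curve.values), dtype=float) + curve.start
    if field is not None:
        nrows = np.array([normalized_row(field, lane, r) for r in rows])
    else:
        nrows = rows
    lo, hi = model.domain_px
    margin = 0.10 * (hi - lo)
    cw = np.full(len(rows), np.nan)
    ok = (nrows >= lo - margin) & (nrows <= hi + margin)
    if ok.any():
        cw[ok] = model._raw_predict(nrows[ok])
    return dataclasses.replace(pattern, bands=tuple(new_bands),
                               curve_weights=cw)
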