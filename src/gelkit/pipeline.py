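"""End-to-end gel analysis: image -> lanes -> normalization -> weighed bands.

This ties the step modules together the way an experiment is built: detect
lanes, extract densitometric curves, call bands, match the reference
marker in each reference lane, build the shift field, fit one migration
model on the canonical (shift-corrected) marker rows, and attach
molecular weights to every band and curve sample.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from . import band_detect, lane_detect, normalize
from .band_detect import BandPattern
from .errors import NormalizationError
from .lane_detect import Lane
from .normalize import MigrationModel, ReferenceMarker, ShiftField
from .preprocess import GelImage


@dataclasses.dataclass(frozen=True)
class GelAnalysis:
    """Everything an analyzed gel contributes to comparisons."""

    lanes: tuple
    patterns: tuple          # weighed BandPatterns, one per lane
    model: MigrationModel
    shift_field: ShiftField
    marker: ReferenceMarker


def analyze_gel(img: GelImage,
                marker: ReferenceMarker,
                reference_lanes: Sequence[int] | None = None,
                expected_lane_count: int | None = None,
                lanes: Sequence[Lane] | None = None,
                model_kind: str = "cubic_spline",
                global_threshold: float | None = None,
                min_band_separation_px: int = band_detect.DEFAULT_MIN_BAND_SEPARATION,
                smooth_sigma: float = band_detect.DEFAULT_SMOOTH_SIGMA,
                ) -> GelAnalysis:
    """Run the full pipeline on one gel image.

    ``reference_lanes`` are lane indices carrying the marker ladder
    (default: outermost lanes). Pass ``lanes`` to skip automatic lane
    detection (e.g. after manual edits). The migration model is fitted on
    canonical marker rows; ``model_kind`` defaults to the interpolating
    cubic spline, 'auto' selects by leave-one-out RMSE.
    """
    if lanes is None:
        lanes = lane_detect.detect_lanes(
            img, expected_lane_count=expected_lane_count)
    lanes = list(lanes)
    if not lanes:
        raise NormalizationError("no lanes to analyze")
    if reference_lanes is None:
        ref_idx = [i for i, l in enumerate(lanes) if l.is_reference]
        if not ref_idx:
            ref_idx = [0, len(lanes) - 1] if len(lanes) > 1 else [0]
    else:
        ref_idx = list(reference_lanes)
    lanes = [dataclasses.replace(l, is_reference=(i in ref_idx))
             for i, l in enumerate(lanes)]

    curves = [lane_detect.extract_lane_profile(img, l) for l in lanes]
    patterns = [
        band_detect.pattern_from_curve(
            c, lane_index=i, marker_name=marker.name,
            global_threshold=global_threshold,
            lane_threshold=lanes[i].band_threshold,
            min_separation_px=min_band_separation_px,
            smooth_sigma=smooth_sigma)
        for i, c in enumerate(curves)
    ]

    ref_matches = []
    for i in ref_idx:
        rows = sorted(float(b.row_px) for b in patterns[i].bands)
        pairs = normalize.match_marker_to_lane(marker, rows)
        ref_matches.append((lanes[i].center_column(), pairs))
    field = normalize.build_shift_field(ref_matches)

    # one migration model on the canonical coordinate (mean of ref lanes)
    canon_pairs = []
    label_mw = {b.label: b.molecular_weight for b in marker.bands}
    labels = None
    for (_, pairs) in ref_matches:
        lbls = {band.label for band, _ in pairs}
        labels = lbls if labels is None else labels & lbls
    for lbl in [b.label for b in marker.bands]:
        if lbl not in labels:
            continue
        rows_l = [dict((band.label, row) for band, row in pairs)[lbl]
                  for _, pairs in ref_matches]
        canon_pairs.append((float(np.mean(rows_l)), label_mw[lbl]))
    model = normalize.fit_migration_model(canon_pairs, kind=model_kind)

    # bands beyond the model domain (+10% margin) cannot be weighed; drop them
    lo, hi = model.domain_px
    margin = 0.10 * (hi - lo)
    weighed = []
    for i, p in enumerate(patterns):
        keep = tuple(
            b for b in p.bands
            if lo - margin
            <= normalize.normalized_row(field, lanes[i], b.row_px)
            <= hi + margin)
        p2 = dataclasses.replace(p, bands=keep)
        weighed.append(band_detect.weigh_bands(p2, model, field, lanes[i]))
    weighed = tuple(weighed)
    return GelAnalysis(lanes=tuple(lanes), patterns=weighed, model=model,
                       shift_field=field, marker=marker)
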