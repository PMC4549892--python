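"""Shared fixtures: synthetic gels and hand-built band patterns."""

from __future__ import annotations

import numpy as np
import pytest

import gelkit as gk
from gelkit import band_detect as bd
from gelkit import lane_detect as ld


@pytest.fixture(scope="session")
def default_gel():
    """One default synthetic gel with ground truth (8 lanes, marker in the
    outermost lanes)."""
    spec = gk.default_spec(seed=3)
    img, truth = gk.generate_gel(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def analyzed_gel(default_gel):
    spec, img, truth = default_gel
    analysis = gk.analyze_gel(img, spec.marker, reference_lanes=[0, 7])
    return spec, img, truth, analysis


def make_pattern(weights, lane_index=0, marker_name="m", curve=None):
    """Band pattern straight from a weight list (no image involved)."""
    bands = tuple(
        bd.Band(lane_index=lane_index, row_px=float(10 * i), height=0.5,
                normalized_row_px=float(10 * i), molecular_weight=float(w))
        for i, w in enumerate(sorted(weights, reverse=True)))
    if curve is None:
        curve = ld.ProjectionProfile(
            values=np.zeros(max(10 * len(weights) + 1, 4)), axis="rows")
    return bd.BandPattern(lane_index=lane_index, bands=bands, curve=curve,
                          marker_name=marker_name)


@pytest.fixture
def pattern_factory():
    return make_pattern
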