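"""Band matching, similarity coefficients and similarity matrices."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gelkit import lane_detect as ld
from gelkit import similarity as sim
from gelkit import synthgel
from gelkit.errors import ComparabilityError, DomainError

from conftest import make_pattern


def exhaustive_best_matching(wa, wb, spec):
    """Independent oracle: maximize cardinality (then minimize total weight
    difference) over ALL one-to-one admissible pairings, by bitmask DP."""
    na, nb = len(wa), len(wb)
    best = {0: (0, 0.0)}  # mask of used b-bands -> (count, cost)
    for i in range(na):
        new = dict(best)
        for mask, (cnt, cost) in best.items():
            for j in range(nb):
                if mask & (1 << j):
                    continue
                if not spec.admissible(wa[i], wb[j]):
                    continue
                m2 = mask | (1 << j)
                cand = (cnt + 1, cost + abs(wa[i] - wb[j]))
                if m2 not in new or (-cand[0], cand[1]) < \
                        (-new[m2][0], new[m2][1]):
                    new[m2] = cand
        best = new
    top = max(best.values(), key=lambda t: (t[0], -t[1]))
    return top


class TestMatchBands:
    def test_identical_patterns_fully_matched(self, pattern_factory):
        a = pattern_factory([100, 200, 300])
        b = pattern_factory([100, 200, 300], lane_index=1)
        pairs = sim.match_bands(a, b, sim.MatchSpec(tolerance=1,
                                                    mode="absolute"))
        assert pairs == [(0, 0), (1, 1), (2, 2)]

    def test_tolerance_boundary_is_inclusive(self, pattern_factory):
        a = pattern_factory([100.0])
        b = pattern_factory([104.0], lane_index=1)
        t3 = sim.MatchSpec(tolerance=3.0, mode="absolute")
        t4 = sim.MatchSpec(tolerance=4.0, mode="absolute")
        assert sim.match_bands(a, b, t3) == []
        assert len(sim.match_bands(a, b, t4)) == 1  # |delta| == t matches
        eps = sim.MatchSpec(tolerance=4.0 - 1e-9, mode="absolute")
        assert sim.match_bands(a, b, eps) == []

    def test_different_markers_rejected(self, pattern_factory):
        a = pattern_factory([100], marker_name="m1")
        b = pattern_factory([100], marker_name="m2")
        with pytest.raises(ComparabilityError):
            sim.match_bands(a, b)

    def test_optimal_matches_exhaustive_oracle(self):
        # broad tolerances up to >20% of the weight scale: many conflicts
        rng = np.random.default_rng(5)
        for _ in range(300):
            na, nb = rng.integers(0, 9), rng.integers(0, 9)
            wa = sorted(rng.uniform(50, 1000, na), reverse=True)
            wb = sorted(rng.uniform(50, 1000, nb), reverse=True)
            spec = sim.MatchSpec(tolerance=float(rng.uniform(5, 120)),
                                 mode="absolute", optimization="optimal")
            got = len(sim.match_bands(make_pattern(wa),
                                      make_pattern(wb, lane_index=1), spec))
            want, _ = exhaustive_best_matching(list(wa), list(wb), spec)
            assert got == want

    def test_greedy_rarely_suboptimal_at_default_tolerance(self, caplog):
        # under the default matching regime (1% relative tolerance) greedy
        # must agree with the optimal assignment on >= 99% of instances
        rng = np.random.default_rng(6)
        trials, mismatches = 400, 0
        for _ in range(trials):
            na, nb = rng.integers(1, 9), rng.integers(1, 9)
            a = make_pattern(rng.uniform(50, 1000, na))
            b = make_pattern(rng.uniform(50, 1000, nb), lane_index=1)
            greedy = len(sim.match_bands(a, b, sim.MatchSpec()))
            optimal = len(sim.match_bands(
                a, b, sim.MatchSpec(optimization="optimal")))
            assert greedy <= optimal
            if greedy != optimal:
                mismatches += 1
        assert mismatches / trials <= 0.01

    def test_symmetry_of_match_cardinality(self, pattern_factory):
        rng = np.random.default_rng(8)
        for _ in range(100):
            a = make_pattern(rng.uniform(50, 800, rng.integers(1, 7)))
            b = make_pattern(rng.uniform(50, 800, rng.integers(1, 7)), 1)
            spec = sim.MatchSpec(tolerance=30.0, mode="absolute")
            assert len(sim.match_bands(a, b, spec)) == \
                len(sim.match_bands(b, a, spec))


def _pattern_with_counts(na, nb, nab):
    """Two patterns with exactly nab shared (equal-weight) bands; unshared
    bands are far outside any reasonable tolerance."""
    shared = [100.0 + 10 * k for k in range(nab)]
    only_a = [5000.0 + 100 * k for k in range(na - nab)]
    only_b = [20000.0 + 100 * k for k in range(nb - nab)]
    return (make_pattern(shared + only_a),
            make_pattern(shared + only_b, lane_index=1))


class TestBandMetrics:
    def test_identical_patterns_score_100(self, pattern_factory):
        a = pattern_factory([100, 200, 300])
        b = pattern_factory([100, 200, 300], lane_index=1)
        for metric in sim.BAND_METRICS:
            assert sim.band_similarity(a, b, metric) == pytest.approx(100.0)

    def test_disjoint_patterns_score_0(self):
        a, b = _pattern_with_counts(4, 5, 0)
        spec = sim.MatchSpec(tolerance=1.0, mode="absolute")
        for metric in sim.BAND_METRICS:
            assert sim.band_similarity(a, b, metric, spec) == 0.0

    def test_empty_pattern_conventions(self, pattern_factory):
        e = make_pattern([])
        f = make_pattern([], lane_index=1)
        x = pattern_factory([100], lane_index=2)
        for metric in sim.BAND_METRICS:
            assert sim.band_similarity(e, f, metric) == 100.0
            assert sim.band_similarity(e, x, metric) == 0.0

    def test_closed_form_example(self):
        a, b = _pattern_with_counts(4, 6, 3)
        spec = sim.MatchSpec(tolerance=1.0, mode="absolute")
        assert sim.band_similarity(a, b, "dice", spec) == pytest.approx(60.0)
        assert sim.band_similarity(a, b, "jaccard", spec) == \
            pytest.approx(100 * 3 / 7)
        assert sim.band_similarity(a, b, "ochiai", spec) == \
            pytest.approx(100 * 3 / np.sqrt(24))

    def test_closed_forms_sweep(self):
        spec = sim.MatchSpec(tolerance=1.0, mode="absolute")
        for na in range(1, 8):
            for nb in range(1, 8):
                for nab in range(0, min(na, nb) + 1):
                    a, b = _pattern_with_counts(na, nb, nab)
                    got = {m: sim.band_similarity(a, b, m, spec)
                           for m in sim.BAND_METRICS}
                    assert got["dice"] == pytest.approx(
                        200 * nab / (na + nb))
                    assert got["jaccard"] == pytest.approx(
                        100 * nab / (na + nb - nab))
                    assert got["ochiai"] == pytest.approx(
                        100 * nab / np.sqrt(na * nb))
                    assert got["band_difference"] == pytest.approx(
                        100 * (1 - (na + nb - 2 * nab) / (na + nb)))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(1, 10), st.integers(1, 10), st.integers(0, 10))
    def test_dice_dominates_jaccard(self, na, nb, nab):
        nab = min(nab, na, nb)
        a, b = _pattern_with_counts(na, nb, nab)
        spec = sim.MatchSpec(tolerance=1.0, mode="absolute")
        assert sim.band_similarity(a, b, "dice", spec) >= \
            sim.band_similarity(a, b, "jaccard", spec) - 1e-9


def curve_pattern(values, lane_index=0):
    return make_pattern([], lane_index=lane_index,
                        curve=ld.ProjectionProfile(
                            values=np.asarray(values, float), axis="rows"))


class TestCurveMetrics:
    def test_identical_curves_score_100(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 1, 80)
        a, b = curve_pattern(v), curve_pattern(v, 1)
        for metric in sim.CURVE_METRICS:
            assert sim.curve_similarity(a, b, metric) == pytest.approx(100.0)

    def test_scale_invariance_after_unit_max(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0.1, 1, 60)
        a, b = curve_pattern(v), curve_pattern(0.5 * v, 1)
        assert sim.curve_similarity(a, b, "pearson") == pytest.approx(100.0)
        assert sim.curve_similarity(a, b, "cosine") == pytest.approx(100.0)

    def test_direct_formula_oracle(self):
        rng = np.random.default_rng(2)
        n = 64
        for _ in range(50):
            va, vb = rng.uniform(0, 1, 120), rng.uniform(0, 1, 120)
            a, b = curve_pattern(va), curve_pattern(vb, 1)
            # same length/start: resampling at resample_n points over the
            # common index range, then unit-max scaling
            grid = np.linspace(0, 119, n)
            x = np.interp(grid, np.arange(120), va)
            y = np.interp(grid, np.arange(120), vb)
            x, y = x / x.max(), y / y.max()
            r = np.corrcoef(x, y)[0, 1]
            assert sim.curve_similarity(a, b, "pearson", n) == \
                pytest.approx(100 * max(0, r), abs=1e-9)
            cos = x @ y / (np.linalg.norm(x) * np.linalg.norm(y))
            assert sim.curve_similarity(a, b, "cosine", n) == \
                pytest.approx(100 * cos, abs=1e-9)
            d2 = np.linalg.norm(x - y)
            assert sim.curve_similarity(a, b, "euclidean", n) == \
                pytest.approx(100 * (1 - d2 / np.sqrt(n)), abs=1e-9)
            d1 = np.abs(x - y).sum()
            assert sim.curve_similarity(a, b, "manhattan", n) == \
                pytest.approx(100 * (1 - d1 / n), abs=1e-9)

    def test_all_scores_in_range(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            a = curve_pattern(rng.uniform(0, 1, 90))
            b = curve_pattern(rng.uniform(0, 1, 90), 1)
            for metric in sim.CURVE_METRICS:
                s = sim.curve_similarity(a, b, metric)
                assert 0.0 <= s <= 100.0


class TestSimilarityMatrix:
    def test_two_identical_lanes(self, pattern_factory):
        a = pattern_factory([100, 200])
        b = pattern_factory([100, 200], lane_index=1)
        m = sim.similarity_matrix([a, b])
        assert np.array_equal(m.values, np.full((2, 2), 100.0))

    def test_symmetric_with_unit_diagonal(self, pattern_factory):
        rng = np.random.default_rng(4)
        pats = [make_pattern(rng.uniform(50, 900, 6), lane_index=i)
                for i in range(5)]
        m = sim.similarity_matrix(pats, "jaccard",
                                  sim.MatchSpec(tolerance=40, mode="absolute"))
        assert np.array_equal(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 100.0)
        assert m.values.min() >= 0 and m.values.max() <= 100

    def test_band_order_invariance(self):
        ws = [300.0, 120.0, 500.0, 80.0]
        a1 = make_pattern(ws)
        a2 = make_pattern(list(reversed(ws)))
        b = make_pattern([310.0, 118.0, 90.0], lane_index=1)
        spec = sim.MatchSpec(tolerance=15, mode="absolute")
        assert sim.band_similarity(a1, b, "dice", spec) == \
            sim.band_similarity(a2, b, "dice", spec)

    def test_comparability_error_names_lane_pair(self, pattern_factory):
        a = pattern_factory([100], marker_name="m1")
        b = pattern_factory([100], lane_index=1, marker_name="m2")
        with pytest.raises(ComparabilityError, match="lane1"):
            sim.similarity_matrix([a, b])

    def test_two_genotype_cohort_separates(self):
        rng = np.random.default_rng(12)
        gA = synthgel.sample_genotype(rng)
        gB = synthgel.sample_genotype(rng)
        pats = []
        for k in range(3):
            pats.append(make_pattern(
                synthgel.perturb_genotype(gA, 0.4, 0.0, 100 + k), len(pats)))
        for k in range(3):
            pats.append(make_pattern(
                synthgel.perturb_genotype(gB, 0.4, 0.0, 200 + k), len(pats)))
        m = sim.similarity_matrix(pats, "dice",
                                  sim.MatchSpec(tolerance=1.0,
                                                mode="relative"))
        within = [m.values[i, j] for i in range(3) for j in range(3) if i < j]
        within += [m.values[i, j] for i in range(3, 6) for j in range(3, 6)
                   if i < j]
        between = [m.values[i, j] for i in range(3) for j in range(3, 6)]
        assert min(within) > max(between)
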