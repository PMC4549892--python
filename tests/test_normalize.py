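"""Marker matching, migration-model fitting and shift-field normalization."""

import itertools

import numpy as np
import pytest

import gelkit as gk
from gelkit import normalize as nz
from gelkit import synthgel
from gelkit.errors import (DomainError, ExtrapolationError, FitError,
                           InsufficientMarkerError, NormalizationError)
from gelkit.lane_detect import Lane


def simple_marker(n=5, top=1000.0, bottom=100.0):
    w = np.geomspace(top, bottom, n)
    return nz.ReferenceMarker(
        name="m", units="kb",
        bands=tuple((f"b{i}", float(x)) for i, x in enumerate(w)))


class TestReferenceMarker:
    def test_requires_three_decreasing_bands(self):
        with pytest.raises(DomainError):
            nz.ReferenceMarker(name="x", units="kb",
                               bands=(("a", 10.0), ("b", 20.0), ("c", 5.0)))
        with pytest.raises(DomainError):
            nz.ReferenceMarker(name="x", units="kb",
                               bands=(("a", 10.0), ("b", 5.0)))

    def test_predefined_markers_load(self):
        for name in ("geometric_ladder", "lambda_ladder_pfg"):
            m = nz.load_predefined_marker(name)
            assert len(m.bands) >= 3
            assert np.all(np.diff(m.weights) < 0)

    def test_json_round_trip(self, tmp_path):
        m = simple_marker()
        f = tmp_path / "m.json"
        m.save(f)
        assert nz.ReferenceMarker.load(f) == m


class TestMarkerMatching:
    def test_equal_counts_pair_in_order(self):
        m = simple_marker(5)
        rows = [10.0, 40.0, 80.0, 130.0, 190.0]
        pairs = nz.match_marker_to_lane(m, rows)
        assert [r for _, r in pairs] == rows
        assert [b.label for b, _ in pairs] == [b.label for b in m.bands]

    def test_too_few_positions_rejected(self):
        with pytest.raises(InsufficientMarkerError):
            nz.match_marker_to_lane(simple_marker(5), [10.0, 50.0])

    def test_extra_noise_peak_dropped_like_exhaustive_oracle(self):
        m = simple_marker(5)
        # true rows from a log-linear law, one spurious peak mid-lane
        true_rows = sorted(300.0 - 90.0 * (np.log10(b.molecular_weight) - 2)
                           for b in m.bands)
        detected = sorted(true_rows + [147.0])
        pairs = nz.match_marker_to_lane(m, detected)
        got_rows = [r for _, r in pairs]
        # exhaustive oracle over all order-preserving 5-subsets
        logw = np.log10(m.weights)
        best, best_cost = None, np.inf
        for subset in itertools.combinations(range(6), 5):
            rows = np.array([detected[i] for i in subset])
            A = np.vstack([np.ones(5), rows]).T
            coef, *_ = np.linalg.lstsq(A, logw, rcond=None)
            ssr = float(np.sum((logw - A @ coef) ** 2))
            if ssr < best_cost:
                best, best_cost = [detected[i] for i in subset], ssr
        assert got_rows == best
        assert 147.0 not in got_rows

    def test_missing_rung_assigned_like_oracle(self):
        m = simple_marker(6)
        rows = sorted(300.0 - 90.0 * (np.log10(b.molecular_weight) - 2)
                      for b in m.bands)
        detected = rows[:2] + rows[3:]  # one rung not detected
        pairs = nz.match_marker_to_lane(m, detected)
        matched_labels = [b.label for b, _ in pairs]
        assert len(pairs) == 5
        assert "b2" not in matched_labels  # the dropped rung


class TestMigrationModelFit:
    def _pairs(self, n=8, a=6.0, b=-0.01):
        rows = np.linspace(50, 320, n)
        return [(float(r), float(10.0 ** (a + b * r))) for r in rows]

    def test_linear_exact_recovery(self):
        model = nz.fit_migration_model(self._pairs(), kind="linear")
        slope, intercept = model.params
        assert abs(slope - (-0.01)) < 1e-6 * 0.01
        assert abs(intercept - 6.0) < 1e-6 * 6.0
        assert model.fit_rmse < 1e-9

    def test_auto_picks_minimum_loo_rmse(self):
        pairs = self._pairs()
        winner = nz.fit_migration_model(pairs, kind="auto")
        # independent leave-one-out refit loop over every candidate kind
        arr = np.asarray(sorted(pairs))
        loos = {}
        for kind in nz.MODEL_KINDS:
            errs = []
            try:
                for i in range(len(arr)):
                    sub = [tuple(p) for j, p in enumerate(arr) if j != i]
                    m = nz.fit_migration_model(sub, kind=kind)
                    pred = m._raw_predict(np.array([arr[i, 0]]))[0]
                    errs.append(np.log10(pred) - np.log10(arr[i, 1]))
            except (FitError, DomainError):
                continue
            loos[kind] = float(np.sqrt(np.mean(np.square(errs))))
        assert loos[winner.model_kind] <= min(loos.values()) + 1e-12

    def test_non_monotone_kind_rejected_auto_falls_back(self):
        pairs = self._pairs(8)
        # perturb one weight upward hard enough to bend a cubic back up
        rows = [p[0] for p in pairs]
        ws = [p[1] for p in pairs]
        ws[6] = ws[5] * 1.8
        bad = list(zip(rows, ws))
        with pytest.raises(FitError):
            nz.fit_migration_model(bad, kind="cubic_spline")
        model = nz.fit_migration_model(bad, kind="auto")
        lo, hi = model.domain_px
        grid = np.linspace(lo, hi, 100)
        assert np.all(np.diff(model._raw_predict(grid)) < 0)

    @pytest.mark.parametrize("kind", ["linear", "quadratic", "cubic",
                                      "cubic_spline", "logarithmic",
                                      "gaussian", "rodbard"])
    def test_all_kinds_fit_loglinear_data_monotone(self, kind):
        model = nz.fit_migration_model(self._pairs(10), kind=kind)
        lo, hi = model.domain_px
        grid = np.linspace(lo, hi, 200)
        w = model._raw_predict(grid)
        assert np.all(w > 0) and np.all(np.diff(w) < 0)

    def test_predict_monotone_and_anchored(self):
        pairs = self._pairs()
        model = nz.fit_migration_model(pairs, kind="cubic_spline")
        for r, w in pairs:
            assert abs(model.predict(r) - w) <= max(1e-6, model.fit_rmse * w)
        assert model.predict(100.0) > model.predict(200.0)

    def test_extrapolation_margin(self):
        model = nz.fit_migration_model(self._pairs(), kind="linear")
        lo, hi = model.domain_px
        span = hi - lo
        model.predict(hi + 0.09 * span)  # inside the 10% margin
        with pytest.raises(ExtrapolationError):
            model.predict(hi + 0.2 * span)

    def test_weight_row_round_trip(self):
        model = nz.fit_migration_model(self._pairs(), kind="cubic_spline")
        lo, hi = model.domain_px
        for r in np.linspace(lo, hi, 17):
            w = model.predict(r)
            assert abs(model.row_for_weight(float(w)) - r) <= 0.5

    def test_serialization_round_trip_is_exact(self):
        for kind in ("linear", "cubic_spline", "rodbard"):
            m = nz.fit_migration_model(self._pairs(10), kind=kind)
            m2 = nz.MigrationModel.from_dict(m.to_dict())
            grid = np.linspace(*m.domain_px, 50)
            assert np.array_equal(m._raw_predict(grid), m2._raw_predict(grid))


def _matches(marker, rows):
    return list(zip(marker.bands, rows))


class TestShiftField:
    def test_single_reference_constant_across_x(self):
        m = simple_marker(4)
        rows = [20.0, 60.0, 120.0, 200.0]
        field = nz.build_shift_field([(50.0, _matches(m, rows))])
        assert field.shift(0.0, 80.0) == field.shift(300.0, 80.0)
        # single lane: canonical == its own rows, shift 0
        assert field.shift(10.0, 60.0) == 0.0

    def test_identical_references_give_zero_field(self):
        m = simple_marker(4)
        rows = [20.0, 60.0, 120.0, 200.0]
        field = nz.build_shift_field([(30.0, _matches(m, rows)),
                                      (200.0, _matches(m, rows))])
        for x in (30.0, 100.0, 200.0):
            for r in (20.0, 90.0, 200.0):
                assert field.shift(x, r) == 0.0

    def test_two_point_spline_is_linear_closed_form(self):
        m = simple_marker(4)
        rows_l = [20.0, 60.0, 120.0, 200.0]
        rows_r = [r + 4.0 for r in rows_l]
        field = nz.build_shift_field([(40.0, _matches(m, rows_l)),
                                      (240.0, _matches(m, rows_r))])
        # canonical = midpoint; left lane shift +2, right lane -2 at anchors
        assert field.shift(40.0, 60.0) == pytest.approx(2.0)
        assert field.shift(240.0, 64.0) == pytest.approx(-2.0)
        # a middle lane interpolates linearly in x
        assert field.shift(140.0, 62.0) == pytest.approx(0.0, abs=1e-9)
        assert field.shift(90.0, 61.0) == pytest.approx(1.0, abs=1e-9)

    def test_reference_anchor_maps_to_canonical(self):
        m = simple_marker(4)
        rows_l = [20.0, 60.0, 120.0, 200.0]
        rows_r = [r + 4.0 for r in rows_l]
        field = nz.build_shift_field([(40.0, _matches(m, rows_l)),
                                      (240.0, _matches(m, rows_r))])
        lane = Lane(centerline=((0.0, 40.0), (250.0, 40.0)), thickness_px=5)
        assert nz.normalized_row(field, lane, 60.0) == pytest.approx(62.0)

    def test_no_reference_rejected(self):
        with pytest.raises(NormalizationError):
            nz.build_shift_field([])

    def test_serialization_round_trip(self):
        m = simple_marker(4)
        field = nz.build_shift_field(
            [(40.0, _matches(m, [20.0, 60.0, 120.0, 200.0]))])
        f2 = nz.ShiftField.from_dict(field.to_dict())
        assert f2.shift(10.0, 77.0) == field.shift(10.0, 77.0)


@pytest.fixture(scope="module")
def two_gels():
    """Two gels of the same genotypes under different migration laws and
    smile warps; per-gel analyses plus ground truth."""
    marker = gk.load_predefined_marker("geometric_ladder")
    rng = np.random.default_rng(42)
    genos = [synthgel.sample_genotype(rng) for _ in range(5)]
    ladder = tuple(float(w) for w in marker.weights)
    lane_genos = (ladder,) + tuple(genos[:2]) + (ladder,) + \
        tuple(genos[2:]) + (ladder,)

    def build(a, b, smile, seed):
        spec = synthgel.GelSpec(
            marker=marker, genotypes=lane_genos, reference_lanes=(0, 3, 7),
            migration_a=a, migration_b=b, smile_amplitude_px=smile,
            seed=seed)
        img, truth = gk.generate_gel(spec)
        return gk.analyze_gel(img, marker, reference_lanes=[0, 3, 7]), truth

    return (build(716.7, -226.9, 6.0, 11), build(660.0, -205.0, -4.0, 22),
            lane_genos)


class TestNormalizationRecovery:
    """Molecular weights must be comparable across independently
    normalized gels."""

    def test_cross_gel_weights_agree_within_3_percent_median(self, two_gels):
        (ana_a, _), (ana_b, _), lane_genos = two_gels
        errs = []
        for li in (1, 2, 4, 5, 6):
            wa = sorted((b.molecular_weight for b in ana_a.patterns[li].bands),
                        reverse=True)
            wb = sorted((b.molecular_weight for b in ana_b.patterns[li].bands),
                        reverse=True)
            for x, y in zip(wa, wb):
                errs.append(abs(x - y) / ((x + y) / 2))
        assert np.median(errs) < 0.03

    def test_reference_marker_rows_map_to_canonical(self, two_gels):
        for ana, _ in [two_gels[0], two_gels[1]]:
            for i_ref in (0, 3, 7):
                rows = sorted(b.row_px for b in ana.patterns[i_ref].bands)
                pairs = gk.match_marker_to_lane(ana.marker, rows)
                for k, (_, row) in enumerate(pairs):
                    corr = nz.normalized_row(ana.shift_field,
                                             ana.lanes[i_ref], row)
                    assert abs(corr - ana.shift_field.canonical_rows[k]) <= 1.5

    def test_spline_weights_within_2_percent_median_of_truth(self, two_gels):
        (ana, truth), _, lane_genos = two_gels
        errs = []
        for li in (1, 2, 4, 5, 6):
            tr = sorted(truth.bands[li], key=lambda t: -t[1])
            det = sorted(ana.patterns[li].bands,
                         key=lambda b: -b.molecular_weight)
            for (row, tw), b in zip(tr, det):
                errs.append(abs(b.molecular_weight - tw) / tw)
        assert np.median(errs) < 0.02
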