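"""Ground-truth benchmarking of the pipeline on synthetic gels.

These helpers score a full analysis against the generator's ground truth
(lane recall, band-detection F1, molecular-weight accuracy), measure
cross-gel weight agreement after independent normalization, and run the
two-genotype clustering benchmark. They exist so the test suite and the
reproduction script share one measurement definition.
"""

from __future__ import annotations

import numpy as np

from . import clustering, similarity, synthgel
from .pipeline import GelAnalysis, analyze_gel
from .synthgel import GroundTruth


def lane_recall(truth: GroundTruth, lanes, tol_px: float = 2.0) -> float:
    """Fraction of ground-truth lanes with a detected centerline within
    ``tol_px`` columns (measured at the top row)."""
    found = 0
    for tc in truth.lane_centers[:, 0]:
        if any(abs(l.centerline[0][1] - tc) <= tol_px for l in lanes):
            found += 1
    return found / len(truth.lane_centers)


def band_scores(truth: GroundTruth, analysis: GelAnalysis,
                tol_px: float = 3.0,
                weight_rtol: float = 0.05) -> tuple[float, float]:
    """(detection F1, fraction of matched bands weighed within
    ``weight_rtol``) over all lanes, matching detected to true bands
    one-to-one within ``tol_px`` rows."""
    tp = fp = fn = 0
    w_good = w_tot = 0
    for li, pattern in enumerate(analysis.patterns):
        true_bands = list(truth.bands[li])
        used: set[int] = set()
        for b in pattern.bands:
            best, best_d = None, np.inf
            for k, (trow, _) in enumerate(true_bands):
                if k in used:
                    continue
                d = abs(trow - b.row_px)
                if d <= tol_px and d < best_d:
                    best, best_d = k, d
            if best is None:
                fp += 1
            else:
                used.add(best)
                tp += 1
                tw = true_bands[best][1]
                w_tot += 1
                if abs(b.molecular_weight - tw) / tw <= weight_rtol:
                    w_good += 1
        fn += len(true_bands) - len(used)
    f1 = 2 * tp / (2 * tp + fp + fn) if tp else 0.0
    return f1, (w_good / w_tot if w_tot else 0.0)


def end_to_end_trial(seed: int) -> dict:
    """Generate the default gel for one seed, run the full pipeline and
    score it against ground truth."""
    spec = synthgel.default_spec(seed=seed)
    img, truth = synthgel.generate_gel(spec)
    analysis = analyze_gel(img, spec.marker,
                           reference_lanes=list(spec.reference_lanes),
                           expected_lane_count=spec.n_lanes)
    lanes = analysis.lanes
    f1, w_ok = band_scores(truth, analysis)
    return {"lane_recall": lane_recall(truth, lanes),
            "band_f1": f1, "weights_within_5pct": w_ok}


def cross_gel_trial(seed: int) -> tuple[float, float]:
    """Run the cross-gel normalization benchmark: the same genotypes on two
    gels with different migration laws and opposite smile warps, three
    reference lanes each. Returns (median relative weight difference
    between gels, worst reference-lane anchor error in px)."""
    marker = synthgel.load_predefined_marker(synthgel.DEFAULT_MARKER_NAME)
    rng = np.random.default_rng(seed)
    genos = [synthgel.sample_genotype(rng) for _ in range(5)]
    ladder = tuple(float(w) for w in marker.weights)
    lane_genos = (ladder,) + tuple(genos[:2]) + (ladder,) + \
        tuple(genos[2:]) + (ladder,)

    def build(a, b, smile, sub_seed):
        spec = synthgel.GelSpec(
            marker=marker, genotypes=lane_genos, reference_lanes=(0, 3, 7),
            migration_a=a, migration_b=b, smile_amplitude_px=smile,
            seed=sub_seed)
        img, truth = synthgel.generate_gel(spec)
        return analyze_gel(img, marker, reference_lanes=[0, 3, 7])

    ana_a = build(716.7, -226.9, 6.0, seed * 2 + 1)
    ana_b = build(660.0, -205.0, -4.0, seed * 2 + 2)

    errs = []
    for li in (1, 2, 4, 5, 6):
        wa = sorted((b.molecular_weight for b in ana_a.patterns[li].bands),
                    reverse=True)
        wb = sorted((b.molecular_weight for b in ana_b.patterns[li].bands),
                    reverse=True)
        for x, y in zip(wa, wb):
            errs.append(abs(x - y) / ((x + y) / 2))

    worst_anchor = 0.0
    from . import normalize as nz
    for ana in (ana_a, ana_b):
        for i_ref in (0, 3, 7):
            rows = sorted(b.row_px for b in ana.patterns[i_ref].bands)
            pairs = nz.match_marker_to_lane(ana.marker, rows)
            for k, (_, row) in enumerate(pairs):
                corr = nz.normalized_row(ana.shift_field, ana.lanes[i_ref],
                                         row)
                worst_anchor = max(
                    worst_anchor,
                    abs(corr - ana.shift_field.canonical_rows[k]))
    return float(np.median(errs)), worst_anchor


def genotype_separation_trial(seed: int, jitter_percent: float = 0.4,
                              lanes_per_genotype: int = 3) -> bool:
    """Two random genotypes, three jittered replicates each; True when the
    UPGMA/Dice dendrogram's root bipartition separates the genotypes."""
    rng = np.random.default_rng(seed)
    g_a = synthgel.sample_genotype(rng)
    g_b = synthgel.sample_genotype(rng)
    from .band_detect import Band, BandPattern
    from .lane_detect import ProjectionProfile

    def pattern(ws, idx):
        bands = tuple(Band(lane_index=idx, row_px=float(i), height=0.5,
                           molecular_weight=float(w))
                      for i, w in enumerate(sorted(ws, reverse=True)))
        return BandPattern(lane_index=idx, bands=bands,
                           curve=ProjectionProfile(values=np.zeros(4),
                                                   axis="rows"),
                           marker_name="m")

    pats = []
    for k in range(lanes_per_genotype):
        pats.append(pattern(synthgel.perturb_genotype(
            g_a, jitter_percent, 0.0, seed * 101 + k), len(pats)))
    for k in range(lanes_per_genotype):
        pats.append(pattern(synthgel.perturb_genotype(
            g_b, jitter_percent, 0.0, seed * 101 + 50 + k), len(pats)))
    matrix = similarity.similarity_matrix(
        pats, "dice", similarity.MatchSpec(tolerance=1.0, mode="relative"))
    tree = clustering.cluster(matrix, "upgma")
    left = set(tree.root.left.members)
    group_a = set(range(lanes_per_genotype))
    n = 2 * lanes_per_genotype
    return left == group_a or left == set(range(n)) - group_a
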