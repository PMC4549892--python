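# Methods

This note documents the models and procedures gelkit implements, the
defaults that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmarks do and do not show.

## Conventions

Images are 2-D float rasters in [0, 1], 0-based and row-major, with row 0
at the wells and migration increasing downward. Bands are **bright on a
dark background** internally; light-background photographs are brought
into this convention with `invert`. Crop rectangles are half-open. Every
enhancement operation is a pure function of (pixels, parameters); a
`GelImage` keeps the as-loaded raster plus the ordered operation history,
and replaying the history reproduces the working pixels bit-for-bit. This
makes preprocessing non-destructive and auditable.

Filter boundaries use reflection (edge darkening would bias the profiles
of edge lanes). Rotation by non-quarter angles uses bilinear interpolation
on an expanded zero-filled canvas — the least destructive choice.
Automatic brightness/contrast is quantile saturation: the window is the
[f, 1−f] intensity quantile pair for a user fraction f. Rolling-ball
background removal runs with the ball's intensity semi-axis expressed in
8-bit gray levels (the classic convention); on a unit-scaled image a ball
with equal spatial and intensity scales would be nearly flat in intensity
and would swallow narrow bands.

## Lane segmentation

The vertical projection profile (column-wise mean intensity) has one local
peak per lane. Peaks are strict local maxima at or above a height
threshold, thinned greedily from the highest (ties: leftmost) so that no
two kept peaks are closer than a minimum separation — simple, exact and
deterministic. Defaults, chosen for typical PFGE gels with 8–16 lanes:
threshold = profile mean + 0.5·std; separation = width/(4 + expected
lanes) when the count is known, else 10 px; lane thickness = 0.8× the
median inter-peak gap (≥ 3 px). Lane centerlines are splines through
control points (degree min(3, n−1)), so detected lanes are straight and
user-curved lanes pass exactly through their control points. Curved-lane
densitometric curves are sampled nearest-pixel across the thickness
centered on the spline column; at PFGE resolution the sub-pixel error
this introduces is well under the band-position tolerance.

## Normalization

**Vertical interpolation.** Reference lanes carry a ladder of fragments of
known size. Detected ladder rows are matched to marker bands in migration
order; with extra (noise) or missing rungs, the assignment minimizes the
squared residuals of a provisional log-linear migration fit over all
order-preserving subsets. When the subset count C(n, k) is small (the
practical case — a 20-rung ladder with one or two spurious peaks) the
minimizer is found by exact enumeration; otherwise an iterated
predict–align–refit dynamic program is used. The exact variant defines
the objective; the DP approximates it at scale.

Migration models map row → molecular weight and must be strictly
decreasing. Polynomials (degree 1–3), the interpolating natural cubic
spline, the logarithmic model log10(mw) = a + b·log(row − c) and the
Gaussian model log10(mw) = a + b·exp(−((row−c)/d)²) are fitted in
log10-weight space, because migration distance is approximately linear in
log fragment size; the 4-parameter Rodbard sigmoid is fitted on raw
weights, per its standard use. Nonlinear fits use deterministic
multi-start least squares. Non-monotone or non-positive fits are
rejected. `auto` fits every feasible kind and picks the smallest
leave-one-out RMSE (computed in log10-weight units for comparability; ties
go to fewer parameters). Weights may be predicted up to 10% of the fitted
span beyond it; further extrapolation is an error. The default model for
pipeline runs is the interpolating spline: with ≥ 10 well-spread ladder
rungs it is exact at the knots and its interpolation error on synthetic
gels is far below the 5% weight tolerance used downstream.

**Horizontal interpolation.** For each marker band the canonical row is
the *mean* of its matched rows across reference lanes (order-independent,
unlike anchoring to a designated first lane). Each reference lane's shift
at that band is canonical − matched; shifts are interpolated linearly
across rows between anchors (clamped outside) and by spline across the
reference lanes' x-positions (constant for one reference lane, linear for
two, cubic for four or more; clamped beyond the outermost). The migration
model itself is fitted on the canonical rows, so shift correction and
weight assignment share one coordinate system. A consequence worth
knowing: with only two reference lanes the x-interpolation is linear, so
a *quadratic* smile across the gel is corrected exactly only at the
reference lanes; three reference lanes (outer + middle) capture it fully.
The cross-gel benchmark therefore runs with three reference lanes, which
is standard practice for wide gels.

## Band calling

The densitometric curve is lightly Gaussian-smoothed (σ = 1 px, σ = 0
disables) to suppress single-pixel noise peaks, then thresholded local
maxima are thinned with a 5 px minimum band separation. The height
threshold is global with per-lane overrides; the headless default is
curve median + 0.3·(max − median), an adaptive stand-in for the
user-tuned value interactive tools rely on. Because smoothing and
separation are fixed while only the threshold varies, band sets shrink
monotonically as the threshold rises (suppressing peaks are always at
least as tall as the peaks they suppress, so thinning cannot resurrect a
band). Manual picks live on a linear undo/redo history; the visible band
list is always a pure replay of the edit prefix over the immutable
auto-detected base, so undo is exact and survives serialization.

## Similarity

Band matching uses |mw₁ − mw₂| ≤ t, inclusive at the boundary. The
tolerance may be absolute (weight units) or relative; the default is
relative, 1% of the smaller band's weight, since migration tolerance
scales with fragment size. Matching is one-to-one: the default greedy
rule repeatedly takes the admissible pair with the smallest weight
difference (ties: smaller first weight, then second) — deterministic and
standard in fingerprint software; an optimal maximum-cardinality
minimum-cost assignment mode exists for verification and agrees with
greedy on ≥ 99% of random instances at the default tolerance.

Coefficients, as percentages: Dice 2n_AB/(n_A+n_B), Jaccard
n_AB/(n_A+n_B−n_AB), Ochiai n_AB/√(n_A·n_B), band difference
1 − (n_A+n_B−2n_AB)/(n_A+n_B). **Jeffrey's X is provisional**: no
authoritative formula was available, so it is implemented as
2n_AB/(n_A+n_B) rescaled to score identical patterns 100 (numerically
equal to Dice); treat it accordingly. Two empty patterns score 100
(identical absence), empty vs non-empty 0.

Curve similarity maps both densitometric curves to log-weight
coordinates (via the per-row weights attached during normalization, or
the raw row axis when unnormalized), resamples them linearly to a common
grid over the overlapping range, scales each to unit maximum, and
computes Pearson (negative r clipped to 0), cosine, or distance-derived
scores 100·(1 − d/d_max) with d_max the distance between curves
disagreeing by the full unit range at every sample (√n for Euclidean, n
for Manhattan) — a documented convention, since no canonical
distance-to-percent mapping exists.

## Clustering

Similarities flip to dissimilarities d = 100 − s (rank-preserving for
every linkage). Agglomeration merges the minimum-d pair; ties merge the
pair with the lexicographically smallest sorted member-index tuple, so
trees are reproducible. Updates are Lance–Williams: UPGMA (size-weighted
average), WPGMA ("mean"), single, complete, centroid (UPGMC) and Ward.
Ward and UPGMC are applied to d directly rather than to a
squared-Euclidean embedding — band-based similarities are not Euclidean,
so this is a convention, not an approximation; UPGMC may produce height
inversions, which are flagged on the tree. Newick export writes
ultrametric branch lengths (node height = d/2, leaves at 0); rendering is
deterministic (identical SVG bytes for identical trees).

Note that the pairwise ordering "UPGMA cophenetic ≤ complete cophenetic"
does *not* hold in general (the two linkages can produce different
topologies); single linkage, however, is the subdominant ultrametric and
is elementwise minimal, which the property tests assert.

## Synthetic gels and what the benchmarks show

The generator emulates PFGE gels: per lane, each fragment of weight w is
an anisotropic Gaussian ridge (σ_row = 2.2 px, σ_col = lane width/4)
centered at row a + b·log10(w), on a constant (optionally ramped)
background of 0.06, with i.i.d. Gaussian pixel noise. Defaults: 360×286
px, 8 lanes, 20-rung geometric ladder (1000→50 kb in constant log steps)
in the outermost lanes, random genotypes (10 bands, log-uniform in
60–900 kb, ≥ 0.035 apart in log10) between them, band amplitude 0.5 and
noise σ = 0.1 — i.e. band SNR 5, the hardest condition the pipeline is
specified for. Optional warps: a quadratic "smile" row offset across the
gel width and sinusoidal lane curvature. The seed fully determines image
and truth.

Benchmarks (tests and `scripts/acceptance.py`) measure, per seed: lane
recall within 2 px; band-calling F1 within 3 px; fraction of bands
weighed within 5% of truth; cross-gel median weight disagreement after
independent normalization of two gels with different migration laws and
opposite smiles; and the rate at which UPGMA/Dice dendrograms separate
two jittered genotypes. Problem sizes (50 end-to-end seeds, 3 cross-gel
replicates, 100 cohorts, 500 matcher pairs, 100 random 8×8 matrices) were
chosen so the whole battery runs in well under a minute of compute per
quantity while keeping Monte-Carlo noise far below the margins tested.

What these numbers do **not** show: the generator's bands are clean
Gaussian ridges with spatially white noise. Real gels have overlapping
and smeared bands, intensity-dependent noise, partial lane distortions
not captured by a global smile, and staining artifacts. Passing the
synthetic battery demonstrates the algorithms are implemented correctly
and are robust at SNR 5 under the modeled distortions — not that default
thresholds are optimal for any particular laboratory's images; the
per-gel and per-lane thresholds exist precisely because that tuning is
data-dependent.

## Degenerate inputs and edge policies

Flat images yield no lanes and no bands (empty results, not errors).
Auto-contrast on a constant image is the identity. A lane's local
contrast window and 1-D background-opening radius apply only to its own
densitometric curve. Markers require ≥ 3 strictly decreasing weights;
marker matching requires ≥ 3 detected rows. Bands outside the migration
model's domain (+10% margin) are dropped during weighing rather than
crashing the pipeline. Similarity requires both patterns to be
normalized with the same marker, by name. Study documents carry a format
version; mismatches fail loudly rather than guessing.
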