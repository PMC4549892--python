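"""Pairwise lane similarity: band-based and curve-based coefficients.

Band-based similarity first matches bands between two lanes. A band b1 may
match a band b2 only if their molecular weights agree within the tolerance
t, i.e. ``|mw_b1 - mw_b2| <= t`` (equivalently mw_b2 - t <= mw_b1 <= mw_b2
+ t); the tolerance may alternatively be expressed relative, as a percent
of the smaller band's weight, which is the default (1%) since migration
tolerance scales with fragment size. Matching is one-to-one: greedily by
smallest weight difference (the default), or as a maximum-cardinality
minimum-cost assignment for verification. With nA, nB bands and nAB
matches the coefficients are

    Dice            100 * 2*nAB / (nA + nB)
    Jaccard         100 * nAB / (nA + nB - nAB)
    Ochiai          100 * nAB / sqrt(nA * nB)
    Jeffrey's X     100 * 2*nAB / (nA + nB)   (provisional rescaling; see docs)
    band difference 100 * (1 - (nA + nB - 2*nAB) / (nA + nB))

Curve-based similarity compares the whole densitometric curves (Pearson,
cosine, Euclidean, Manhattan) after mapping both to molecular-weight
coordinates, resampling over the overlapping weight range and scaling each
curve to unit maximum.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .band_detect import BandPattern
from .errors import ComparabilityError, DomainError

BAND_METRICS = ("dice", "jaccard", "ochiai", "jeffreys_x", "band_difference")
CURVE_METRICS = ("pearson", "cosine", "euclidean", "manhattan")

_BIG = 1e15  # inadmissible-pair cost for the assignment solver


@dataclasses.dataclass(frozen=True)
class MatchSpec:
    """Band-matching parameters.

    ``tolerance`` is the t of the matching inequality, in molecular-weight
    units when ``mode='absolute'`` or as percent of the smaller band's
    weight when ``mode='relative'`` (the default, 1%).
    """

    tolerance: float = 1.0
    mode: str = "relative"
    optimization: str = "greedy"  # or 'optimal'

    def __post_init__(self):
        if self.tolerance <= 0:
            raise DomainError("tolerance must be > 0")
        if self.mode not in ("absolute", "relative"):
            raise DomainError("mode must be 'absolute' or 'relative'")
        if self.optimization not in ("greedy", "optimal"):
            raise DomainError("optimization must be 'greedy' or 'optimal'")

    def admissible(self, mw_a: float, mw_b: float) -> bool:
        t = self.tolerance if self.mode == "absolute" else \
            self.tolerance / 100.0 * min(mw_a, mw_b)
        return abs(mw_a - mw_b) <= t


def _pattern_weights(p: BandPattern) -> np.ndarray:
    w = p.weights
    if len(w) and np.any(~np.isfinite(w)):
        raise DomainError("pattern has unweighed bands; run weigh_bands first")
    return w


def _check_comparable(a: BandPattern, b: BandPattern) -> None:
    if a.marker_name != b.marker_name:
        raise ComparabilityError(
            f"patterns normalized with different markers: "
            f"{a.marker_name!r} vs {b.marker_name!r}")


def match_bands(a: BandPattern, b: BandPattern,
                spec: MatchSpec = MatchSpec()) -> list[tuple[int, int]]:
    """One-to-one band pairing (indices into a.bands, b.bands).

    greedy: repeatedly take the admissible pair with the smallest weight
    difference (ties: smaller mw_a, then smaller mw_b), removing both
    bands. optimal: maximum-cardinality minimum-cost assignment over the
    admissible pairs.
    """
    _check_comparable(a, b)
    wa, wb = _pattern_weights(a), _pattern_weights(b)
    if len(wa) == 0 or len(wb) == 0:
        return []
    if spec.optimization == "greedy":
        cands = [(abs(wa[i] - wb[j]), wa[i], wb[j], i, j)
                 for i in range(len(wa)) for j in range(len(wb))
                 if spec.admissible(wa[i], wb[j])]
        cands.sort()
        used_a, used_b, out = set(), set(), []
        for _, _, _, i, j in cands:
            if i not in used_a and j not in used_b:
                used_a.add(i)
                used_b.add(j)
                out.append((i, j))
        return sorted(out)
    # optimal: pad with the big cost so unmatched pairs are never profitable
    C = np.full((len(wa), len(wb)), _BIG)
    for i in range(len(wa)):
        for j in range(len(wb)):
            if spec.admissible(wa[i], wb[j]):
                C[i, j] = abs(wa[i] - wb[j])
    ri, cj = linear_sum_assignment(C)
    return sorted((int(i), int(j)) for i, j in zip(ri, cj)
                  if C[i, j] < _BIG / 2)


def band_similarity(a: BandPattern, b: BandPattern,
                    metric: str = "dice",
                    spec: MatchSpec = MatchSpec()) -> float:
    """Band-based similarity percent in [0, 100].

    Two empty patterns are identically absent (100); empty vs non-empty is
    0 for every metric.
    """
    if metric not in BAND_METRICS:
        raise DomainError(f"unknown band metric {metric!r}")
    _check_comparable(a, b)
    na, nb = len(a.bands), len(b.bands)
    if na == 0 and nb == 0:
        return 100.0
    if na == 0 or nb == 0:
        return 0.0
    nab = len(match_bands(a, b, spec))
    if metric == "dice":
        return 100.0 * 2.0 * nab / (na + nb)
    if metric == "jaccard":
        return 100.0 * nab / (na + nb - nab)
    if metric == "ochiai":
        return 100.0 * nab / np.sqrt(na * nb)
    if metric == "jeffreys_x":
        # provisional: nAB/(nA+nB) rescaled x2 so identical patterns score 100
        return 100.0 * 2.0 * nab / (na + nb)
    # band_difference: dissimilarity (nA + nB - 2 nAB)/(nA + nB), complemented
    return 100.0 * (1.0 - (na + nb - 2.0 * nab) / (na + nb))


# ---------------------------------------------------------------------------
# curve-based similarity
# ---------------------------------------------------------------------------


def _curve_axis(p: BandPattern) -> tuple[np.ndarray, np.ndarray]:
    """Curve samples on a log10-weight axis (descending weight = ascending
    migration). Falls back to the raw row axis when weights are absent."""
    v = p.curve.values
    if p.curve_weights is not None:
        w = np.asarray(p.curve_weights, dtype=float)
        ok = np.isfinite(w) & (w > 0)
        x = np.log10(w[ok])
        return x[::-1], v[ok][::-1]  # ascending log-weight
    x = np.arange(len(v), dtype=float) + p.curve.start
    return x, v


def curve_similarity(a: BandPattern, b: BandPattern, metric: str = "pearson",
                     resample_n: int = 256) -> float:
    """Curve-based similarity percent from the densitometric curves.

    Both curves are resampled linearly to ``resample_n`` points over their
    overlapping weight range and scaled to unit maximum. Pearson reports
    100*max(0, r); cosine 100*x.y/(|x||y|); Euclidean and Manhattan map
    distance d to 100*(1 - d/d_max) with d_max the distance between curves
    disagreeing by the full unit range at every sample (sqrt(n) and n).
    """
    if metric not in CURVE_METRICS:
        raise DomainError(f"unknown curve metric {metric!r}")
    if resample_n < 16:
        raise DomainError("resample_n must be >= 16")
    _check_comparable(a, b)
    xa, va = _curve_axis(a)
    xb, vb = _curve_axis(b)
    if (a.curve_weights is None) != (b.curve_weights is None):
        raise ComparabilityError("one curve has weights, the other does not")
    lo, hi = max(xa.min(), xb.min()), min(xa.max(), xb.max())
    if hi <= lo:
        raise ComparabilityError("curves have no overlapping weight range")
    grid = np.linspace(lo, hi, resample_n)
    x = np.interp(grid, xa, va)
    y = np.interp(grid, xb, vb)
    if x.max() > 0:
        x = x / x.max()
    if y.max() > 0:
        y = y / y.max()
    if metric == "pearson":
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            r = 1.0 if np.allclose(x, y) else 0.0
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        return 100.0 * max(0.0, r)
    if metric == "cosine":
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx == 0 or ny == 0:
            return 100.0 if nx == ny else 0.0
        return 100.0 * float(x @ y) / (nx * ny)
    if metric == "euclidean":
        d = float(np.linalg.norm(x - y))
        return 100.0 * (1.0 - d / np.sqrt(resample_n))
    d1 = float(np.abs(x - y).sum())
    return 100.0 * (1.0 - d1 / resample_n)


# ---------------------------------------------------------------------------
# similarity matrices
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric n x n lane-similarity percentages with method metadata."""

    lane_ids: tuple
    values: np.ndarray
    method: str
    params: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "lane_ids", tuple(self.lane_ids))
        n = len(self.lane_ids)
        if v.shape != (n, n):
            raise DomainError("matrix shape does not match lane_ids")
        if not np.allclose(v, v.T, atol=0):
            raise DomainError("similarity matrix must be symmetric")
        if v.min() < 0 or v.max() > 100:
            raise DomainError("similarities must lie in [0, 100]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.lane_ids,
                            columns=self.lane_ids)

    def to_csv(self, path) -> None:
        df = self.to_dataframe().round(2)
        df.to_csv(path, float_format="%.2f")


def similarity_matrix(patterns: Sequence[BandPattern],
                      method: str = "dice",
                      spec: MatchSpec = MatchSpec(),
                      lane_ids: Sequence[str] | None = None,
                      resample_n: int = 256) -> SimilarityMatrix:
    """All-pairs similarity for a list of band patterns (default metric
    Dice). Every pair is computed once and mirrored; the diagonal is 100."""
    n = len(patterns)
    if n < 2:
        raise DomainError("need >= 2 lanes")
    if lane_ids is None:
        lane_ids = [f"lane{p.lane_index}" for p in patterns]
    V = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                if method in BAND_METRICS:
                    s = band_similarity(patterns[i], patterns[j], method, spec)
                elif method in CURVE_METRICS:
                    s = curve_similarity(patterns[i], patterns[j], method,
                                         resample_n)
                else:
                    raise DomainError(f"unknown method {method!r}")
            except ComparabilityError as exc:
                raise ComparabilityError(
                    f"lanes {lane_ids[i]!r} and {lane_ids[j]!r}: {exc}"
                ) from exc
            V[i, j] = V[j, i] = s
    params: dict = {"resample_n": resample_n} if method in CURVE_METRICS else {
        "tolerance": spec.tolerance, "mode": spec.mode,
        "optimization": spec.optimization}
    return SimilarityMatrix(lane_ids=tuple(lane_ids), values=V,
                            method=method, params=params)
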