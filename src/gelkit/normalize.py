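"""Migration-model fitting and cross-lane normalization.

Band positions in a gel depend on run conditions, so raw pixel rows are not
comparable across lanes or gels. Normalization uses reference lanes loaded
with a ladder of fragments of known molecular weight:

* **vertical interpolation** — within each reference lane, the matched
  (pixel row, molecular weight) pairs are fitted by a monotone *migration
  model* mapping migration distance to molecular weight (electrophoretic
  migration is roughly linear in log10 of fragment size, so polynomial,
  spline and gaussian models are fitted in log-weight space; the Rodbard
  sigmoid is fitted on raw weights, as is conventional);
* **horizontal interpolation** — between reference lanes, a per-row column
  shift is interpolated (cubic-spline across lane x-positions, linear across
  rows between marker anchors) so every lane's rows can be mapped into a
  canonical coordinate before weights are assigned.

The canonical coordinate is the mean of the reference lanes' marker rows,
making normalization independent of lane order.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline, make_interp_spline
from scipy.optimize import brentq, least_squares

from .errors import (DomainError, ExtrapolationError, FitError,
                     InsufficientMarkerError, NormalizationError)

MODEL_KINDS = ("linear", "quadratic", "cubic", "cubic_spline",
               "logarithmic", "gaussian", "rodbard")

#: free parameters per model kind (spline counted by its knots at fit time)
_N_PARAMS = {"linear": 2, "quadratic": 3, "cubic": 4, "logarithmic": 3,
             "gaussian": 4, "rodbard": 4}

_DOMAIN_MARGIN = 0.10  # fractional extrapolation allowance beyond the fit span


# ---------------------------------------------------------------------------
# reference markers
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class MarkerBand:
    label: str
    molecular_weight: float


@dataclasses.dataclass(frozen=True)
class ReferenceMarker:
    """Ordered ladder of known fragments, listed in migration order (least
    migrated first), so molecular weights are strictly decreasing."""

    name: str
    units: str
    bands: tuple

    def __post_init__(self):
        bands = tuple(b if isinstance(b, MarkerBand) else MarkerBand(*b)
                      for b in self.bands)
        object.__setattr__(self, "bands", bands)
        if len(bands) < 3:
            raise DomainError("a reference marker needs >= 3 bands")
        mw = [b.molecular_weight for b in bands]
        if any(w <= 0 for w in mw):
            raise DomainError("molecular weights must be positive")
        if any(y >= x for x, y in zip(mw, mw[1:])):
            raise DomainError("marker weights must be strictly decreasing")

    @property
    def weights(self) -> np.ndarray:
        return np.array([b.molecular_weight for b in self.bands])

    def to_dict(self) -> dict:
        return {"name": self.name, "units": self.units,
                "bands": [{"label": b.label, "mw": b.molecular_weight}
                          for b in self.bands]}

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceMarker":
        return cls(name=d["name"], units=d["units"],
                   bands=tuple(MarkerBand(b["label"], float(b["mw"]))
                               for b in d["bands"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceMarker":
        return cls.from_dict(json.loads(Path(path).read_text()))


def load_predefined_marker(name: str) -> ReferenceMarker:
    """Load a marker shipped as package data (e.g. 'lambda_ladder_pfg')."""
    p = Path(__file__).parent / "data" / "markers" / f"{name}.json"
    if not p.exists():
        avail = sorted(q.stem for q in p.parent.glob("*.json"))
        raise DomainError(f"no predefined marker {name!r}; available: {avail}")
    return ReferenceMarker.load(p)


# ---------------------------------------------------------------------------
# marker-to-lane matching
# ---------------------------------------------------------------------------


def _loglinear_ssr(rows: np.ndarray, logw: np.ndarray) -> float:
    """Residual sum of squares of a log-linear migration fit."""
    A = np.vstack([np.ones_like(rows), rows]).T
    coef, *_ = np.linalg.lstsq(A, logw, rcond=None)
    r = logw - A @ coef
    return float(r @ r)


def match_marker_to_lane(marker: ReferenceMarker,
                         detected_positions: Sequence[float],
                         max_enumeration: int = 20000
                         ) -> list[tuple[MarkerBand, float]]:
    """Pair marker bands with detected band rows, in migration order.

    Equal counts pair 1:1 in order. Otherwise the |marker| best-supported
    positions are chosen by an order-preserving assignment minimizing the
    squared residuals of a provisional log-linear migration fit: exact
    subset enumeration when the number of order-preserving subsets is small,
    else an iterated predict-align-refit dynamic program.
    """
    pos = np.asarray(detected_positions, dtype=np.float64)
    if np.any(np.diff(pos) < 0):
        raise DomainError("detected_positions must be sorted ascending")
    if len(pos) < 3:
        raise InsufficientMarkerError(
            f"need >= 3 detected positions, got {len(pos)}")
    bands = marker.bands
    logw = np.log10(marker.weights)
    m, n = len(bands), len(pos)
    if n == m:
        return list(zip(bands, pos.tolist()))
    if n < m:
        # fewer detected bands than ladder rungs: choose which rungs they are
        k = n
        from math import comb
        if comb(m, k) <= max_enumeration:
            best, best_cost = None, np.inf
            for subset in itertools.combinations(range(m), k):
                cost = _loglinear_ssr(pos, logw[list(subset)])
                if cost < best_cost - 1e-15:
                    best, best_cost = subset, cost
            return [(bands[j], float(pos[i])) for i, j in enumerate(best)]
        sel = _dp_align(logw, pos)
        return [(bands[j], float(pos[i])) for j, i in sel]
    # more detected positions than marker bands: drop spurious peaks
    from math import comb
    if comb(n, m) <= max_enumeration:
        best, best_cost = None, np.inf
        for subset in itertools.combinations(range(n), m):
            cost = _loglinear_ssr(pos[list(subset)], logw)
            if cost < best_cost - 1e-15:
                best, best_cost = subset, cost
        return [(bands[j], float(pos[i])) for j, i in enumerate(best)]
    sel = _dp_align(logw, pos)
    return [(bands[j], float(pos[i])) for j, i in sel]


def _op_min_assign(C: np.ndarray) -> list[tuple[int, int]]:
    """Order-preserving min-cost injective assignment of every row of the
    cost matrix C (small side) to a distinct column (large side)."""
    s, l = C.shape
    INF = np.inf
    cost = np.full((s + 1, l + 1), INF)
    cost[0, :] = 0.0
    choice = np.zeros((s + 1, l + 1), dtype=int)
    for u in range(1, s + 1):
        for v in range(u, l + 1):
            take = cost[u - 1, v - 1] + C[u - 1, v - 1]
            skip = cost[u, v - 1] if v > u else INF
            if skip < take:
                cost[u, v], choice[u, v] = skip, 0
            else:
                cost[u, v], choice[u, v] = take, 1
    pairs = []
    u, v = s, l
    while u > 0:
        if choice[u, v]:
            pairs.append((u - 1, v - 1))
            u, v = u - 1, v - 1
        else:
            v -= 1
    pairs.reverse()
    return pairs


def _dp_align(logw: np.ndarray, pos: np.ndarray,
              n_iter: int = 3) -> list[tuple[int, int]]:
    """Iterated predict-align-refit assignment of marker bands to detected
    positions: fit log-linear on the current pairing, predict a target row
    per marker band, realign by minimal squared-distance order-preserving
    DP, repeat. Returns (band index, position index) pairs covering the
    smaller side."""
    m, n = len(logw), len(pos)
    # initial target rows: marker bands evenly spread over the detected span
    r_hat = np.interp(np.linspace(0, 1, m), np.linspace(0, 1, n), pos)
    pairs: list[tuple[int, int]] = []
    for _ in range(n_iter):
        if n >= m:
            C = (pos[None, :] - r_hat[:, None]) ** 2  # (m, n)
            pairs = _op_min_assign(C)
        else:
            C = (pos[:, None] - r_hat[None, :]) ** 2  # (n, m)
            pairs = [(j, i) for i, j in _op_min_assign(C)]
        jj = np.array([p[0] for p in pairs])
        ii = np.array([p[1] for p in pairs])
        A = np.vstack([np.ones(len(pairs)), pos[ii]]).T
        coef, *_ = np.linalg.lstsq(A, logw[jj], rcond=None)
        if abs(coef[1]) < 1e-12:
            break
        r_hat = (logw - coef[0]) / coef[1]
    return pairs


# ---------------------------------------------------------------------------
# migration models
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class MigrationModel:
    """Fitted monotone mapping pixel row -> molecular weight.

    ``params`` is kind-specific: polynomial coefficients (highest power
    first) on log10(weight); spline knot rows + log10(weight) values;
    (a, b, c) for the logarithmic model log10(w) = a + b*log(row - c);
    (a, b, c, d) for the gaussian model log10(w) = a + b*exp(-((row-c)/d)^2)
    and for the Rodbard sigmoid w = d + (a - d)/(1 + (row/c)^b).
    """

    model_kind: str
    params: tuple
    fit_rmse: float
    domain_px: tuple
    reference_lane_index: int = -1

    def _raw_predict(self, rows: np.ndarray) -> np.ndarray:
        k, p = self.model_kind, self.params
        if k in ("linear", "quadratic", "cubic"):
            return 10.0 ** np.polyval(np.asarray(p), rows)
        if k == "cubic_spline":
            knots_r, knots_lw = np.asarray(p[0]), np.asarray(p[1])
            spl = CubicSpline(knots_r, knots_lw, bc_type="natural")
            return 10.0 ** spl(rows)
        if k == "logarithmic":
            a, b, c = p
            return 10.0 ** (a + b * np.log(rows - c))
        if k == "gaussian":
            a, b, c, d = p
            return 10.0 ** (a + b * np.exp(-(((rows - c) / d) ** 2)))
        if k == "rodbard":
            a, b, c, d = p
            return d + (a - d) / (1.0 + (rows / c) ** b)
        raise DomainError(f"unknown model kind {self.model_kind!r}")

    def predict(self, rows) -> np.ndarray | float:
        """Molecular weight at the given row(s); rows may extend at most 10%
        of the fitted span beyond it, further raises ExtrapolationError."""
        r = np.atleast_1d(np.asarray(rows, dtype=np.float64))
        lo, hi = self.domain_px
        margin = _DOMAIN_MARGIN * (hi - lo)
        if np.any(r < lo - margin) or np.any(r > hi + margin):
            raise ExtrapolationError(
                f"row(s) outside model domain [{lo}, {hi}] + 10% margin")
        out = self._raw_predict(r)
        return out if np.ndim(rows) else float(out[0])

    def row_for_weight(self, weight: float) -> float:
        """Numerically invert the monotone model (bisection over the domain)."""
        lo, hi = self.domain_px
        f = lambda r: self._raw_predict(np.array([r]))[0] - weight
        flo, fhi = f(lo), f(hi)
        if flo * fhi > 0:
            raise DomainError(f"weight {weight} outside model range")
        return float(brentq(f, lo, hi, xtol=1e-9))

    def to_dict(self) -> dict:
        p = self.params
        if self.model_kind == "cubic_spline":
            p = [list(map(float, p[0])), list(map(float, p[1]))]
        else:
            p = list(map(float, p))
        return {"model_kind": self.model_kind, "params": p,
                "fit_rmse": self.fit_rmse, "domain_px": list(self.domain_px),
                "reference_lane_index": self.reference_lane_index}

    @classmethod
    def from_dict(cls, d: dict) -> "MigrationModel":
        p = d["params"]
        if d["model_kind"] == "cubic_spline":
            p = (tuple(p[0]), tuple(p[1]))
        else:
            p = tuple(p)
        return cls(model_kind=d["model_kind"], params=p,
                   fit_rmse=float(d["fit_rmse"]),
                   domain_px=tuple(d["domain_px"]),
                   reference_lane_index=int(d["reference_lane_index"]))


def _is_monotone_decreasing(model: MigrationModel, n_grid: int = 256) -> bool:
    lo, hi = model.domain_px
    grid = np.linspace(lo, hi, n_grid)
    w = model._raw_predict(grid)
    return bool(np.all(np.isfinite(w)) and np.all(w > 0)
                and np.all(np.diff(w) < 0))


def _fit_one(rows: np.ndarray, logw: np.ndarray, kind: str,
             reference_lane_index: int) -> MigrationModel:
    """Least-squares fit of a single model kind; raises FitError on failure."""
    domain = (float(rows.min()), float(rows.max()))
    w = 10.0 ** logw

    def _model(kind, params, rmse):
        return MigrationModel(model_kind=kind, params=params,
                              fit_rmse=float(rmse), domain_px=domain,
                              reference_lane_index=reference_lane_index)

    if kind in ("linear", "quadratic", "cubic"):
        deg = {"linear": 1, "quadratic": 2, "cubic": 3}[kind]
        if len(rows) < deg + 2:
            raise FitError(f"{kind}: need >= {deg + 2} pairs")
        coef = np.polyfit(rows, logw, deg)
        resid = logw - np.polyval(coef, rows)
        return _model(kind, tuple(coef), np.sqrt(np.mean(resid ** 2)))

    if kind == "cubic_spline":
        # interpolating natural spline; exact at the knots
        if len(rows) < 3:
            raise FitError("cubic_spline: need >= 3 pairs")
        return _model(kind, (tuple(rows), tuple(logw)), 0.0)

    span = rows.max() - rows.min()

    if kind == "logarithmic":
        if len(rows) < 4:
            raise FitError("logarithmic: need >= 4 pairs")
        best = None
        for f in (0.05, 0.2, 0.5, 1.0, 3.0):
            c0 = rows.min() - f * span

            def resid(p):
                a, b, c = p
                c = min(c, rows.min() - 1e-6)
                return a + b * np.log(rows - c) - logw

            x = np.log(rows - c0)
            A = np.vstack([np.ones_like(x), x]).T
            ab, *_ = np.linalg.lstsq(A, logw, rcond=None)
            try:
                sol = least_squares(resid, x0=[ab[0], ab[1], c0],
                                    bounds=([-np.inf, -np.inf, -np.inf],
                                            [np.inf, np.inf, rows.min() - 1e-6]),
                                    method="trf", max_nfev=2000)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise FitError("logarithmic fit did not converge")
        rmse = np.sqrt(np.mean(best.fun ** 2))
        return _model(kind, tuple(best.x), rmse)

    if kind == "gaussian":
        if len(rows) < 5:
            raise FitError("gaussian: need >= 5 pairs")
        best = None
        for c0 in (rows.min() - span, rows.min(), rows.mean() - span):
            for d0 in (span, 2 * span, 4 * span):

                def resid(p):
                    a, b, c, d = p
                    return a + b * np.exp(-(((rows - c) / d) ** 2)) - logw

                g = np.exp(-(((rows - c0) / d0) ** 2))
                A = np.vstack([np.ones_like(g), g]).T
                ab, *_ = np.linalg.lstsq(A, logw, rcond=None)
                try:
                    sol = least_squares(resid, x0=[ab[0], ab[1], c0, d0],
                                        method="lm", max_nfev=2000)
                except Exception:
                    continue
                if abs(sol.x[3]) < 1e-9:
                    continue
                if best is None or sol.cost < best.cost:
                    best = sol
        if best is None:
            raise FitError("gaussian fit did not converge")
        rmse = np.sqrt(np.mean(best.fun ** 2))
        return _model(kind, tuple(best.x), rmse)

    if kind == "rodbard":
        if len(rows) < 5:
            raise FitError("rodbard: need >= 5 pairs")
        best = None
        wmax, wmin = w.max(), w.min()
        for b0 in (1.0, 2.0, 4.0):
            for c0 in (np.median(rows), rows.mean()):

                def resid(p):
                    a, b, c, d = p
                    with np.errstate(over="ignore"):
                        return d + (a - d) / (1.0 + (rows / c) ** b) - w

                try:
                    sol = least_squares(
                        resid, x0=[wmax * 1.05, b0, c0, wmin * 0.5],
                        bounds=([0, 1e-6, 1e-6, 0],
                                [np.inf, np.inf, np.inf, np.inf]),
                        method="trf", max_nfev=4000)
                except Exception:
                    continue
                if best is None or sol.cost < best.cost:
                    best = sol
        if best is None:
            raise FitError("rodbard fit did not converge")
        pred = best.x[3] + (best.x[0] - best.x[3]) / \
            (1.0 + (rows / best.x[2]) ** best.x[1])
        if np.any(pred <= 0):
            raise FitError("rodbard fit predicts non-positive weights")
        rmse = np.sqrt(np.mean((np.log10(pred) - logw) ** 2))
        return _model(kind, tuple(best.x), rmse)

    raise DomainError(f"unknown model kind {kind!r}")


def _loo_rmse(rows: np.ndarray, logw: np.ndarray, kind: str) -> float:
    """Leave-one-out RMSE (in log10-weight units) by full refits."""
    errs = []
    for i in range(len(rows)):
        mask = np.ones(len(rows), dtype=bool)
        mask[i] = False
        try:
            m = _fit_one(rows[mask], logw[mask], kind, -1)
        except FitError:
            return np.inf
        if not _is_monotone_decreasing(m):
            return np.inf
        # held-out row may sit at the edge of the reduced domain
        pred = m._raw_predict(np.array([rows[i]]))[0]
        if not np.isfinite(pred) or pred <= 0:
            return np.inf
        errs.append(np.log10(pred) - logw[i])
    return float(np.sqrt(np.mean(np.square(errs))))


def fit_migration_model(pairs: Sequence[tuple[float, float]],
                        kind: str = "auto",
                        reference_lane_index: int = -1) -> MigrationModel:
    """Fit a monotone migration model to (pixel row, molecular weight) pairs.

    ``kind='auto'`` fits every feasible kind, rejects non-monotone fits and
    picks the lowest leave-one-out RMSE (ties broken toward fewer
    parameters). A single requested kind is fitted directly and rejected if
    non-monotone.
    """
    arr = np.asarray(sorted(pairs), dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise DomainError("need >= 2 (row, weight) pairs")
    rows, w = arr[:, 0], arr[:, 1]
    if np.any(w <= 0):
        raise DomainError("molecular weights must be positive")
    if len(np.unique(rows)) != len(rows):
        raise DomainError("duplicate rows in fit pairs")
    logw = np.log10(w)

    if kind != "auto":
        model = _fit_one(rows, logw, kind, reference_lane_index)
        if not _is_monotone_decreasing(model):
            raise FitError(
                f"{kind} fit is not strictly decreasing over its domain")
        return model

    candidates = []
    diagnostics = {}
    for k in MODEL_KINDS:
        try:
            model = _fit_one(rows, logw, k, reference_lane_index)
        except FitError as exc:
            diagnostics[k] = str(exc)
            continue
        if not _is_monotone_decreasing(model):
            diagnostics[k] = "non-monotone"
            continue
        loo = _loo_rmse(rows, logw, k)
        if not np.isfinite(loo):
            diagnostics[k] = "leave-one-out refit failed"
            continue
        n_par = _N_PARAMS.get(k, len(rows))
        candidates.append((loo, n_par, k, model))
    if not candidates:
        raise FitError(f"no migration model could be fitted: {diagnostics}")
    candidates.sort(key=lambda t: (t[0], t[1], MODEL_KINDS.index(t[2])))
    return candidates[0][3]


def predict_weight(model: MigrationModel, row) -> float | np.ndarray:
    """Molecular weight at a (normalized) pixel row. Thin wrapper over
    :meth:`MigrationModel.predict`."""
    return model.predict(row)


# ---------------------------------------------------------------------------
# shift field (horizontal interpolation)
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ShiftField:
    """Row correction as a smooth function of lane x-position and row.

    For each marker band the canonical row is the mean of its matched rows
    across reference lanes; each reference lane's shift at that band is
    (canonical - matched). Shifts are interpolated linearly across rows
    between marker anchors (clamped outside) and by cubic spline across the
    reference lanes' x-positions (constant for a single reference lane,
    clamped beyond the outermost reference lanes).
    """

    ref_x: np.ndarray          # (k,) reference-lane center columns, ascending
    marker_rows: np.ndarray    # (k, m) matched rows per reference lane
    canonical_rows: np.ndarray  # (m,)

    def __post_init__(self):
        object.__setattr__(self, "ref_x", np.asarray(self.ref_x, float))
        object.__setattr__(self, "marker_rows",
                           np.asarray(self.marker_rows, float))
        object.__setattr__(self, "canonical_rows",
                           np.asarray(self.canonical_rows, float))

    def shift(self, x: float, row: float) -> float:
        """Row shift at lane x-position ``x`` and image row ``row``."""
        per_lane = np.array([
            np.interp(row, self.marker_rows[j],
                      self.canonical_rows - self.marker_rows[j])
            for j in range(len(self.ref_x))
        ])
        if len(self.ref_x) == 1:
            return float(per_lane[0])
        k = min(3, len(self.ref_x) - 1)
        spl = make_interp_spline(self.ref_x, per_lane, k=k)
        xq = float(np.clip(x, self.ref_x[0], self.ref_x[-1]))
        return float(spl(xq))

    def to_dict(self) -> dict:
        return {"ref_x": self.ref_x.tolist(),
                "marker_rows": self.marker_rows.tolist(),
                "canonical_rows": self.canonical_rows.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ShiftField":
        return cls(ref_x=d["ref_x"], marker_rows=d["marker_rows"],
                   canonical_rows=d["canonical_rows"])


def build_shift_field(
    reference_matches: Sequence[tuple[float, Sequence[tuple[MarkerBand, float]]]],
) -> ShiftField:
    """Build the shift field from reference-lane marker matches.

    ``reference_matches`` is a list of (lane x-position, matched pairs) — one
    entry per reference lane, pairs as returned by
    :func:`match_marker_to_lane`. Only marker bands matched in *every*
    reference lane anchor the field (>= 3 required).
    """
    if not reference_matches:
        raise NormalizationError("at least one reference lane is required")
    label_rows = []
    for x, pairs in reference_matches:
        label_rows.append({band.label: row for band, row in pairs})
    common = [lbl for lbl in label_rows[0]
              if all(lbl in lr for lr in label_rows)]
    if len(common) < 3:
        raise NormalizationError(
            "fewer than 3 marker bands matched in every reference lane")
    order = np.argsort([label_rows[0][lbl] for lbl in common])
    common = [common[i] for i in order]
    xs = np.array([x for x, _ in reference_matches], dtype=float)
    rows = np.array([[lr[lbl] for lbl in common] for lr in label_rows])
    sort = np.argsort(xs)
    xs, rows = xs[sort], rows[sort]
    if len(xs) > 1 and np.any(np.diff(xs) <= 0):
        raise NormalizationError("reference lanes must have distinct x-positions")
    canonical = rows.mean(axis=0)
    return ShiftField(ref_x=xs, marker_rows=rows, canonical_rows=canonical)


def normalized_row(field: ShiftField, lane, row: float) -> float:
    """Shift-corrected row for a pixel row on the given lane."""
    x = lane.column_at(row) if hasattr(lane, "column_at") else float(lane)
    return float(row) + field.shift(float(x), float(row))
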