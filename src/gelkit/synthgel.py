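"""Synthetic gel images with full ground truth.

The generator emulates the visual character of PFGE gels: parallel
(optionally curved) lanes of anisotropic-Gaussian bands on a noisy,
non-uniform background. Band rows come from a strictly monotone migration
law ``row = a + b * log10(mw)`` plus an optional per-lane "smile" offset
(lanes near the gel edge migrate less), so every band's true row and
molecular weight are known exactly. The seed fully determines the output:
the same spec and seed give a bit-identical image and truth.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np

from .errors import DomainError
from .normalize import ReferenceMarker, load_predefined_marker
from .preprocess import GelImage

DEFAULT_MARKER_NAME = "geometric_ladder"


@dataclasses.dataclass(frozen=True)
class GelSpec:
    """Full description of a synthetic gel.

    ``genotypes`` lists each lane's molecular weights (reference lanes carry
    the marker's ladder). The migration law places a fragment of weight w at
    row ``migration_a + migration_b * log10(w)`` (b < 0: big fragments stay
    near the wells); ``smile_amplitude_px`` adds ``amp * u^2`` rows per
    lane, u in [-1, 1] across the gel width. ``lane_curvature_px`` bends
    each lane's centerline sinusoidally. Intensities: each band is a 2-D
    Gaussian ridge of height ``band_amplitude`` and widths
    (``band_sigma_row``, lane_width/4); the background is
    ``background_level`` plus a vertical ramp; pixel noise is i.i.d.
    Gaussian with ``noise_sigma``.
    """

    marker: ReferenceMarker
    genotypes: tuple
    reference_lanes: tuple
    height_px: int = 360
    width_px: int = 286
    lane_width_px: int = 14
    lane_curvature_px: float = 0.0
    migration_a: float = 716.7
    migration_b: float = -226.9
    smile_amplitude_px: float = 0.0
    band_amplitude: float = 0.5
    band_sigma_row: float = 2.2
    background_level: float = 0.06
    background_ramp: float = 0.0
    noise_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.migration_b >= 0:
            raise DomainError("migration_b must be negative (monotone law)")
        object.__setattr__(self, "genotypes",
                           tuple(tuple(float(w) for w in g)
                                 for g in self.genotypes))
        object.__setattr__(self, "reference_lanes",
                           tuple(int(i) for i in self.reference_lanes))
        if len(self.genotypes) < 1:
            raise DomainError("need at least one lane")

    @property
    def n_lanes(self) -> int:
        return len(self.genotypes)

    def lane_centers(self) -> np.ndarray:
        w = self.width_px
        n = self.n_lanes
        return np.array([(i + 1) * w / (n + 1) for i in range(n)])

    def band_row(self, mw: float, lane: int) -> float:
        u = 2.0 * self.lane_centers()[lane] / (self.width_px - 1) - 1.0
        return (self.migration_a + self.migration_b * np.log10(mw)
                + self.smile_amplitude_px * u * u)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["marker"] = self.marker.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GelSpec":
        d = dict(d)
        d["marker"] = ReferenceMarker.from_dict(d["marker"])
        d["genotypes"] = tuple(tuple(g) for g in d["genotypes"])
        d["reference_lanes"] = tuple(d["reference_lanes"])
        return cls(**d)


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """Pre-noise truth for a generated gel: per-lane centerline columns
    (one per image row), per-lane (row, molecular weight) band lists,
    reference-lane indices and the marker table used."""

    lane_centers: np.ndarray          # (n_lanes, height) centerline columns
    bands: tuple                      # per lane: tuple of (row, mw)
    reference_lanes: tuple
    marker: ReferenceMarker


def generate_gel(spec: GelSpec) -> tuple[GelImage, GroundTruth]:
    """Render a synthetic gel and its ground truth."""
    h, w = spec.height_px, spec.width_px
    rng = np.random.default_rng(spec.seed)
    rows = np.arange(h, dtype=np.float64)
    img = np.full((h, w), spec.background_level, dtype=np.float64)
    if spec.background_ramp:
        img += spec.background_ramp * (rows / max(h - 1, 1))[:, None]

    centers = spec.lane_centers()
    sigma_c = spec.lane_width_px / 4.0
    sigma_r = spec.band_sigma_row
    lane_centerlines = np.empty((spec.n_lanes, h))
    truth_bands = []
    for li, genotype in enumerate(spec.genotypes):
        colline = centers[li] + spec.lane_curvature_px * np.sin(
            np.pi * rows / max(h - 1, 1))
        lane_centerlines[li] = colline
        lane_bands = []
        for mw in genotype:
            r = spec.band_row(mw, li)
            if not (0 <= r <= h - 1):
                raise DomainError(
                    f"weight {mw} maps to row {r:.1f} outside the gel")
            lane_bands.append((float(r), float(mw)))
            r0 = max(0, int(np.floor(r - 4 * sigma_r)))
            r1 = min(h, int(np.ceil(r + 4 * sigma_r)) + 1)
            rr = rows[r0:r1]
            amp_r = spec.band_amplitude * np.exp(
                -((rr - r) ** 2) / (2 * sigma_r ** 2))
            c0 = max(0, int(np.floor(colline[r0:r1].min() - 4 * sigma_c)))
            c1 = min(w, int(np.ceil(colline[r0:r1].max() + 4 * sigma_c)) + 1)
            cc = np.arange(c0, c1, dtype=np.float64)
            prof_c = np.exp(-((cc[None, :] - colline[r0:r1, None]) ** 2)
                            / (2 * sigma_c ** 2))
            img[r0:r1, c0:c1] += amp_r[:, None] * prof_c
        truth_bands.append(tuple(lane_bands))

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    truth = GroundTruth(lane_centers=lane_centerlines,
                        bands=tuple(truth_bands),
                        reference_lanes=spec.reference_lanes,
                        marker=spec.marker)
    return GelImage.from_array(img), truth


def perturb_genotype(weights: Sequence[float], jitter_percent: float,
                     drop_prob: float, seed: int) -> list[float]:
    """Jitter each weight by a uniform +-jitter_percent% factor and drop
    bands independently with probability drop_prob (must be < 1).
    Deterministic under the seed."""
    if jitter_percent < 0:
        raise DomainError("jitter_percent must be >= 0")
    if not 0.0 <= drop_prob < 1.0:
        raise DomainError("drop_prob must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    out = []
    for w in weights:
        eps = rng.uniform(-jitter_percent / 100.0, jitter_percent / 100.0)
        keep = rng.random() >= drop_prob
        if keep:
            out.append(float(w) * (1.0 + eps))
    return out


def sample_genotype(rng: np.random.Generator, n_bands: int = 10,
                    mw_range: tuple = (60.0, 900.0),
                    min_dlog: float = 0.035) -> tuple:
    """Draw a random genotype: ``n_bands`` weights log-uniform in
    ``mw_range``, greedily thinned so adjacent bands are separated by at
    least ``min_dlog`` in log10 (keeps bands resolvable on the gel)."""
    lo, hi = np.log10(mw_range[0]), np.log10(mw_range[1])
    cand = np.sort(rng.uniform(lo, hi, size=6 * n_bands))[::-1]
    picked = []
    for lw in cand:
        if all(abs(lw - q) >= min_dlog for q in picked):
            picked.append(lw)
        if len(picked) == n_bands:
            break
    return tuple(float(10.0 ** lw) for lw in sorted(picked, reverse=True))


def log_law_through(mw_range: tuple, row_range: tuple) -> tuple:
    """(a, b) of row = a + b*log10(mw) placing mw_range at row_range."""
    (w_hi, w_lo), (r_top, r_bot) = mw_range, row_range
    b = (r_bot - r_top) / (np.log10(w_lo) - np.log10(w_hi))
    a = r_top - b * np.log10(w_hi)
    return float(a), float(b)


def default_spec(seed: int = 0, n_lanes: int = 8,
                 marker: ReferenceMarker | None = None,
                 **overrides) -> GelSpec:
    """Study-conditions default: an 8-lane gel with marker ladders in the
    outermost lanes and random genotypes between them. Unless a migration
    law is given, one is derived to span the marker over 10-92% of the gel
    height."""
    if marker is None:
        marker = load_predefined_marker(DEFAULT_MARKER_NAME)
    if "migration_a" not in overrides and "migration_b" not in overrides:
        h = overrides.get("height_px", 360)
        w = marker.weights
        a, b = log_law_through((float(w.max()), float(w.min())),
                               (0.10 * h, 0.92 * h))
        overrides["migration_a"], overrides["migration_b"] = a, b
    rng = np.random.default_rng(seed)
    ladder = tuple(float(w) for w in marker.weights)
    genotypes = []
    for i in range(n_lanes):
        if i in (0, n_lanes - 1):
            genotypes.append(ladder)
        else:
            genotypes.append(sample_genotype(rng))
    return GelSpec(marker=marker, genotypes=tuple(genotypes),
                   reference_lanes=(0, n_lanes - 1), seed=seed, **overrides)


def save_truth(truth: GroundTruth, path) -> None:
    doc = {"lane_centers": truth.lane_centers.tolist(),
           "bands": [[list(b) for b in lane] for lane in truth.bands],
           "reference_lanes": list(truth.reference_lanes),
           "marker": truth.marker.to_dict()}
    with open(path, "w") as fh:
        json.dump(doc, fh)
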