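"""Persistence: studies, experiments, comparisons and similarity search.

Storage is a versioned on-disk directory of JSON documents rather than an
embedded database: each study gets its own sub-directory holding
``study.json``, one JSON document per experiment and copies of any source
images. Experiments can additionally be exported as a self-contained zip
bundle (experiment + marker + image) for sharing between users; an
imported experiment is comparable with local experiments normalized with
the same reference marker.

All numeric fields (band weights, densitometric curves, model parameters)
round-trip at full float precision, so a saved-and-reloaded experiment
compares bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
import shutil
import zipfile
from pathlib import Path
from typing import Sequence

import numpy as np

from .band_detect import Band, BandPattern
from .errors import IncompleteBundleError, StoreError
from .lane_detect import Lane, ProjectionProfile
from .normalize import MigrationModel, ReferenceMarker, ShiftField
from .similarity import (BAND_METRICS, MatchSpec, SimilarityMatrix,
                         band_similarity, curve_similarity)

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1

#: info keys pre-declared on every lane; arbitrary extra keys are allowed
FIXED_INFO_KEYS = ("genus", "species", "strain_number", "country")


# ---------------------------------------------------------------------------
# (de)serialization helpers
# ---------------------------------------------------------------------------


def _floats(seq):
    return [None if (x is None or not np.isfinite(x)) else float(x)
            for x in seq]


def _lane_to_dict(l: Lane) -> dict:
    return {"centerline": [list(p) for p in l.centerline],
            "thickness_px": l.thickness_px, "is_reference": l.is_reference,
            "info": dict(l.info), "local_adjust": l.local_adjust,
            "band_threshold": l.band_threshold}


def _lane_from_dict(d: dict) -> Lane:
    adj = d.get("local_adjust")
    if adj and "window" in adj:
        adj = dict(adj)
        adj["window"] = tuple(adj["window"])
    return Lane(centerline=tuple(tuple(p) for p in d["centerline"]),
                thickness_px=int(d["thickness_px"]),
                is_reference=bool(d["is_reference"]),
                info=dict(d.get("info", {})), local_adjust=adj,
                band_threshold=d.get("band_threshold"))


def _band_to_dict(b: Band) -> dict:
    return {"lane_index": b.lane_index, "row_px": b.row_px,
            "height": b.height, "origin": b.origin,
            "normalized_row_px": b.normalized_row_px,
            "molecular_weight": b.molecular_weight}


def _pattern_to_dict(p: BandPattern) -> dict:
    cw = None if p.curve_weights is None else _floats(p.curve_weights)
    return {"lane_index": p.lane_index, "marker_name": p.marker_name,
            "bands": [_band_to_dict(b) for b in p.bands],
            "curve": {"values": [float(v) for v in p.curve.values],
                      "start": p.curve.start},
            "curve_weights": cw,
            "edits": [list(e) for e in p.edits],
            "edit_cursor": p.edit_cursor,
            "base_bands": (None if p.base_bands is None
                           else [_band_to_dict(b) for b in p.base_bands])}


def _pattern_from_dict(d: dict) -> BandPattern:
    cw = d.get("curve_weights")
    if cw is not None:
        cw = np.array([np.nan if v is None else v for v in cw], dtype=float)
    return BandPattern(
        lane_index=int(d["lane_index"]),
        bands=tuple(Band(**b) for b in d["bands"]),
        curve=ProjectionProfile(values=np.array(d["curve"]["values"]),
                                axis="rows", start=int(d["curve"]["start"])),
        marker_name=d["marker_name"], curve_weights=cw,
        edits=tuple((e[0], float(e[1])) for e in d.get("edits", [])),
        edit_cursor=int(d.get("edit_cursor", 0)),
        base_bands=(None if d.get("base_bands") is None
                    else tuple(Band(**b) for b in d["base_bands"])))


# ---------------------------------------------------------------------------
# experiments and studies
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class Experiment:
    """One analyzed gel image: lanes, weighed band patterns, marker and
    normalization parameters, plus the image reference and its
    preprocessing history."""

    name: str
    date: str
    marker: ReferenceMarker
    lanes: list
    patterns: list
    model: MigrationModel | None = None
    shift_field: ShiftField | None = None
    image_path: str | None = None
    preprocess_history: list = dataclasses.field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "name": self.name, "date": self.date,
            "marker": self.marker.to_dict(),
            "lanes": [_lane_to_dict(l) for l in self.lanes],
            "patterns": [_pattern_to_dict(p) for p in self.patterns],
            "model": self.model.to_dict() if self.model else None,
            "shift_field": (self.shift_field.to_dict()
                            if self.shift_field else None),
            "image_path": self.image_path,
            "preprocess_history": [[n, p] for n, p in self.preprocess_history],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Experiment":
        _check_version(d)
        return cls(
            name=d["name"], date=d["date"],
            marker=ReferenceMarker.from_dict(d["marker"]),
            lanes=[_lane_from_dict(x) for x in d["lanes"]],
            patterns=[_pattern_from_dict(x) for x in d["patterns"]],
            model=(MigrationModel.from_dict(d["model"])
                   if d.get("model") else None),
            shift_field=(ShiftField.from_dict(d["shift_field"])
                         if d.get("shift_field") else None),
            image_path=d.get("image_path"),
            preprocess_history=[(n, p) for n, p
                                in d.get("preprocess_history", [])])

    @classmethod
    def from_analysis(cls, name: str, analysis, date: str = "",
                      image_path: str | None = None,
                      preprocess_history=()) -> "Experiment":
        """Wrap a :class:`gelkit.pipeline.GelAnalysis` as an experiment."""
        return cls(name=name, date=date, marker=analysis.marker,
                   lanes=list(analysis.lanes),
                   patterns=list(analysis.patterns),
                   model=analysis.model, shift_field=analysis.shift_field,
                   image_path=image_path,
                   preprocess_history=list(preprocess_history))

    def band_table(self):
        """Flat band table (lane, row, normalized_row, height, weight)."""
        import pandas as pd
        rows = []
        for p in self.patterns:
            for b in p.bands:
                rows.append({"lane": p.lane_index, "row_px": b.row_px,
                             "normalized_row_px": b.normalized_row_px,
                             "height": b.height,
                             "molecular_weight": b.molecular_weight,
                             "origin": b.origin})
        return pd.DataFrame(rows)


@dataclasses.dataclass
class Comparison:
    """A stored comparison: which lanes, how they were compared, and the
    resulting matrix and dendrogram (as Newick)."""

    name: str
    lane_refs: list          # (experiment name, lane index) pairs
    method: str
    params: dict
    matrix_lane_ids: list
    matrix_values: list
    tree_newick: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Comparison":
        d = dict(d)
        d["lane_refs"] = [tuple(x) for x in d["lane_refs"]]
        return cls(**d)


@dataclasses.dataclass
class Study:
    """A named collection of experiments and their comparisons."""

    name: str
    experiments: list = dataclasses.field(default_factory=list)
    comparisons: list = dataclasses.field(default_factory=list)

    def experiment(self, name: str) -> Experiment:
        for e in self.experiments:
            if e.name == name:
                return e
        raise KeyError(name)


def _check_version(d: dict) -> None:
    v = d.get("format_version")
    if v != FORMAT_VERSION:
        raise StoreError(
            f"format version mismatch: file has {v!r}, "
            f"this gelkit reads {FORMAT_VERSION}")


def _slug(name: str) -> str:
    s = re.sub(r"[^A-Za-z0-9._-]+", "_", name).strip("_")
    return s or "unnamed"


def save_study(study: Study, root: str | Path) -> Path:
    """Write a study under ``root/<study-name>/``; returns the study dir.

    Studies saved to the same root live in independent sub-directories and
    never clobber each other.
    """
    root = Path(root)
    sdir = root / _slug(study.name)
    (sdir / "experiments").mkdir(parents=True, exist_ok=True)
    exp_files = []
    for e in study.experiments:
        fname = f"experiments/{_slug(e.name)}.json"
        doc = e.to_dict()
        if e.image_path and Path(e.image_path).exists():
            imdir = sdir / "images"
            imdir.mkdir(exist_ok=True)
            dest = imdir / Path(e.image_path).name
            if Path(e.image_path).resolve() != dest.resolve():
                shutil.copyfile(e.image_path, dest)
            doc["image_path"] = f"images/{dest.name}"
        (sdir / fname).write_text(json.dumps(doc))
        exp_files.append(fname)
    top = {"format_version": FORMAT_VERSION, "name": study.name,
           "experiments": exp_files,
           "comparisons": [c.to_dict() for c in study.comparisons]}
    (sdir / "study.json").write_text(json.dumps(top))
    return sdir


def load_study(path: str | Path) -> Study:
    """Load a study from its directory (the one holding study.json)."""
    sdir = Path(path)
    f = sdir / "study.json"
    if not f.exists():
        raise StoreError(f"no study.json under {sdir}")
    try:
        top = json.loads(f.read_text())
    except json.JSONDecodeError as exc:
        raise StoreError(f"corrupt study file {f}: {exc}") from exc
    _check_version(top)
    exps = []
    for rel in top["experiments"]:
        try:
            doc = json.loads((sdir / rel).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise StoreError(f"corrupt experiment file {rel}: {exc}") from exc
        e = Experiment.from_dict(doc)
        if e.image_path:
            e.image_path = str(sdir / e.image_path)
        exps.append(e)
    comps = [Comparison.from_dict(c) for c in top.get("comparisons", [])]
    return Study(name=top["name"], experiments=exps, comparisons=comps)


# ---------------------------------------------------------------------------
# experiment bundles
# ---------------------------------------------------------------------------


def export_experiment(exp: Experiment, bundle_path: str | Path) -> Path:
    """Write a self-contained zip bundle (experiment + marker + image)."""
    bundle_path = Path(bundle_path)
    with zipfile.ZipFile(bundle_path, "w", zipfile.ZIP_DEFLATED) as z:
        doc = exp.to_dict()
        if exp.image_path and Path(exp.image_path).exists():
            z.write(exp.image_path, f"image{Path(exp.image_path).suffix}")
            doc["image_path"] = f"image{Path(exp.image_path).suffix}"
        else:
            doc["image_path"] = None
        z.writestr("experiment.json", json.dumps(doc))
        z.writestr("marker.json", json.dumps(exp.marker.to_dict()))
        z.writestr("manifest.json",
                   json.dumps({"format_version": FORMAT_VERSION}))
    return bundle_path


def import_experiment(bundle_path: str | Path,
                      extract_image_to: str | Path | None = None
                      ) -> Experiment:
    """Read an experiment bundle written by :func:`export_experiment`."""
    bundle_path = Path(bundle_path)
    try:
        with zipfile.ZipFile(bundle_path) as z:
            names = set(z.namelist())
            if "marker.json" not in names:
                raise IncompleteBundleError(
                    f"bundle {bundle_path} lacks marker.json")
            if "experiment.json" not in names:
                raise IncompleteBundleError(
                    f"bundle {bundle_path} lacks experiment.json")
            manifest = json.loads(z.read("manifest.json")) \
                if "manifest.json" in names else {}
            _check_version(manifest)
            doc = json.loads(z.read("experiment.json"))
            exp = Experiment.from_dict(doc)
            if exp.image_path and extract_image_to is not None:
                out = Path(extract_image_to)
                out.mkdir(parents=True, exist_ok=True)
                z.extract(exp.image_path, out)
                exp.image_path = str(out / exp.image_path)
            return exp
    except zipfile.BadZipFile as exc:
        raise StoreError(f"corrupt bundle {bundle_path}: {exc}") from exc


# ---------------------------------------------------------------------------
# similarity search
# ---------------------------------------------------------------------------


def find_similar_lanes(query: BandPattern,
                       store: Study | Sequence[Study],
                       method: str = "dice",
                       spec: MatchSpec = MatchSpec(),
                       min_similarity_percent: float = 0.0,
                       resample_n: int = 256) -> list[tuple[tuple, float]]:
    """Score every compatible stored lane against the query pattern.

    Returns ``((study, experiment, lane_index), similarity)`` pairs with
    similarity >= the threshold, sorted by descending similarity (ties:
    study name, experiment name, lane index). Lanes normalized with a
    different marker are skipped and counted in the log.
    """
    if not 0.0 <= min_similarity_percent <= 100.0:
        raise ValueError("min_similarity_percent must lie in [0, 100]")
    studies = [store] if isinstance(store, Study) else list(store)
    if not studies or all(not s.experiments for s in studies):
        logger.warning("similarity search over an empty store")
    results = []
    skipped = 0
    for s in studies:
        for e in s.experiments:
            for p in e.patterns:
                if p.marker_name != query.marker_name:
                    skipped += 1
                    continue
                if method in BAND_METRICS:
                    sim = band_similarity(query, p, method, spec)
                else:
                    sim = curve_similarity(query, p, method, resample_n)
                if sim >= min_similarity_percent:
                    results.append(((s.name, e.name, p.lane_index), sim))
    if skipped:
        logger.info("similarity search skipped %d incompatible lanes", skipped)
    results.sort(key=lambda t: (-t[1], t[0][0], t[0][1], t[0][2]))
    return results
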