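"""Descriptor comparison, significance, database build/update and scanning.

Two chains are compared by the Euclidean distance D between their
30-component descriptors.  The statistical meaning of a distance is read
off the background distribution of distances d(x) over all unordered pairs
of database entries: the significance ``pD`` of an observed distance is the
fraction of background distances strictly larger, so a small ``1 - pD``
flags an uncommonly similar pair.

The database is a single JSON file holding a header (pattern-enumeration
version, creation time), the ``entry_id -> descriptor`` map, and the
background distribution.  The background is kept as the full sorted sample
up to a cap, beyond which it degrades gracefully to a fixed-bin histogram.
Databases built under different pattern enumerations are never mixed.
"""

from __future__ import annotations

import json
import logging
import math
import os
import tempfile
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from .gauss import GaussDescriptor, compute_descriptor
from .patterns import PATTERN_VERSION
from .structure_io import ChainSelector, StructureError, parse_structure, validate_curve

__all__ = [
    "DistanceResult",
    "ScanHit",
    "BackgroundDistribution",
    "DescriptorDatabase",
    "descriptor_distance",
    "significance",
    "compare",
    "build_database",
    "update_database",
    "scan",
    "roc_curve",
    "RocCurve",
    "write_descriptors_tsv",
    "read_descriptors_tsv",
]

logger = logging.getLogger(__name__)

#: above this many stored background distances, switch to a histogram
SAMPLE_LIMIT = 1_000_000
HISTOGRAM_BINS = 10_000


@dataclass(frozen=True)
class DistanceResult:
    """Distance D between two descriptors plus its background significance."""

    distance: float
    significance: float | None = None
    background_size: int = 0


@dataclass(frozen=True)
class ScanHit:
    """One database match of a scan query."""

    entry_id: str
    distance: float
    significance: float


def descriptor_distance(d1: GaussDescriptor, d2: GaussDescriptor) -> float:
    """Euclidean distance between two 30-component descriptors.

    Descriptors must come from the same pattern enumeration (version).
    """
    if d1.version != d2.version:
        raise ValueError(
            f"descriptor version mismatch: {d1.version!r} vs {d2.version!r}"
        )
    return float(np.linalg.norm(d1.vector - d2.vector))


class BackgroundDistribution:
    """All-pairs distance distribution supporting the survival query
    ``P(d > D)`` with strict inequality."""

    def __init__(self, sample=None, bin_edges=None, counts=None):
        if sample is not None:
            self.sample = np.sort(np.asarray(sample, dtype=float))
            self.bin_edges = None
            self.counts = None
            self.size = len(self.sample)
        else:
            self.sample = None
            self.bin_edges = np.asarray(bin_edges, dtype=float)
            self.counts = np.asarray(counts, dtype=np.int64)
            self.size = int(self.counts.sum())

    @classmethod
    def from_distances(cls, distances) -> "BackgroundDistribution":
        distances = np.asarray(distances, dtype=float)
        if len(distances) <= SAMPLE_LIMIT:
            return cls(sample=distances)
        edges = np.linspace(0.0, float(distances.max()), HISTOGRAM_BINS + 1)
        counts, _ = np.histogram(distances, bins=edges)
        return cls(bin_edges=edges, counts=counts)

    def extend(self, new_distances) -> "BackgroundDistribution":
        new_distances = np.asarray(new_distances, dtype=float)
        if self.sample is not None:
            merged = np.concatenate([self.sample, new_distances])
            return self.from_distances(merged)
        # histogram mode: clip into the existing bins (documented approximation)
        counts = self.counts.copy()
        clipped = np.clip(new_distances, self.bin_edges[0], self.bin_edges[-1])
        add, _ = np.histogram(clipped, bins=self.bin_edges)
        return BackgroundDistribution(bin_edges=self.bin_edges, counts=counts + add)

    def survival(self, d: float) -> float:
        """Fraction of background distances strictly greater than ``d``."""
        if self.size == 0:
            raise ValueError("empty background distribution")
        if self.sample is not None:
            above = self.size - np.searchsorted(self.sample, d, side="right")
            return float(above) / self.size
        # histogram: count bins lying entirely above d
        idx = np.searchsorted(self.bin_edges, d, side="right")
        return float(self.counts[idx:].sum()) / self.size


@dataclass
class DescriptorDatabase:
    """Persisted descriptor collection plus background distance sample."""

    entries: dict[str, GaussDescriptor] = field(default_factory=dict)
    background: BackgroundDistribution | None = None
    version: str = PATTERN_VERSION
    created: str = ""
    skipped: list[tuple[str, str]] = field(default_factory=list)  # not persisted

    def __len__(self) -> int:
        return len(self.entries)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Atomic single-file JSON store."""
        path = Path(path)
        bg: dict = {}
        if self.background is not None:
            if self.background.sample is not None:
                bg = {"sample": self.background.sample.tolist()}
            else:
                bg = {
                    "bin_edges": self.background.bin_edges.tolist(),
                    "counts": self.background.counts.tolist(),
                }
        payload = {
            "format": "rnagauss-db",
            "version": self.version,
            "created": self.created or datetime.now(timezone.utc).isoformat(),
            "entries": {
                eid: d.vector.tolist() for eid, d in sorted(self.entries.items())
            },
            "background": bg,
        }
        fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=".tmp")
        try:
            with os.fdopen(fd, "w") as fh:
                json.dump(payload, fh)
            os.replace(tmp, path)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise
        return path

    @classmethod
    def load(cls, path: str | Path) -> "DescriptorDatabase":
        path = Path(path)
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "rnagauss-db":
            raise ValueError(f"{path} is not a descriptor database")
        version = payload["version"]
        entries = {
            eid: GaussDescriptor(eid, np.asarray(vec), version)
            for eid, vec in payload["entries"].items()
        }
        bg = payload.get("background") or {}
        if "sample" in bg:
            background = BackgroundDistribution(sample=bg["sample"])
        elif "bin_edges" in bg:
            background = BackgroundDistribution(
                bin_edges=bg["bin_edges"], counts=bg["counts"]
            )
        else:
            background = None
        return cls(
            entries=entries,
            background=background,
            version=version,
            created=payload.get("created", ""),
        )


def significance(distance: float, db: DescriptorDatabase) -> float:
    """Empirical significance pD: fraction of all-pairs background distances
    strictly greater than the observed distance."""
    if db.background is None or db.background.size == 0:
        raise ValueError("database has no background distribution")
    return db.background.survival(distance)


def compare(
    d1: GaussDescriptor, d2: GaussDescriptor, db: DescriptorDatabase | None = None
) -> DistanceResult:
    """Pairwise comparison; attaches significance when a database is given."""
    dist = descriptor_distance(d1, d2)
    if db is not None and db.background is not None and db.background.size:
        return DistanceResult(dist, significance(dist, db), db.background.size)
    return DistanceResult(dist)


# ---------------------------------------------------------------------------
# database construction


def _descriptor_from_file(path: str | Path, chain_id=None, model_index=None):
    curve = parse_structure(ChainSelector(path, chain_id, model_index))
    return compute_descriptor(validate_curve(curve))


def _collect_descriptors(pdb_paths) -> tuple[list[GaussDescriptor], list[tuple[str, str]]]:
    descriptors: list[GaussDescriptor] = []
    skipped: list[tuple[str, str]] = []
    for path in pdb_paths:
        try:
            descriptors.append(_descriptor_from_file(path))
        except (StructureError, FileNotFoundError) as exc:
            logger.warning("skipping %s: %s", path, exc)
            skipped.append((str(path), str(exc)))
    return descriptors, skipped


def _all_pairs_distances(descriptors: list[GaussDescriptor]) -> np.ndarray:
    vecs = np.array([d.vector for d in descriptors])
    n = len(vecs)
    out = []
    for i in range(n - 1):
        out.append(np.linalg.norm(vecs[i + 1:] - vecs[i], axis=1))
    return np.concatenate(out) if out else np.array([])


def build_database(pdb_paths, store_path: str | Path | None = None) -> DescriptorDatabase:
    """Compute descriptors for every valid chain and the all-pairs
    background; chains with <= 7 nucleotides are skipped and logged.

    Persists atomically to ``store_path`` when given.
    """
    descriptors, skipped = _collect_descriptors(pdb_paths)
    if not descriptors:
        raise ValueError("no valid chains among the inputs")
    entries = {d.entry_id: d for d in descriptors}
    background = BackgroundDistribution.from_distances(
        _all_pairs_distances(list(entries.values()))
    )
    db = DescriptorDatabase(
        entries=entries,
        background=background,
        created=datetime.now(timezone.utc).isoformat(),
        skipped=skipped,
    )
    if store_path is not None:
        db.save(store_path)
    return db


def update_database(
    db: DescriptorDatabase, new_paths, store_path: str | Path | None = None
) -> DescriptorDatabase:
    """Add new entries only, extending the background with the new-vs-all
    distances; equivalent to a full rebuild on the union set."""
    if db.version != PATTERN_VERSION:
        raise ValueError(
            f"database version {db.version!r} does not match this build "
            f"({PATTERN_VERSION!r})"
        )
    descriptors, skipped = _collect_descriptors(new_paths)
    fresh = []
    for d in descriptors:
        if d.entry_id in db.entries or any(f.entry_id == d.entry_id for f in fresh):
            logger.info("entry %s already present; unchanged", d.entry_id)
            skipped.append((d.entry_id, "already present"))
            continue
        fresh.append(d)
    if not fresh:
        db.skipped = skipped
        return db

    old = list(db.entries.values())
    new_distances = []
    for i, d in enumerate(fresh):
        others = old + fresh[:i]
        if others:
            vecs = np.array([o.vector for o in others])
            new_distances.append(np.linalg.norm(vecs - d.vector, axis=1))
    extra = np.concatenate(new_distances) if new_distances else np.array([])

    entries = dict(db.entries)
    entries.update({d.entry_id: d for d in fresh})
    background = (
        db.background.extend(extra)
        if db.background is not None
        else BackgroundDistribution.from_distances(extra)
    )
    out = DescriptorDatabase(
        entries=entries,
        background=background,
        version=db.version,
        created=db.created,
        skipped=skipped,
    )
    if store_path is not None:
        out.save(store_path)
    return out


def scan(
    query: GaussDescriptor,
    db: DescriptorDatabase,
    cutoff: float = 0.5,
    top_n: int = 10,
) -> list[ScanHit]:
    """Database entries within ``cutoff`` of the query, closest first.

    Ties in distance break lexicographically by entry id; the list is
    truncated to ``top_n``.  An empty result is valid.
    """
    if not db.entries:
        raise ValueError("database is empty")
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    hits = []
    for eid, desc in db.entries.items():
        d = descriptor_distance(query, desc)
        if d <= cutoff:
            hits.append((d, eid))
    hits.sort()
    has_bg = db.background is not None and db.background.size > 0
    return [
        ScanHit(eid, d, db.background.survival(d) if has_bg else math.nan)
        for d, eid in hits[:top_n]
    ]


# ---------------------------------------------------------------------------
# ROC utility for cluster-recovery evaluation


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC of same-cluster prediction by distance thresholding."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    auc: float


def roc_curve(distances: np.ndarray, labels, thresholds=None) -> RocCurve:
    """ROC of predicting same-cluster pairs by ``distance <= threshold``.

    ``distances`` is a square symmetric matrix over items, ``labels`` the
    cluster assignment.  Default thresholds are the midpoints between
    consecutive sorted unique pair distances (the exact empirical curve);
    AUC by the trapezoid rule.
    """
    distances = np.asarray(distances, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    if distances.shape != (n, n):
        raise ValueError("distances must be a square matrix matching labels")
    iu, ju = np.triu_indices(n, k=1)
    pair_d = distances[iu, ju]
    same = labels[iu] == labels[ju]
    n_pos = int(same.sum())
    n_neg = int((~same).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both same-cluster and different-cluster pairs")

    if thresholds is None:
        uniq = np.unique(pair_d)
        mids = (uniq[:-1] + uniq[1:]) / 2.0
        thresholds = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    thresholds = np.asarray(thresholds, dtype=float)

    pred = pair_d[None, :] <= thresholds[:, None]
    tp = (pred & same[None, :]).sum(axis=1)
    fp = (pred & ~same[None, :]).sum(axis=1)
    sens = tp / n_pos
    fpr = fp / n_neg
    order = np.argsort(fpr, kind="stable")
    auc = float(np.trapezoid(sens[order], fpr[order]))
    return RocCurve(thresholds, sens, fpr, auc)


# ---------------------------------------------------------------------------
# flat-text interchange


def write_descriptors_tsv(db: DescriptorDatabase, path: str | Path) -> Path:
    """One line per entry: entry_id + 30 full-precision components."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# rnagauss descriptors\t{db.version}\n")
        for eid, d in sorted(db.entries.items()):
            comps = "\t".join(f"{x:.17g}" for x in d.vector)
            fh.write(f"{eid}\t{comps}\n")
    return path


def read_descriptors_tsv(path: str | Path) -> DescriptorDatabase:
    """Inverse of :func:`write_descriptors_tsv` (no background)."""
    path = Path(path)
    entries: dict[str, GaussDescriptor] = {}
    version = PATTERN_VERSION
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line.split("\t")
                if len(parts) > 1:
                    version = parts[1]
                continue
            fields = line.split("\t")
            eid, vec = fields[0], np.array([float(x) for x in fields[1:]])
            entries[eid] = GaussDescriptor(eid, vec, version)
    return DescriptorDatabase(entries=entries, version=version)
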