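"""Jukes–Cantor corrected pairwise distances and alignment trimming.

Distances are stored as proportions (substitutions/site) internally; percent
appears only at the reporting layer. Under JC69 the corrected distance for an
observed mismatch proportion p is

    d = -(3/4) * ln(1 - (4/3) * p),

defined for p < 3/4; pairs at or beyond that bound are saturated and flagged
undefined rather than silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_formats import Alignment, SequenceRecord

SATURATION_P = 0.75

# upper-case residues only reach this module (read_fasta normalises)
_MISSING = {"-", "N"}


class SaturatedDistanceError(ValueError):
    """Raised when p >= 3/4 and the JC69 correction is undefined."""


def p_distance(a: SequenceRecord, b: SequenceRecord) -> tuple[float, int]:
    """Observed mismatch proportion between two aligned sequences.

    Columns where either sequence carries a gap or N are excluded
    (pairwise deletion). Returns ``(p, n_sites)``.
    """
    if len(a) != len(b):
        raise ValueError(
            f"sequences {a.id!r} ({len(a)} bp) and {b.id!r} ({len(b)} bp) are not aligned"
        )
    n_sites = 0
    mismatches = 0
    for x, y in zip(a.seq, b.seq):
        if x in _MISSING or y in _MISSING:
            continue
        n_sites += 1
        if x != y:
            mismatches += 1
    if n_sites == 0:
        raise ValueError(f"no comparable sites between {a.id!r} and {b.id!r}")
    return mismatches / n_sites, n_sites


def jc69_distance(p: float) -> float:
    """JC69-corrected distance for observed mismatch proportion ``p``."""
    if p < 0:
        raise ValueError(f"mismatch proportion must be >= 0, got {p}")
    if p >= SATURATION_P:
        raise SaturatedDistanceError(f"saturated distance: p = {p} >= 3/4")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of JC69 distances with taxon labels.

    Saturated or incomparable pairs are NaN in ``d`` (flagged, never
    dropped); ``n_sites`` carries the per-pair count of compared columns.
    """

    labels: tuple[str, ...]
    d: np.ndarray
    n_sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n) or self.n_sites.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(np.diagonal(self.d), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        finite = self.d[np.isfinite(self.d)]
        if (finite < 0).any():
            raise ValueError("distances must be nonnegative")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.d[i, j])

    def is_defined(self, a: str, b: str) -> bool:
        return bool(np.isfinite(self.d[self.labels.index(a), self.labels.index(b)]))

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if not np.isfinite(self.d[i, j]):
                    out.append((self.labels[i], self.labels[j]))
        return out

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                row = "\t".join(
                    f"{self.d[i, j]:.8f}" if np.isfinite(self.d[i, j]) else "NA"
                    for j in range(len(self.labels))
                )
                fh.write(f"{lab}\t{row}\n")

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for i, lab in enumerate(self.labels):
                row = " ".join(f"{self.d[i, j]:.8f}" for j in range(len(self.labels)))
                fh.write(f"{lab}  {row}\n")


def complete_deletion(aln: Alignment) -> Alignment:
    """Drop every column containing a gap or N in any record."""
    keep = [
        j for j in range(aln.length) if not any(c in _MISSING for c in aln.column(j))
    ]
    if not keep:
        raise ValueError("complete deletion removed every column")
    return Alignment(
        tuple(
            SequenceRecord(r.id, "".join(r.seq[j] for j in keep)) for r in aln.records
        )
    )


def pairwise_matrix(aln: Alignment, gap_deletion: str = "pairwise") -> DistanceMatrix:
    """JC69 distance matrix over all pairs of an alignment.

    ``gap_deletion`` selects pairwise (default) or complete deletion of
    gapped/N columns. Saturated pairs become NaN entries.
    """
    if len(aln) < 2:
        raise ValueError("need at least 2 sequences")
    if gap_deletion == "complete":
        aln = complete_deletion(aln)
    elif gap_deletion != "pairwise":
        raise ValueError(f"unknown gap_deletion mode {gap_deletion!r}")
    n = len(aln)
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    recs = aln.records
    for i in range(n):
        sites[i, i] = aln.length
        for j in range(i + 1, n):
            p, ns = p_distance(recs[i], recs[j])
            try:
                dij = jc69_distance(p)
            except SaturatedDistanceError:
                dij = math.nan
            d[i, j] = d[j, i] = dij
            sites[i, j] = sites[j, i] = ns
    return DistanceMatrix(tuple(aln.ids), d, sites)


def trim_columns(aln: Alignment, max_missing_fraction: float = 0.25) -> Alignment:
    """Remove columns absent (gap or N) in more than ``max_missing_fraction``
    of the sequences; the comparison is strict, so a column exactly at the
    threshold is kept. Row order is preserved."""
    if not 0 <= max_missing_fraction < 1:
        raise ValueError("max_missing_fraction must be in [0, 1)")
    n = len(aln)
    keep = []
    for j in range(aln.length):
        missing = sum(1 for c in aln.column(j) if c in _MISSING)
        if missing / n <= max_missing_fraction:
            keep.append(j)
    if not keep:
        raise ValueError("trimming removed every column")
    return Alignment(
        tuple(
            SequenceRecord(r.id, "".join(r.seq[j] for j in keep)) for r in aln.records
        )
    )


def summarize_distances(
    dm: DistanceMatrix, pairs: set[tuple[str, str]] | list[tuple[str, str]]
) -> dict:
    """Mean/min/max JC distance over selected label pairs.

    Returns both proportion and percent forms. Undefined (saturated) pairs
    in the selection are an error listing the offending pairs.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no pairs selected")
    bad = [p for p in pairs if not dm.is_defined(*p)]
    if bad:
        raise ValueError(f"undefined distances for pairs: {bad}")
    vals = [dm[p] for p in pairs]
    return {
        "mean": float(np.mean(vals)),
        "min": float(np.min(vals)),
        "max": float(np.max(vals)),
        "mean_pct": float(np.mean(vals)) * 100.0,
        "min_pct": float(np.min(vals)) * 100.0,
        "max_pct": float(np.max(vals)) * 100.0,
        "n_pairs": len(vals),
    }


def summarize_values(values: list[float]) -> dict:
    """Mean/min/max summary of an already-extracted distance list."""
    if not values:
        raise ValueError("no distances to summarise")
    if any(v < 0 or not math.isfinite(v) for v in values):
        raise ValueError("distances must be finite and nonnegative")
    return {
        "mean": float(np.mean(values)),
        "min": float(np.min(values)),
        "max": float(np.max(values)),
        "n": len(values),
    }
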