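"""Readers, writers and configuration for the HTT detection pipeline.

External formats handled here: FASTA (sequences, via Biopython), newick
(trees, via dendropy), 12-column tab-separated similarity-search hit tables
(the standard tabular output of BLAST-like tools), and YAML configuration.

Coordinate convention: hit tables carry 1-based inclusive coordinates (the
search-tool convention); they are normalised so ``subject_start <=
subject_end`` with the original orientation recorded in ``strand``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable

import dendropy
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("httdetect")

_VALID = set("ACGTN-")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over the alphabet {A,C,G,T,N,-}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)

    def ungapped(self) -> str:
        return self.seq.replace("-", "")


@dataclass(frozen=True)
class Alignment:
    """An ordered list of equal-length sequence records."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment has no records")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths in alignment: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def column(self, j: int) -> list[str]:
        return [r.seq[j] for r in self.records]


@dataclass(frozen=True)
class HitRecord:
    """One row of a tabular similarity-search output.

    ``subject_start <= subject_end`` always holds; a hit reported on the
    reverse strand has its coordinates swapped and ``strand == '-'``.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    subject_start: int
    subject_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.aln_length < 1:
            raise ValueError("alignment length must be >= 1")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("percent identity must be in [0, 100]")
        if self.subject_start > self.subject_end:
            raise ValueError("subject_start must be <= subject_end after normalisation")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and rates applied across the pipeline.

    Defaults: hits are retained above 90% identity over more than 500 bp;
    consensus columns need at least 5 supporting copies; alignment columns
    missing in more than 25% of sequences are trimmed; the neutral
    substitution rate is the Drosophila melanogaster estimate of 0.0346
    substitutions/site/myr.
    """

    min_identity: float = 90.0
    min_hit_length: int = 500
    min_consensus_depth: int = 5
    max_missing_fraction: float = 0.25
    neutral_rate: float = 0.0346
    min_margin: float = 0.0
    gap_deletion: str = "pairwise"  # or "complete"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_hit_length", "min_consensus_depth", "neutral_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 <= self.max_missing_fraction < 1:
            raise ValueError("max_missing_fraction must be in [0, 1)")
        if self.gap_deletion not in {"pairwise", "complete"}:
            raise ValueError("gap_deletion must be 'pairwise' or 'complete'")

    def log_thresholds(self) -> None:
        for f in fields(self):
            logger.info("config %s = %r", f.name, getattr(self, f.name))


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from an optional YAML file plus overrides."""
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**values)


def _clean_seq(raw: str, where: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _VALID
    if bad:
        # IUPAC ambiguity codes other than N carry no usable signal under JC
        seq = "".join(c if c in _VALID else "N" for c in seq)
        logger.debug("%s: mapped ambiguity codes %s to N", where, sorted(bad))
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    Sequences are uppercased, U is mapped to T and ambiguity codes other
    than N are mapped to N. Record order is preserved. Duplicate ids and
    empty files are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, _clean_seq(str(rec.seq), rec.id)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_alignment(path: str | Path) -> Alignment:
    """Read a FASTA file that must contain equal-length (aligned) sequences."""
    return Alignment(tuple(read_fasta(path)))


def read_newick(path_or_string: str | Path) -> dendropy.Tree:
    """Parse a single newick tree from a file path or a literal string.

    Leaf labels must be unique. The rooted/unrooted state is taken from the
    newick string (``[&R]``/``[&U]`` hints honoured; default unrooted).
    """
    s = str(path_or_string)
    if s.lstrip().startswith("(") or s.rstrip().endswith(";"):
        src = {"data": s}
    else:
        src = {"path": s}
    try:
        tree = dendropy.Tree.get(schema="newick", preserve_underscores=True, **src)
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"newick parse error: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate leaf labels: {dupes}")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    """Serialise a tree, keeping the rooted/unrooted state as an annotation."""
    s = tree.as_string(schema="newick", unquoted_underscores=True)
    s = s.strip() + "\n"
    if path is not None:
        Path(path).write_text(s)
    return s


def read_hits_table(path: str | Path) -> list[HitRecord]:
    """Read a 12-column tab-separated hit table (qid sid %id len mism gapo
    qstart qend sstart send evalue bits).

    Subject coordinates are normalised to start <= end; a reversed pair is
    recorded as a minus-strand hit.
    """
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(cols)}"
                )
            q, s = cols[0], cols[1]
            pid = float(cols[2])
            alen = int(cols[3])
            sstart, send = int(cols[8]), int(cols[9])
            strand = "+"
            if sstart > send:
                sstart, send = send, sstart
                strand = "-"
            hits.append(HitRecord(q, s, pid, alen, sstart, send, strand))
    if not hits:
        logger.warning("hit table %s contains no hits", path)
    return hits


__all__ = [
    "SequenceRecord",
    "Alignment",
    "HitRecord",
    "PipelineConfig",
    "load_config",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "read_newick",
    "write_newick",
    "read_hits_table",
]
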