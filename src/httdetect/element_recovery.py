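"""TE family recovery: hit filtering, consensus building and element anatomy.

A family consensus is the per-column plurality over aligned copies, with a
coverage requirement: a column enters the consensus only if at least
``min_depth`` copies carry an informative residue there (gaps and N are
non-informative). Anatomy checks cover the Tc1/Mariner hallmarks — terminal
inverted repeats (TIRs), TA target-site duplications (TSDs) and an intact
transposase open reading frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .io_formats import Alignment, HitRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_STOPS = {"TAA", "TAG", "TGA"}
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class OrfHit:
    """Longest ATG..stop open reading frame found over the six frames."""

    aa_length: int
    frame: int  # 0, 1, 2 offset within the scanned strand
    strand: str  # '+' or '-'
    start: int  # 0-based nt start of the ATG on the scanned strand
    is_intact: bool


@dataclass(frozen=True)
class ConsensusElement:
    """A reconstructed TE family consensus plus structural annotation."""

    name: str
    seq: str
    depth_profile: tuple[int, ...]
    tir: Optional[tuple[int, int]]  # (length bp, mismatches)
    tsd_is_TA: Optional[bool]
    longest_orf_aa: int
    orf_intact: bool
    orf: Optional[OrfHit] = None

    def __post_init__(self) -> None:
        if len(self.depth_profile) != len(self.seq):
            raise ValueError("depth profile length must equal consensus length")
        if self.longest_orf_aa < 0:
            raise ValueError("ORF length must be >= 0")
        if self.tir is not None and self.tir[0] < 0:
            raise ValueError("TIR length must be >= 0")

    def __len__(self) -> int:
        return len(self.seq)


def filter_hits(
    hits: list[HitRecord], min_identity: float = 90.0, min_hit_length: int = 500
) -> list[HitRecord]:
    """Keep hits with more than ``min_identity`` percent identity over more
    than ``min_hit_length`` bp; both comparisons are strict. Order preserved."""
    if min_identity <= 0 or min_hit_length <= 0:
        raise ValueError("filter thresholds must be strictly positive")
    return [
        h
        for h in hits
        if h.pct_identity > min_identity and h.aln_length > min_hit_length
    ]


def build_consensus(
    copies: Alignment,
    min_depth: int = 5,
    name: str = "consensus",
    flanks: Optional[tuple[str, str]] = None,
    tir_min_len: int = 10,
    tir_max_mismatch: int = 0,
) -> ConsensusElement:
    """Plurality consensus over aligned copies with per-column coverage.

    Per column, depth counts non-gap, non-N residues; columns with depth
    below ``min_depth`` are excluded, so the whole reported consensus is
    covered by at least ``min_depth`` different copies. Plurality ties break
    by fixed residue order A < C < G < T for determinism. The consensus is
    gap-free by construction. ``flanks`` are the 2-nt host sequences
    immediately outside the element, used for the TSD check when available.
    """
    if len(copies) < min_depth:
        raise ValueError(
            f"need at least {min_depth} copies, got {len(copies)}"
        )
    seq_chars: list[str] = []
    depths: list[int] = []
    for j in range(copies.length):
        col = copies.column(j)
        counts = {"A": 0, "C": 0, "G": 0, "T": 0}
        for c in col:
            if c in counts:
                counts[c] += 1
        depth = sum(counts.values())
        if depth < min_depth:
            continue
        # max() on dict items resolves ties by the fixed A<C<G<T key order
        best = max("ACGT", key=lambda b: counts[b])
        seq_chars.append(best)
        depths.append(depth)
    if not seq_chars:
        raise ValueError("insufficient coverage: no column reaches min_depth")
    seq = "".join(seq_chars)
    tir = (
        detect_tirs(seq, min_len=tir_min_len, max_mismatch=tir_max_mismatch)
        if len(seq) >= 2 * tir_min_len
        else None
    )
    orf = find_longest_orf(seq)
    tsd = check_tsd(*flanks) if flanks is not None else None
    return ConsensusElement(
        name=name,
        seq=seq,
        depth_profile=tuple(depths),
        tir=tir,
        tsd_is_TA=tsd,
        longest_orf_aa=orf.aa_length,
        orf_intact=orf.is_intact,
        orf=orf,
    )


def detect_tirs(
    seq: str, min_len: int = 10, max_mismatch: int = 0
) -> Optional[tuple[int, int]]:
    """Longest terminal inverted repeat, ungapped and end-anchored.

    Returns ``(length, mismatches)`` for the longest prefix whose reverse
    complement matches the suffix with at most ``max_mismatch`` mismatches,
    or None when no match of at least ``min_len`` bp exists. N never counts
    as a match.
    """
    if len(seq) < 2 * min_len:
        raise ValueError(f"sequence shorter than twice min_len ({min_len})")
    best: Optional[tuple[int, int]] = None
    for length in range(min_len, len(seq) // 2 + 1):
        prefix = seq[:length]
        tail_rc = revcomp(seq[-length:])
        mism = sum(
            1 for a, b in zip(prefix, tail_rc) if a != b or a == "N"
        )
        if mism <= max_mismatch:
            best = (length, mism)
    return best


def check_tsd(left_flank: str, right_flank: str) -> bool:
    """True iff both 2-nt flanks are the TA target-site duplication."""
    return left_flank.upper() == "TA" and right_flank.upper() == "TA"


def _translate_codon(codon: str) -> str:
    if "N" in codon or "-" in codon or len(codon) < 3:
        return "X"
    return _CODON_TABLE.get(codon, "X")


def find_longest_orf(seq: str) -> OrfHit:
    """Longest ATG-to-stop open reading frame over all six frames.

    The amino-acid length excludes the stop codon. Codons containing N
    translate to X, never to a stop, so missing data cannot truncate an
    ORF. With no ATG..stop anywhere, length 0 is reported.
    """
    best = OrfHit(0, 0, "+", 0, False)
    for strand in ("+", "-"):
        s = seq if strand == "+" else revcomp(seq)
        for frame in range(3):
            start: Optional[int] = None
            for pos in range(frame, len(s) - 2, 3):
                codon = s[pos : pos + 3]
                if start is None:
                    if codon == "ATG":
                        start = pos
                    continue
                if codon in _STOPS:
                    aa = (pos - start) // 3
                    if aa > best.aa_length:
                        best = OrfHit(aa, frame, strand, start, True)
                    start = None
    return best


def copy_orf_is_intact(copy_seq: str, consensus_orf: OrfHit, orf_nt_span: int) -> bool:
    """Assess a copy's transposase intactness in the consensus-defined frame.

    The copy (in element orientation, aligned to consensus coordinates) is
    translated from the consensus ORF start over the consensus ORF span; it
    is intact iff no premature stop appears before the final codon.
    """
    s = copy_seq if consensus_orf.strand == "+" else revcomp(copy_seq)
    region = s[consensus_orf.start : consensus_orf.start + orf_nt_span]
    ungapped = region.replace("-", "")
    codons = [ungapped[i : i + 3] for i in range(0, len(ungapped) - 2, 3)]
    if not codons:
        return False
    internal = codons[:-1]
    return all(c not in _STOPS for c in internal)
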