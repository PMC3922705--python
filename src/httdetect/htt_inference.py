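"""The vertical-inheritance null test and burst-age dating.

Under vertical transmission a TE evolves neutrally after insertion, i.e. at
least as fast as host genes under purifying selection, so between-taxon TE
distances should be at least as large as orthologous-gene distances. A TE
whose between-taxon distances all fall strictly below every gene distance
violates that null and is called horizontally transferred (HT). The verdict
uses strict range separation — max(TE) < min(genes) — the most conservative
reading of the evidence; a Mann–Whitney U statistic between the two lists is
reported as supporting context only, never as the verdict, because gene
distances are not exchangeable samples.

Burst age: a family's amplification age is the mean copy-to-consensus
JC distance divided by a neutral substitution rate (substitutions/site/myr).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

from scipy import stats

from .distances import (
    SaturatedDistanceError,
    jc69_distance,
    p_distance,
    summarize_values,
)
from .element_recovery import ConsensusElement
from .io_formats import Alignment, SequenceRecord

logger = logging.getLogger("httdetect")

HT = "HT"
VERTICAL = "vertical-compatible"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class HTTCall:
    """Verdict of the vertical-inheritance test for one family and taxon pair."""

    te_family: str
    taxon_pair: tuple[str, str]
    te_dist_summary: dict
    gene_dist_summary: dict
    n_genes: int
    verdict: str
    margin: float  # min(gene) - max(TE), substitutions/site
    mannwhitney_u: Optional[float] = None
    mannwhitney_p: Optional[float] = None

    def __post_init__(self) -> None:
        if self.verdict == HT and self.margin <= 0:
            raise ValueError("HT verdict requires positive margin")
        if self.n_genes < 1:
            raise ValueError("need at least one gene distance")


@dataclass(frozen=True)
class BurstAgeEstimate:
    """Age of a TE amplification burst from copy/consensus divergence."""

    te_family: str
    species: str
    mean_copy_consensus_dist: float  # substitutions/site
    neutral_rate: float  # substitutions/site/myr
    age: float  # myr
    n_copies_used: int = 0
    n_copies_excluded: int = 0

    def __post_init__(self) -> None:
        if self.age < 0 or self.mean_copy_consensus_dist < 0:
            raise ValueError("distances and ages must be nonnegative")
        expected = self.mean_copy_consensus_dist / self.neutral_rate
        if not math.isclose(self.age, expected, rel_tol=1e-9):
            raise ValueError("age must equal mean distance / neutral rate")

    @property
    def age_2sf(self) -> float:
        """Age rounded to 2 significant figures for human reports."""
        if self.age == 0:
            return 0.0
        from math import floor, log10

        return round(self.age, -int(floor(log10(abs(self.age)))) + 1)


def vertical_null_test(
    te_dists: list[float],
    gene_dists: list[float],
    te_family: str = "TE",
    taxon_pair: tuple[str, str] = ("A", "B"),
    min_margin: float = 0.0,
) -> HTTCall:
    """Test a TE's between-taxon distances against the vertical null.

    Verdict HT iff max(te) < min(genes) with margin above ``min_margin``;
    vertical-compatible iff min(te) >= min(genes); otherwise indeterminate
    (overlapping ranges).
    """
    for name, vals in (("TE", te_dists), ("gene", gene_dists)):
        if not vals:
            raise ValueError(f"empty {name} distance list")
        if any(v < 0 or not math.isfinite(v) for v in vals):
            raise ValueError(f"negative or undefined {name} distance")
    te_sum = summarize_values(list(te_dists))
    gene_sum = summarize_values(list(gene_dists))
    margin = gene_sum["min"] - te_sum["max"]
    if margin > min_margin:
        verdict = HT
    elif te_sum["min"] >= gene_sum["min"]:
        verdict = VERTICAL
    else:
        verdict = INDETERMINATE
    u = p = None
    if len(te_dists) >= 2 and len(gene_dists) >= 2:
        res = stats.mannwhitneyu(te_dists, gene_dists, alternative="less")
        u, p = float(res.statistic), float(res.pvalue)
    return HTTCall(
        te_family=te_family,
        taxon_pair=taxon_pair,
        te_dist_summary=te_sum,
        gene_dist_summary=gene_sum,
        n_genes=len(gene_dists),
        verdict=verdict,
        margin=margin,
        mannwhitney_u=u,
        mannwhitney_p=p,
    )


def copy_consensus_divergence(
    copies: Alignment, consensus: ConsensusElement | SequenceRecord | str
) -> tuple[float, int, int]:
    """Mean JC distance of each copy to the family consensus.

    Copies must be aligned to consensus coordinates. Saturated copies are
    excluded with a warning. Returns ``(mean, n_used, n_excluded)``.
    """
    if isinstance(consensus, ConsensusElement):
        cons = SequenceRecord(consensus.name, consensus.seq)
    elif isinstance(consensus, str):
        cons = SequenceRecord("consensus", consensus)
    else:
        cons = consensus
    dists: list[float] = []
    excluded = 0
    for rec in copies:
        p, _ = p_distance(rec, cons)
        try:
            dists.append(jc69_distance(p))
        except SaturatedDistanceError:
            excluded += 1
            logger.warning("copy %s saturated vs consensus; excluded", rec.id)
    if not dists:
        raise ValueError("all copies saturated against the consensus")
    return sum(dists) / len(dists), len(dists), excluded


def burst_age(
    mean_dist: float,
    neutral_rate: float,
    te_family: str = "TE",
    species: str = "",
    n_copies_used: int = 0,
    n_copies_excluded: int = 0,
) -> BurstAgeEstimate:
    """Date a TE amplification burst: age = mean copy/consensus distance
    divided by the neutral substitution rate.

    No neutral rate is known for isopods; callers must supply a rate
    explicitly for such lineages (there is no silent default here).
    """
    if neutral_rate <= 0:
        raise ValueError("neutral rate must be strictly positive")
    if mean_dist < 0:
        raise ValueError("mean distance must be nonnegative")
    return BurstAgeEstimate(
        te_family=te_family,
        species=species,
        mean_copy_consensus_dist=mean_dist,
        neutral_rate=neutral_rate,
        age=mean_dist / neutral_rate,
        n_copies_used=n_copies_used,
        n_copies_excluded=n_copies_excluded,
    )
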