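"""Truth-scored validation runs: simulate a scenario, run the inference.

These helpers wire the generator straight into the detection operations so
calibration experiments (sensitivity of the HT call, false-positive rate
under vertical inheritance, burst-age parameter recovery) can be scripted
without touching the filesystem.
"""

from __future__ import annotations

import numpy as np

from .distances import pairwise_matrix
from .element_recovery import build_consensus
from .htt_inference import (
    HTTCall,
    burst_age,
    copy_consensus_divergence,
    vertical_null_test,
)
from .io_formats import Alignment, SequenceRecord
from .synthetic_data import TransferScenario, inject_te_history, simulate_genes


def scenario_verdict(
    scenario: TransferScenario, taxon_pair: tuple[str, str] = ("sp1", "sp2")
) -> HTTCall:
    """Simulate one scenario and run the vertical-null test on a taxon pair.

    TE evidence is the JC distance between the two species' reconstructed
    family consensuses; gene evidence is the per-gene JC distance list.
    """
    a, b = taxon_pair
    copies, _ = inject_te_history(scenario)
    cons = {
        sp: build_consensus(
            copies[sp], min_depth=min(5, len(copies[sp])), name=sp
        )
        for sp in (a, b)
    }
    dm = pairwise_matrix(
        Alignment((SequenceRecord(a, cons[a].seq), SequenceRecord(b, cons[b].seq)))
    )
    gene_dists = []
    for aln in simulate_genes(scenario).values():
        gdm = pairwise_matrix(aln)
        if gdm.is_defined(a, b):
            gene_dists.append(gdm[a, b])
    return vertical_null_test(
        [dm[a, b]], gene_dists, te_family=scenario.te_family, taxon_pair=(a, b)
    )


def verdict_rate(
    make_scenario, n_replicates: int, base_seed: int, verdict: str = "HT"
) -> float:
    """Fraction of replicates whose call matches ``verdict``.

    ``make_scenario(seed)`` builds the per-replicate scenario; replicate
    seeds are derived deterministically from ``base_seed``."""
    seeds = np.random.SeedSequence(base_seed).generate_state(n_replicates) % (2**31)
    hits = sum(
        scenario_verdict(make_scenario(int(s))).verdict == verdict for s in seeds
    )
    return hits / n_replicates


def recover_burst_age(
    scenario: TransferScenario, species: str = "sp1", neutral_rate: float = 0.0346
):
    """Simulate a burst and date it back from the copies alone.

    Returns (estimate, standard_error_myr) where the SE is over per-copy
    age estimates."""
    from .distances import jc69_distance, p_distance

    copies, _ = inject_te_history(scenario)
    cons = build_consensus(copies[species], min_depth=min(5, len(copies[species])))
    mean_d, n_used, n_exc = copy_consensus_divergence(copies[species], cons)
    est = burst_age(
        mean_d, neutral_rate, species=species,
        n_copies_used=n_used, n_copies_excluded=n_exc,
    )
    per_copy = []
    cons_rec = SequenceRecord("cons", cons.seq)
    for r in copies[species]:
        p, _ = p_distance(r, cons_rec)
        per_copy.append(jc69_distance(p) / neutral_rate)
    se = float(np.std(per_copy, ddof=1) / np.sqrt(len(per_copy)))
    return est, se
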