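"""End-to-end orchestration: dataset directory in, JSON + TSV report out.

Expected dataset layout (what :func:`httdetect.synthetic_data.generate_dataset`
emits, and what real analyses should mirror):

    species_tree.nwk            rooted newick, branch lengths in myr
    genes/<gene>.fasta          aligned orthologs, one sequence per species
    te/<family>/<species>.fasta aligned TE copies, element orientation
    presence.tsv                species x family presence/absence

All TE copies of a family, across species, must share one coordinate
system (aligned to the family consensus). Reported distances are
substitutions/site (proportions); percent only in the TSV. Output is a pure
function of (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .distances import pairwise_matrix, summarize_values, trim_columns
from .element_recovery import build_consensus
from .htt_inference import burst_age, copy_consensus_divergence, vertical_null_test
from .io_formats import (
    Alignment,
    PipelineConfig,
    SequenceRecord,
    read_alignment,
    read_fasta,
    read_newick,
)
from .phylo_concordance import (
    PresenceMatrix,
    copy_monophyly,
    dollo_min_losses,
    nj_tree,
    rf_distance,
)

logger = logging.getLogger("httdetect")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        return wrapper

    return deco


@_stage("load")
def _load_dataset(dataset_dir: Path) -> dict:
    tree = read_newick(dataset_dir / "species_tree.nwk")
    tree.is_rooted = True
    presence = PresenceMatrix.from_tsv(dataset_dir / "presence.tsv")
    presence.validate_against(tree)
    genes = {
        p.stem: read_alignment(p) for p in sorted((dataset_dir / "genes").glob("*.fasta"))
    }
    families: dict[str, dict[str, Alignment]] = {}
    te_dir = dataset_dir / "te"
    if te_dir.is_dir():
        for fam_dir in sorted(p for p in te_dir.iterdir() if p.is_dir()):
            families[fam_dir.name] = {
                p.stem: Alignment(tuple(read_fasta(p)))
                for p in sorted(fam_dir.glob("*.fasta"))
            }
    if not genes:
        raise ValueError("no gene alignments found")
    if not families:
        raise ValueError("no TE copy files found")
    return {"tree": tree, "presence": presence, "genes": genes, "families": families}


@_stage("consensus")
def _build_consensuses(families, config: PipelineConfig) -> dict:
    out: dict[str, dict[str, dict]] = {}
    for fam, per_sp in families.items():
        out[fam] = {}
        for sp, copies in per_sp.items():
            depth = min(config.min_consensus_depth, len(copies))
            if depth < config.min_consensus_depth:
                logger.warning(
                    "%s/%s: only %d copies (< %d); consensus flagged low coverage",
                    fam, sp, len(copies), config.min_consensus_depth,
                )
            cons = build_consensus(copies, min_depth=depth, name=f"{fam}_{sp}")
            out[fam][sp] = {
                "consensus": cons,
                "copies": copies,
                "low_coverage": depth < config.min_consensus_depth,
            }
    return out


@_stage("distances")
def _gene_pair_distances(genes, config: PipelineConfig) -> dict:
    """Per species pair, the list of per-gene JC distances."""
    per_pair: dict[tuple[str, str], list[float]] = {}
    for gname, aln in genes.items():
        trimmed = trim_columns(aln, config.max_missing_fraction)
        dm = pairwise_matrix(trimmed, gap_deletion=config.gap_deletion)
        labs = dm.labels
        for i, a in enumerate(labs):
            for b in labs[i + 1:]:
                if dm.is_defined(a, b):
                    per_pair.setdefault(tuple(sorted((a, b))), []).append(dm[a, b])
                else:
                    logger.warning("gene %s pair (%s,%s) saturated; skipped", gname, a, b)
    return per_pair


@_stage("httcall")
def _htt_calls(consensuses, gene_pair_dists, config: PipelineConfig) -> list:
    calls = []
    for fam, per_sp in consensuses.items():
        species = sorted(per_sp)
        for i, a in enumerate(species):
            for b in species[i + 1:]:
                ca = per_sp[a]["consensus"]
                cb = per_sp[b]["consensus"]
                pair_aln = Alignment(
                    (SequenceRecord(a, ca.seq), SequenceRecord(b, cb.seq))
                )
                dm = pairwise_matrix(pair_aln)
                if not dm.is_defined(a, b):
                    logger.warning("%s (%s,%s): TE distance saturated", fam, a, b)
                    continue
                genes = gene_pair_dists.get(tuple(sorted((a, b))))
                if not genes:
                    logger.warning("%s (%s,%s): no gene distances", fam, a, b)
                    continue
                calls.append(
                    vertical_null_test(
                        [dm[a, b]], genes, te_family=fam, taxon_pair=(a, b),
                        min_margin=config.min_margin,
                    )
                )
    return calls


@_stage("date-burst")
def _burst_ages(consensuses, config: PipelineConfig) -> list:
    ages = []
    for fam, per_sp in consensuses.items():
        for sp, rec in sorted(per_sp.items()):
            mean_d, n_used, n_exc = copy_consensus_divergence(
                rec["copies"], rec["consensus"]
            )
            ages.append(
                burst_age(
                    mean_d, config.neutral_rate, te_family=fam, species=sp,
                    n_copies_used=n_used, n_copies_excluded=n_exc,
                )
            )
    return ages


@_stage("concordance")
def _concordance(tree, presence: PresenceMatrix, consensuses) -> list:
    reports = []
    n_leaves = len(presence.species)
    for fam in presence.te_families:
        pres = presence.presence(fam)
        gains, losses = dollo_min_losses(tree, pres)
        entry = {
            "family": fam,
            "dollo_gains": gains,
            "dollo_losses": losses,
            "n_present_species": sum(pres.values()),
            "n_species": n_leaves,
        }
        per_sp = consensuses.get(fam, {})
        # pooled copy tree across species for monophyly
        all_copies = []
        species_of_copy = {}
        for sp, rec in sorted(per_sp.items()):
            for r in rec["copies"]:
                all_copies.append(r)
                species_of_copy[r.id] = sp
        if len(all_copies) >= 4:
            dm = pairwise_matrix(Alignment(tuple(all_copies)))
            if not dm.undefined_pairs():
                copy_tree = nj_tree(dm)
                mono = copy_monophyly(copy_tree, species_of_copy)
                entry.update(
                    n_monophyletic_species=mono["n_monophyletic"],
                    n_species_with_multiple_copies=mono["n_species_with_multiple_copies"],
                    monophyly=mono["monophyly"],
                )
        # species-level TE tree vs host tree (carriers only)
        carriers = sorted(per_sp)
        if len(carriers) >= 4:
            cons_aln = Alignment(
                tuple(SequenceRecord(sp, per_sp[sp]["consensus"].seq) for sp in carriers)
            )
            dm = pairwise_matrix(cons_aln)
            if not dm.undefined_pairs():
                te_tree = nj_tree(dm)
                host_sub = tree.extract_tree_with_taxa_labels(carriers)
                rf, max_rf = rf_distance(te_tree, host_sub)
                entry.update(rf_distance=rf, max_rf=max_rf)
        reports.append(entry)
    return reports


def run_pipeline(
    config: PipelineConfig, dataset_dir: str | Path, out_dir: str | Path
) -> dict:
    """Run every analysis stage on a dataset directory.

    Writes ``report.json`` (machine) and ``report.tsv`` (human) under
    ``out_dir`` and returns the report dict. Any stage failure raises
    :class:`PipelineError` naming the stage and cause.
    """
    dataset_dir = Path(dataset_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.log_thresholds()

    data = _load_dataset(dataset_dir)
    consensuses = _build_consensuses(data["families"], config)
    gene_pair_dists = _gene_pair_distances(data["genes"], config)
    calls = _htt_calls(consensuses, gene_pair_dists, config)
    ages = _burst_ages(consensuses, config)
    concordance = _concordance(data["tree"], data["presence"], consensuses)

    report = {
        "httdetect_version": __version__,
        "config": {
            "min_identity": config.min_identity,
            "min_hit_length": config.min_hit_length,
            "min_consensus_depth": config.min_consensus_depth,
            "max_missing_fraction": config.max_missing_fraction,
            "neutral_rate": config.neutral_rate,
            "min_margin": config.min_margin,
            "gap_deletion": config.gap_deletion,
            "rng_seed": config.rng_seed,
        },
        "coordinate_convention": "1-based inclusive in hit tables; internal 0-based half-open",
        "consensus": {
            fam: {
                sp: {
                    "length": len(rec["consensus"]),
                    "min_depth": min(rec["consensus"].depth_profile),
                    "tir": rec["consensus"].tir,
                    "longest_orf_aa": rec["consensus"].longest_orf_aa,
                    "orf_intact": rec["consensus"].orf_intact,
                    "n_copies": len(rec["copies"]),
                    "low_coverage": rec["low_coverage"],
                }
                for sp, rec in sorted(per_sp.items())
            }
            for fam, per_sp in consensuses.items()
        },
        "gene_distance_summary": {
            "|".join(pair): summarize_values(vals)
            for pair, vals in sorted(gene_pair_dists.items())
        },
        "htt_calls": [
            {
                "te_family": c.te_family,
                "taxon_pair": list(c.taxon_pair),
                "verdict": c.verdict,
                "margin": c.margin,
                "te_dist": c.te_dist_summary,
                "gene_dist": c.gene_dist_summary,
                "n_genes": c.n_genes,
            }
            for c in calls
        ],
        "burst_ages": [
            {
                "te_family": a.te_family,
                "species": a.species,
                "mean_copy_consensus_dist": a.mean_copy_consensus_dist,
                "neutral_rate": a.neutral_rate,
                "age_myr": a.age,
                "age_myr_2sf": a.age_2sf,
                "n_copies_used": a.n_copies_used,
                "n_copies_excluded": a.n_copies_excluded,
            }
            for a in ages
        ],
        "concordance": concordance,
    }

    (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    _write_tsv(report, out_dir / "report.tsv")
    return report


def _write_tsv(report: dict, path: Path) -> None:
    rows = []
    for c in report["htt_calls"]:
        rows.append(
            {
                "section": "htt_call",
                "family": c["te_family"],
                "taxa": "|".join(c["taxon_pair"]),
                "verdict": c["verdict"],
                "margin_pct": round(c["margin"] * 100, 2),
                "te_mean_pct": round(c["te_dist"]["mean"] * 100, 2),
                "gene_mean_pct": round(c["gene_dist"]["mean"] * 100, 2),
            }
        )
    for a in report["burst_ages"]:
        rows.append(
            {
                "section": "burst_age",
                "family": a["te_family"],
                "taxa": a["species"],
                "verdict": "",
                "margin_pct": "",
                "te_mean_pct": round(a["mean_copy_consensus_dist"] * 100, 2),
                "gene_mean_pct": "",
                "age_myr": a["age_myr_2sf"],
            }
        )
    for e in report["concordance"]:
        rows.append(
            {
                "section": "concordance",
                "family": e["family"],
                "taxa": "",
                "verdict": "",
                "dollo_losses": e["dollo_losses"],
                "rf": e.get("rf_distance", ""),
                "max_rf": e.get("max_rf", ""),
            }
        )
    pd.DataFrame(rows).fillna("").to_csv(path, sep="\t", index=False)
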