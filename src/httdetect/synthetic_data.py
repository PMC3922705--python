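"""Synthetic datasets with known TE transfer histories.

The generator emulates the statistical structure the HTT analysis assumes:

* a dated (ultrametric, myr-scaled) host species tree;
* orthologous genes evolving under purifying selection, modelled as
  Jukes–Cantor substitution at a purifying-scaled fraction of the neutral
  rate;
* TE copies evolving neutrally (full rate) from their insertion onward;
* explicit vertical inheritance and user-specified horizontal transfer
  events (donor, recipient, time), plus per-species amplification bursts
  producing star-like copy families around the ancestral element.

All randomness flows from the single scenario seed; an identical scenario
yields byte-identical output.

Element lineages are traced backward through the host tree: a lineage
follows its host lineage toward the root, jumping from recipient to donor
when it crosses a horizontal-transfer receipt point, until it reaches the
insertion event that created the family. Pairwise element divergence times
(first meeting of two traces) are ultrametric by construction, which lets
the element genealogy be rebuilt exactly and sequences be simulated along
it.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
import yaml

from .io_formats import Alignment, SequenceRecord, write_fasta, write_newick

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
NEUTRAL_RATE_DMEL = 0.0346  # substitutions/site/myr, D. melanogaster


# ---------------------------------------------------------------------------
# low-level sequence evolution


def random_seq(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def seq_to_str(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


def str_to_seq(s: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    arr = lut[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return arr


def jc_evolve(
    seq: np.ndarray, rate: float, time: float, rng: np.random.Generator
) -> np.ndarray:
    """Evolve a sequence for ``time`` myr at ``rate`` subs/site/myr under JC69.

    The per-site probability of observing a different base after branch
    length d = rate*time is (3/4)(1 - exp(-4d/3)); changed sites move
    uniformly to one of the three other bases.
    """
    d = rate * time
    if d < 0:
        raise ValueError("negative branch length")
    p_change = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
    out = seq.copy()
    mask = rng.random(seq.size) < p_change
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
    return out


def k80_evolve(
    seq: np.ndarray, rate: float, time: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Kimura two-parameter variant (transition/transversion bias hook)."""
    d = rate * time
    k = kappa
    # K80 closed-form substitution probabilities at total distance d
    a = 2.0 * d / (k + 2.0)  # transversion-class exponent scale
    p_ts = 0.25 + 0.25 * math.exp(-2.0 * a) - 0.5 * math.exp(-(k + 1.0) * a)
    p_tv = 0.25 - 0.25 * math.exp(-2.0 * a)  # each of the two transversions
    u = rng.random(seq.size)
    out = seq.copy()
    # base coding A=0 C=1 G=2 T=3; transition partner: A<->G, C<->T
    transition = np.array([2, 3, 0, 1], dtype=np.uint8)
    tv1 = np.array([1, 0, 1, 0], dtype=np.uint8)
    tv2 = np.array([3, 2, 3, 2], dtype=np.uint8)
    m_ts = u < p_ts
    m_tv1 = (u >= p_ts) & (u < p_ts + p_tv)
    m_tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    out[m_ts] = transition[seq[m_ts]]
    out[m_tv1] = tv1[seq[m_tv1]]
    out[m_tv2] = tv2[seq[m_tv2]]
    return out


# ---------------------------------------------------------------------------
# species tree


def simulate_species_tree(
    n_species: int, depth_myr: float, seed: int | np.random.Generator = 0
) -> dendropy.Tree:
    """Pure-birth (Yule) tree rescaled so every root-to-tip path equals
    ``depth_myr``; leaves are labelled sp1..spN in birth order."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace([f"sp{i+1}" for i in range(n_species)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    # forward simulation: the root splits at time 0, later splits accumulate
    # exponential waits, then everything is rescaled to the requested depth
    root = tree.seed_node
    root.time = 0.0
    tips = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        tips.append(child)
    t = 0.0
    while len(tips) < n_species:
        t += rng.exponential(1.0 / len(tips))
        idx = int(rng.integers(len(tips)))
        nd = tips.pop(idx)
        nd.time = t
        for _ in range(2):
            child = dendropy.Node()
            nd.add_child(child)
            tips.append(child)
    t_end = t + rng.exponential(1.0 / len(tips))
    scale = depth_myr / t_end
    for i, nd in enumerate(tips):
        nd.time = t_end
        nd.taxon = taxa.get_taxon(f"sp{i+1}")
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = (nd.time - nd.parent_node.time) * scale
    tree.is_rooted = True
    return tree


def node_ages(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Ages (myr above the tips) for an ultrametric tree."""
    ages: dict[dendropy.Node, float] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            ages[nd] = 0.0
        else:
            child_ages = [ages[c] + (c.edge.length or 0.0) for c in nd.child_nodes()]
            if max(child_ages) - min(child_ages) > 1e-6 * max(max(child_ages), 1.0):
                raise ValueError("species tree must be ultrametric (myr-dated)")
            ages[nd] = sum(child_ages) / len(child_ages)
    return ages


def evolve_sequence(
    tree: dendropy.Tree,
    root_seq: np.ndarray | str,
    rate: float,
    seed: int | np.random.Generator = 0,
    kappa: Optional[float] = None,
) -> Alignment:
    """Simulate substitution along a tree; returns the ungapped leaf alignment.

    Branch lengths are interpreted in myr and multiplied by ``rate``
    (subs/site/myr). Pure JC69 by default; ``kappa`` switches on a
    transition/transversion bias (K80) for robustness experiments.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = root_seq if isinstance(root_seq, np.ndarray) else str_to_seq(root_seq)
    states: dict[dendropy.Node, np.ndarray] = {tree.seed_node: root}
    records = []
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            t = nd.edge.length or 0.0
            parent_state = states[nd.parent_node]
            if kappa is None:
                states[nd] = jc_evolve(parent_state, rate, t, rng)
            else:
                states[nd] = k80_evolve(parent_state, rate, t, kappa, rng)
        if nd.is_leaf():
            records.append(SequenceRecord(nd.taxon.label, seq_to_str(states[nd])))
    return Alignment(tuple(records))


# ---------------------------------------------------------------------------
# transfer scenarios


@dataclass
class TransferScenario:
    """Ground-truth description of a simulated TE history.

    Times are myr before present; the species tree must be ultrametric with
    branch lengths in myr. ``insertions`` places the element on the lineage
    of a named species at a given age; ``ht_events`` copies the donor
    lineage's element state into the recipient lineage at the event age.
    ``gene_rate_scaling`` (scalar or (low, high) range sampled per gene)
    models purifying selection as a deterministic rate multiplier.
    """

    species_tree: str  # newick, branch lengths in myr
    te_rate: float = NEUTRAL_RATE_DMEL
    gene_rate: float = NEUTRAL_RATE_DMEL
    gene_rate_scaling: float | tuple[float, float] = 0.5
    n_genes: int = 20
    gene_length: int = 1000
    te_length: int = 1304
    te_family: str = "TEfam1"
    insertions: tuple[tuple[str, float], ...] = ()
    ht_events: tuple[tuple[str, str, float], ...] = ()
    copies_per_species: int = 5
    copy_burst_age: float = 0.2  # myr; star-like within-genome amplification
    burst: Optional[tuple[str, float, int]] = None  # (species, age myr, n copies)
    kappa: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.te_rate <= 0 or self.gene_rate <= 0:
            raise ValueError("rates must be > 0")
        lo, hi = self._scaling_range()
        if not (0 < lo <= hi <= 1):
            raise ValueError("gene_rate_scaling must lie in (0, 1]")

    def _scaling_range(self) -> tuple[float, float]:
        s = self.gene_rate_scaling
        if isinstance(s, (tuple, list)):
            return float(s[0]), float(s[1])
        return float(s), float(s)

    def tree(self) -> dendropy.Tree:
        t = dendropy.Tree.get(
            data=self.species_tree, schema="newick", preserve_underscores=True
        )
        t.is_rooted = True
        return t

    def to_dict(self) -> dict:
        d = asdict(self)
        d["insertions"] = [list(x) for x in self.insertions]
        d["ht_events"] = [list(x) for x in self.ht_events]
        if isinstance(d["gene_rate_scaling"], tuple):
            d["gene_rate_scaling"] = list(d["gene_rate_scaling"])
        return d


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated dataset."""

    scenario: dict
    carriers: list[str]
    copy_records: dict  # species -> list of {copy, burst_age}
    expected_te_distances: dict  # "spA|spB" -> JC subs/site
    expected_gene_distances: dict  # gene -> {"spA|spB": subs/site}
    gene_scalings: dict  # gene -> multiplier

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def _scenario_rngs(
    scenario: "TransferScenario",
) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
    """Independent child streams (TE, gene-scalings, gene-sequences) from
    the single scenario seed, so truth and data generation agree."""
    ss = np.random.SeedSequence(scenario.seed)
    return tuple(np.random.default_rng(s) for s in ss.spawn(3))


class _HostMap:
    """Positions and backward traces of element lineages on the host tree."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.ages = node_ages(tree)
        self.root_age = self.ages[tree.seed_node]
        self.leaf = {
            lf.taxon.label: lf for lf in tree.leaf_node_iter()
        }

    def position(
        self, species: str, age: float, allow_stem: bool = False
    ) -> dendropy.Node:
        """The node whose parent edge covers ``age`` on the species' path.

        Ages at or above the root land on the stem lineage (the root
        node); that is allowed for insertions (an element may predate the
        clade) but not for horizontal-transfer events, which require the
        involved lineages to exist at the event time."""
        if species not in self.leaf:
            raise ValueError(f"unknown species {species!r}")
        if age > self.root_age + 1e-9 and not allow_stem:
            raise ValueError(
                f"lineage of {species} does not exist at {age} myr "
                f"(root age {self.root_age})"
            )
        nd = self.leaf[species]
        while nd.parent_node is not None and self.ages[nd.parent_node] <= age + 1e-12:
            nd = nd.parent_node
        return nd

    def trace(
        self, species: str, ht_points: list[tuple[float, dendropy.Node, dendropy.Node]]
    ) -> list[tuple[float, float, dendropy.Node]]:
        """Backward trace of the element lineage from a tip.

        ``ht_points`` holds (age, recipient_position, donor_position) for
        every HT event, ascending in age. Returns (age_lo, age_hi, node)
        segments; the node identifies the host edge above it.
        """
        segs: list[tuple[float, float, dendropy.Node]] = []
        a = 0.0
        nd = self.leaf[species]
        used: set[int] = set()
        while True:
            top = self.ages[nd.parent_node] if nd.parent_node else math.inf
            jump = None
            for k, (t, recip_pos, donor_pos) in enumerate(ht_points):
                if (
                    k not in used
                    and recip_pos is nd
                    and donor_pos is not recip_pos
                    and a - 1e-12 <= t < top
                ):
                    jump = (k, t, donor_pos)
                    break
            if jump is not None:
                k, t, donor_pos = jump
                used.add(k)
                segs.append((a, t, nd))
                a, nd = t, donor_pos
                continue
            segs.append((a, top, nd))
            if nd.parent_node is None:
                return segs
            a, nd = top, nd.parent_node


def _meeting_age(
    s1: list[tuple[float, float, dendropy.Node]],
    s2: list[tuple[float, float, dendropy.Node]],
) -> float:
    """Youngest age at which two backward traces occupy the same host edge."""
    best = math.inf
    for a1, b1, n1 in s1:
        for a2, b2, n2 in s2:
            if n1 is n2 and max(a1, a2) < min(b1, b2) + 1e-12:
                best = min(best, max(a1, a2))
    return best


def _cluster_ultrametric(labels: list[str], meet: dict[frozenset, float]) -> dict:
    """Recursive genealogy reconstruction from ultrametric meeting ages."""
    if len(labels) == 1:
        return {"age": 0.0, "species": labels[0], "children": []}
    a = max(meet[frozenset((x, y))] for i, x in enumerate(labels) for y in labels[i + 1:])
    # union-find into groups meeting strictly below a
    parent = {x: x for x in labels}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, x in enumerate(labels):
        for y in labels[i + 1:]:
            if meet[frozenset((x, y))] < a - 1e-12:
                parent[find(x)] = find(y)
    groups: dict[str, list[str]] = {}
    for x in labels:
        groups.setdefault(find(x), []).append(x)
    children = [_cluster_ultrametric(sorted(g), meet) for g in sorted(groups.values())]
    return {"age": a, "species": None, "children": children}


def inject_te_history(
    scenario: TransferScenario,
) -> tuple[dict[str, Alignment], SimTruth]:
    """Simulate the TE component of a scenario.

    Returns per-species copy lists (element orientation, aligned to
    consensus coordinates — no indel process) and the ground truth with
    analytic expected pairwise distances (2 * rate * divergence-time,
    before JC estimation noise).
    """
    if not scenario.insertions:
        raise ValueError("scenario has no TE insertion")
    tree = scenario.tree()
    host = _HostMap(tree)
    rng_te, rng_scal, _ = _scenario_rngs(scenario)

    ins_points = []
    for sp, t in scenario.insertions:
        ins_points.append((host.position(sp, t, allow_stem=True), float(t)))
    ht_points = []
    for donor, recip, t in sorted(scenario.ht_events, key=lambda e: e[2]):
        ht_points.append((float(t), host.position(recip, t), host.position(donor, t)))

    # carriers: leaves whose backward trace crosses an insertion point
    traces: dict[str, list] = {}
    origin: dict[str, int] = {}
    for sp in sorted(host.leaf):
        tr = host.trace(sp, ht_points)
        traces[sp] = tr
        for k, (nd, t_ins) in enumerate(ins_points):
            hit = any(
                n is nd and a - 1e-12 <= t_ins < b for a, b, n in tr
            )
            if hit and (sp not in origin or t_ins < ins_points[origin[sp]][1]):
                origin[sp] = k
    carriers = sorted(origin)
    if not carriers:
        raise ValueError("no species carries the element under this scenario")

    copies: dict[str, Alignment] = {}
    copy_records: dict[str, list] = {}
    expected: dict[str, float] = {}

    for k, (nd_ins, t_ins) in enumerate(ins_points):
        fam = [sp for sp in carriers if origin[sp] == k]
        if not fam:
            continue
        meet: dict[frozenset, float] = {}
        for i, x in enumerate(fam):
            for y in fam[i + 1:]:
                m = min(_meeting_age(traces[x], traces[y]), t_ins)
                meet[frozenset((x, y))] = m
                expected[f"{x}|{y}"] = 2.0 * scenario.te_rate * m
        genealogy = _cluster_ultrametric(fam, meet) if len(fam) > 1 else {
            "age": 0.0, "species": fam[0], "children": []
        }
        root_seq = random_seq(scenario.te_length, rng_te)

        def burst_params(sp: str) -> tuple[float, int]:
            if scenario.burst is not None and scenario.burst[0] == sp:
                return float(scenario.burst[1]), int(scenario.burst[2])
            return scenario.copy_burst_age, scenario.copies_per_species

        def descend(node: dict, state: np.ndarray, age_from: float) -> None:
            if node["species"] is not None:
                sp = node["species"]
                b_age, n_cop = burst_params(sp)
                b_age = min(b_age, age_from)
                # lineage down to the amplification burst, then star copies
                anc = jc_evolve(state, scenario.te_rate, age_from - b_age, rng_te)
                copies[sp] = Alignment(
                    tuple(
                        SequenceRecord(
                            f"{sp}_{scenario.te_family}_c{i+1}",
                            seq_to_str(jc_evolve(anc, scenario.te_rate, b_age, rng_te)),
                        )
                        for i in range(n_cop)
                    )
                )
                copy_records[sp] = [
                    {"copy": r.id, "burst_age_myr": b_age} for r in copies[sp]
                ]
                return
            st = jc_evolve(state, scenario.te_rate, age_from - node["age"], rng_te)
            for child in node["children"]:
                descend(child, st, node["age"])

        descend(genealogy, root_seq, t_ins)

    # genes under purifying selection
    lo, hi = scenario._scaling_range()
    scalings = {
        f"gene{g+1}": float(rng_scal.uniform(lo, hi)) for g in range(scenario.n_genes)
    }
    gene_expected: dict[str, dict[str, float]] = {}
    pair_div: dict[str, float] = {}
    labels = sorted(host.leaf)
    for i, x in enumerate(labels):
        for y in labels[i + 1:]:
            mrca = tree.mrca(taxon_labels=[x, y])
            pair_div[f"{x}|{y}"] = host.ages[mrca]
    for g, s in scalings.items():
        gene_expected[g] = {
            pair: 2.0 * scenario.gene_rate * s * t for pair, t in pair_div.items()
        }

    truth = SimTruth(
        scenario=scenario.to_dict(),
        carriers=carriers,
        copy_records=copy_records,
        expected_te_distances=expected,
        expected_gene_distances=gene_expected,
        gene_scalings=scalings,
    )
    return copies, truth


def simulate_genes(scenario: TransferScenario) -> dict[str, Alignment]:
    """Orthologous gene alignments evolved along the host tree.

    Per-gene purifying-selection multipliers come from the same child
    stream as the truth record, so they match exactly."""
    tree = scenario.tree()
    _, rng_scal, rng_gene = _scenario_rngs(scenario)
    lo, hi = scenario._scaling_range()
    out: dict[str, Alignment] = {}
    for g in range(scenario.n_genes):
        s = float(rng_scal.uniform(lo, hi))
        root = random_seq(scenario.gene_length, rng_gene)
        out[f"gene{g+1}"] = evolve_sequence(
            tree, root, scenario.gene_rate * s, rng_gene, kappa=scenario.kappa
        )
    return out


def generate_dataset(scenario: TransferScenario, outdir: str | Path) -> Path:
    """Emit the file kinds the pipeline consumes, plus the truth JSON.

    Layout: species_tree.nwk, genes/geneN.fasta (aligned orthologs),
    te/<family>/<species>.fasta (copies), presence.tsv, truth.json,
    scenario.yaml.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ValueError(f"cannot create output directory {outdir}: {exc}") from exc

    tree = scenario.tree()
    tree.is_rooted = True
    write_newick(tree, outdir / "species_tree.nwk")

    copies, truth = inject_te_history(scenario)
    genes = simulate_genes(scenario)

    (outdir / "genes").mkdir(exist_ok=True)
    for name, aln in sorted(genes.items()):
        write_fasta(aln.records, outdir / "genes" / f"{name}.fasta")
    fam_dir = outdir / "te" / scenario.te_family
    fam_dir.mkdir(parents=True, exist_ok=True)
    for sp, recs in sorted(copies.items()):
        write_fasta(recs, fam_dir / f"{sp}.fasta")

    species = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    with open(outdir / "presence.tsv", "w") as fh:
        fh.write(f"species\t{scenario.te_family}\n")
        for sp in species:
            fh.write(f"{sp}\t{int(sp in copies)}\n")

    truth.to_json(outdir / "truth.json")
    with open(outdir / "scenario.yaml", "w") as fh:
        yaml.safe_dump(scenario.to_dict(), fh, sort_keys=True)
    return outdir


# ---------------------------------------------------------------------------
# preset scenarios: the study conditions used throughout tests and reports


def default_vertical_scenario(seed: int = 0, n_genes: int = 20) -> TransferScenario:
    """Vertical-only control: two species split 10 myr ago, the element
    inserted before the split and inherited by both; genes at half the
    neutral rate. TE distances should match or exceed gene distances."""
    return TransferScenario(
        species_tree="(sp1:10,sp2:10);",
        insertions=(("sp1", 50.0),),
        gene_rate_scaling=(0.3, 0.7),
        n_genes=n_genes,
        seed=seed,
    )


def default_ht_scenario(seed: int = 0, n_genes: int = 20) -> TransferScenario:
    """Recent horizontal transfer across a deep (400 myr) host split.

    Orthologous genes are deeply conserved: per-gene effective rates are
    drawn so expected gene JC distances span ~0.21–0.49 subs/site, the
    range observed for real orthologs across a split of this depth. The
    element moves from sp1 to sp2 one myr before present, so the expected
    between-species TE distance is 2 * 0.0346 * 1 ≈ 0.07 — far below every
    gene distance, the HT signature."""
    return TransferScenario(
        species_tree="(sp1:400,sp2:400);",
        insertions=(("sp1", 350.0),),
        ht_events=(("sp1", "sp2", 1.0),),
        gene_rate_scaling=(0.0076, 0.0177),
        n_genes=n_genes,
        seed=seed,
    )


def burst_recovery_scenario(
    seed: int = 0, age_myr: float = 3.2, n_copies: int = 20, te_length: int = 10_000
) -> TransferScenario:
    """Single species with a dated amplification burst, for burst-age
    parameter recovery (defaults mirror a 3.2-myr-old burst)."""
    return TransferScenario(
        species_tree="(sp1:5,sp2:5);",
        insertions=(("sp1", 4.0),),
        burst=("sp1", age_myr, n_copies),
        te_length=te_length,
        n_genes=2,
        gene_length=200,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# synthetic stand-ins for published element anatomy


def _orf_nt(aa: int, rng: np.random.Generator) -> str:
    """ATG + (aa-1) random non-stop codons + TAA -> encodes ``aa`` residues."""
    sense = [c for c in _ALL_CODONS if c not in ("TAA", "TAG", "TGA") and c != "ATG"]
    body = "".join(sense[int(rng.integers(len(sense)))] for _ in range(aa - 1))
    return "ATG" + body + "TAA"


_ALL_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]

_RC = str.maketrans("ACGT", "TGCA")


def synthetic_mariner_element(
    length: int = 1304,
    tir_len: int = 39,
    orf_aa: int = 361,
    name: str = "synthetic_Crmar2_like",
    seed: int = 20130501,
) -> SequenceRecord:
    """A synthetic Tc1/Mariner-like element with prescribed anatomy.

    Constructs (deterministically from ``seed``) a sequence of the given
    length with exact terminal inverted repeats of ``tir_len`` bp, a single
    longest open reading frame of ``orf_aa`` residues on the plus strand,
    and stop codons guarding all frames around the ORF so no longer ORF can
    arise. This is a synthetic stand-in for a published consensus, used to
    validate the anatomy detectors; it shares only its structural
    parameters with any real element, not its sequence.
    """
    orf_nt_len = 3 * orf_aa + 3
    spacer_total = length - 2 * tir_len - orf_nt_len
    if spacer_total < 24:
        raise ValueError("element too short for the requested anatomy")
    rng = np.random.default_rng(seed)
    left_sp = spacer_total // 2
    right_sp = spacer_total - left_sp

    def guarded_spacer(n: int) -> str:
        # stop codons tiled in all three frames kill read-through ORFs
        core = "TAATAATAA"
        fill = seq_to_str(random_seq(max(n - 2 * len(core), 0), rng))
        s = core + fill + core
        return s[:n] if len(s) >= n else (s + "T" * n)[:n]

    for attempt in range(64):
        tir = seq_to_str(random_seq(tir_len, rng))
        body = (
            guarded_spacer(left_sp)
            + _orf_nt(orf_aa, rng)
            + guarded_spacer(right_sp)
        )
        # last interior base must not complement the first, or the TIR
        # would extend past tir_len by chance
        if body[-1] == body[0].translate(_RC):
            body = body[:-1] + "C"
        seq = tir + body + tir.translate(_RC)[::-1]
        assert len(seq) == length
        # the TIR must not extend by chance past tir_len
        if seq[tir_len] != seq[-tir_len - 1].translate(_RC):
            from .element_recovery import detect_tirs, find_longest_orf

            t = detect_tirs(seq, min_len=min(10, tir_len), max_mismatch=0)
            o = find_longest_orf(seq)
            if t == (tir_len, 0) and o.aa_length == orf_aa and o.strand == "+":
                return SequenceRecord(name, seq)
    raise RuntimeError("failed to construct synthetic element")


def synthetic_ortholog_distances(
    n: int = 46, dmin: float = 0.21, dmax: float = 0.49
) -> list[float]:
    """A synthetic stand-in set of per-gene JC distances.

    Evenly spaced on [dmin, dmax], so min/max are exact and the mean is the
    midpoint — mirroring the summary statistics of a real deep-split
    ortholog set without reproducing any real per-gene values."""
    return [float(x) for x in np.linspace(dmin, dmax, n)]
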