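# Methods

## The inference problem

A transposable element found in two host lineages can have got there in
two ways: vertical descent from their common ancestor, or horizontal
transfer (HT) between the lineages. The two histories make opposite
predictions about sequence divergence. A TE copy evolves essentially
neutrally once inserted, so under vertical descent the TE sequences of two
species have been diverging at (at least) the neutral rate since the
species split — as long as, and usually longer than, orthologous host
genes, which are slowed by purifying selection. A TE that is *far more
similar* between two species than any of their orthologous genes therefore
cannot have been inherited vertically.

`httdetect` makes that argument operational and conservative:

    verdict = HT                  iff  max(TE distances) < min(gene distances)
    verdict = vertical-compatible iff  min(TE distances) >= min(gene distances)
    verdict = indeterminate       otherwise (overlapping ranges)

Strict range separation is the most demanding reading of the evidence: a
single gene as similar as the TE blocks the call. An optional `min_margin`
(default 0) lets users demand a larger gap. A Mann–Whitney U between the
two lists is attached as context only and never decides the verdict: gene
distances are a fixed panel, not an exchangeable sample, so a rank test's
nominal p-value has no clean interpretation here.

All distances are Jukes–Cantor corrected, `d = −(3/4)·ln(1 − (4/3)·p)`,
with `p` the mismatch proportion over columns where neither sequence has a
gap or N (pairwise deletion; complete deletion is available via
`gap_deletion="complete"` since the setting used in classical analyses of
this kind is often unreported). `p ≥ 3/4` has no JC distance; such pairs
are flagged undefined (NaN) and surface as errors wherever a defined value
is required, never silently dropped. Distances are proportions internally;
percent appears only in reports — mixing the two scales is a classic
source of unit bugs in this literature. JC69 is used deliberately: no
K2P/GTR/gamma variants, because the detection argument needs only an
order-of-magnitude separation and a single consistent metric.

## Element recovery and anatomy

Similarity hits are retained iff identity > 90% over > 500 bp (both
strict). The family consensus over aligned copies is per-column plurality
with a coverage requirement: a column's depth is its count of non-gap,
non-N residues, and columns below `min_consensus_depth` (default 5) are
excluded, so the entire reported consensus is covered by at least that
many distinct copies. Plurality ties break by the fixed residue order
A < C < G < T for determinism. Coverage is enforced per column, not per
alignment, because partial fragments can leave terminal columns supported
by only a copy or two even in a deep alignment.

Anatomy checks target Tc1/Mariner hallmarks:

- **TIR detection** is an ungapped, end-anchored scan: the longest prefix
  whose reverse complement matches the suffix with at most
  `max_mismatch` mismatches (N never matches). Tc1/Mariner TIRs are short
  and strictly terminal, so an alignment-free scan is both sufficient and
  exactly testable against an O(n²) brute-force oracle.
- **TSD check**: both 2-nt host flanks equal `TA`.
- **ORF scan**: all six frames, ATG-to-stop, length in residues excluding
  the stop; codons containing N translate to X and never terminate an
  ORF, so missing data cannot fake a nonsense mutation. A *copy's*
  transposase intactness is judged in the consensus-defined frame (no
  premature stop over the consensus ORF span) rather than by re-detecting
  ORFs per copy — the question is whether the copy still encodes the
  family's transposase, not whether it contains any ORF.

## Burst dating

A family's amplification burst leaves many copies diverging star-like from
their common source. Its age is estimated as

    age (myr) = mean copy-to-consensus JC distance / neutral rate

with the neutral rate in substitutions/site/myr. The packaged default,
0.0346, is the experimentally derived *Drosophila melanogaster* rate; it
is a config value, not a constant, and `burst_age` refuses a non-positive
rate rather than guessing — several host groups (terrestrial isopods among
them) have no published nuclear rate, and dating there requires an
explicit user-supplied value. Copies saturated against the consensus are
excluded with a warning and the exclusion count is reported. Reports round
ages to 2 significant figures; JSON keeps full precision.

## Tree-based evidence

- **Neighbor joining** (Saitou–Nei Q criterion) builds copy trees and
  species-level TE trees from JC matrices. Q-ties break to the lowest
  index pair; negative branch lengths are clamped to zero with the deficit
  logged. On exactly additive matrices NJ provably recovers the generating
  topology, which the tests exploit as an oracle.
- **Dollo parsimony**: a presence/absence pattern is explained by a single
  gain at the MRCA of the present species plus losses; the minimum loss
  count (maximal absent clades under that ancestor) quantifies patchiness.
  Dollo rather than Fitch because multiple independent gains are exactly
  the alternative (HT) hypothesis being counted against: the report gives
  the loss budget vertical inheritance would require, to be weighed
  against ≥ 1 transfer.
- **Copy monophyly**: a species' copies are monophyletic iff some edge of
  the unrooted copy tree splits exactly them from everything else;
  single-copy species are reported as singletons, not counted.
- **Robinson–Foulds** distance on non-trivial bipartitions quantifies
  host/TE tree incongruence, with `max_rf = 2(n−3)`.

Host species trees are *inputs* (newick), never estimated here: the HTT
evidence consumes the tree, and host-tree estimation has its own mature
tooling.

## The simulator

`synthetic_data` generates datasets with exactly the structure the
analysis assumes, plus ground truth:

- **Host tree**: pure-birth topology rescaled ultrametrically to a chosen
  root depth in myr (or any user newick with myr branch lengths).
- **Genes**: JC evolution along the host tree at
  `gene_rate × scaling`, with the purifying-selection proxy `scaling`
  either a scalar or a per-gene uniform range. Default scaling 0.5 —
  appropriate for shallow trees; the deep-split presets instead draw
  scalings of 0.0076–0.0177 so that expected ortholog distances across a
  400-myr split span ≈ 0.21–0.49 substitutions/site, the range typical of
  deeply conserved orthologs (a scaling of 0.5 across such a split would
  saturate JC entirely).
- **TE history**: an insertion places the element on a named lineage at a
  given age (stem insertions above the root model elements predating the
  clade); each HT event copies the donor lineage's element state into the
  recipient at the event age. Element lineages are traced backward through
  the host tree with jumps at transfer points; pairwise first-meeting ages
  are ultrametric by construction, the genealogy is rebuilt from them
  exactly, and sequences are simulated along it. Transfers into a lineage
  older than the lineage itself are rejected.
- **Bursts**: each carrier species' copies radiate star-like from the
  lineage state at the burst age (default 5 copies, 0.2 myr — giving the
  few-percent within-genome copy divergence typical of recent invasions);
  a `burst` override sets (species, age, copy count) explicitly. The star
  shape matches the implicit model of the copy/consensus dating formula.
- **No indels by default** (alignments are exact); an optional indel hook
  is deliberately out of scope for the default conditions so that
  alignment error cannot be confounded with detection error.
- **Truth**: carriers, per-copy records, analytic expected distances
  (2 × rate × divergence-time per pair) and the full scenario, serialised
  as JSON next to the data. All randomness derives from one seed; an
  identical scenario reproduces byte-identical output.

Preset study conditions: the **HT preset** is a 2-species, 400-myr split
with a transfer 1 myr before present (expected TE distance
2·0.0346·1 ≈ 0.07 versus gene distances ≥ 0.21); the **vertical preset**
is a 10-myr split with the element inserted on the stem, genes at half
the neutral rate (TE distance ≈ 0.69 versus genes 0.21–0.48). Twenty
1-kb genes per dataset keep 200-replicate calibrations fast on one CPU.

What passing on these simulations does **not** show: robustness to
alignment error and indels, to rate variation among sites or lineages, to
non-JC substitution processes (a K80 `kappa` hook exists for robustness
experiments), to copy-number dynamics within genomes, or to
incomplete/fragmented copies. Real analyses must still bring externally
curated alignments.

## Calibration results computed by the suite

The acceptance script and test suite recompute, rather than assert as
constants: the two burst-age worked examples (0.11/0.0346 → 3.2 myr,
0.069/0.0346 → 2.0 myr); anatomy recovery (1304 bp / 39-bp TIR / 361-aa
ORF and 1013 bp / 28-bp TIR / 200-aa ORF) from synthetic consensuses
carrying those structural parameters; a 46-gene distance summary
(mean 35%, min 21%, max 49%); NJ/Dollo/RF agreement with independent
brute-force oracles; and, over 200 seeded replicates per condition,
vertical-null-test sensitivity (≥ 0.90 required) and false-positive rate
(≤ 0.05 required), plus burst-age recovery of a simulated 3.2-myr burst
within 2 standard errors (pooled over replicates, because copy pairs
within one replicate share a single realised divergence and are not
independent).

## Known limitations

- The HT verdict is a range comparison, not a probability; it inherits the
  panel of genes supplied. Few or atypically conserved genes weaken it in
  opposite directions.
- Burst dating assumes a star radiation from the consensus and a known,
  constant neutral rate; nested amplification or rate misspecification
  biases ages proportionally.
- The simulator has one element lineage per species between burst and
  transfer events, so within-burst (copy-level) donor sampling — needed to
  produce non-monophyletic copy clades — is not modelled; copy monophyly
  is validated on constructed trees instead.
- Consensus building requires pre-aligned copies; merging overlapping raw
  hit fragments into a copy alignment is upstream of this package.
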