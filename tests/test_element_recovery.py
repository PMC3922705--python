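import numpy as np
import pytest

from httdetect.element_recovery import (
    build_consensus,
    check_tsd,
    copy_orf_is_intact,
    detect_tirs,
    filter_hits,
    find_longest_orf,
    revcomp,
)
from httdetect.io_formats import Alignment, HitRecord, SequenceRecord
from httdetect.synthetic_data import synthetic_mariner_element


def hit(pid, alen):
    return HitRecord("q", "s", pid, alen, 1, alen)


class TestFilterHits:
    def test_kept_above_both_thresholds(self):
        assert filter_hits([hit(95.0, 600)]) == [hit(95.0, 600)]

    def test_boundary_is_strict(self):
        assert filter_hits([hit(90.0, 600)]) == []
        assert filter_hits([hit(91.0, 500)]) == []

    def test_six_hit_enumeration(self):
        hits = [hit(95, 600), hit(90, 600), hit(91, 500), hit(91, 501),
                hit(89, 800), hit(99, 5000)]
        kept = filter_hits(hits)
        # independent enumeration of the strict > rule over the six tuples
        expect = [h for h in hits if h.pct_identity > 90 and h.aln_length > 500]
        assert kept == expect
        assert len(kept) == 3

    def test_empty_in_empty_out(self):
        assert filter_hits([]) == []

    def test_order_preserved(self):
        hits = [hit(99, 5000), hit(95, 600)]
        assert filter_hits(hits) == hits


def aln(*seqs):
    return Alignment(tuple(SequenceRecord(f"c{i}", s) for i, s in enumerate(seqs)))


class TestBuildConsensus:
    def test_identical_copies(self):
        cons = build_consensus(aln(*["ACGTACGTACGTACGTACGT"] * 5), min_depth=5)
        assert cons.seq == "ACGTACGTACGTACGTACGT"
        assert set(cons.depth_profile) == {5}

    def test_plurality_column(self):
        # one column disagrees 3 A vs 2 G
        copies = aln("AC", "AC", "AC", "GC", "GC")
        cons = build_consensus(copies, min_depth=5)
        assert cons.seq == "AC"

    def test_plurality_tie_breaks_to_earlier_residue(self):
        copies = aln("AAC", "AAC", "GGC", "GGC", "TTC", "TTC")
        # ties A=G=T are impossible here; 2/2/2 three-way tie -> A wins
        cons = build_consensus(copies, min_depth=5)
        assert cons.seq[0] == "A"

    def test_low_depth_column_excluded(self):
        copies = aln("ACGT", "ACGT", "ACGT", "ACGT", "ACG-", "ACG-")
        cons = build_consensus(copies, min_depth=5)
        assert cons.seq == "ACG"
        assert len(cons.depth_profile) == 3

    def test_insufficient_coverage_error(self):
        copies = aln("A---", "-C--", "--G-", "---T", "A---")
        with pytest.raises(ValueError, match="insufficient coverage"):
            build_consensus(copies, min_depth=5)

    def test_too_few_copies_error(self):
        with pytest.raises(ValueError):
            build_consensus(aln("AC", "AC"), min_depth=5)

    def test_permutation_invariance(self, rng):
        seqs = ["ACGTAAGGTC", "ACGTAAGGTC", "ACCTAAGGTC", "ACGTATGGTC", "TCGTAAGGTC"]
        c1 = build_consensus(aln(*seqs), min_depth=5)
        order = rng.permutation(len(seqs))
        c2 = build_consensus(aln(*[seqs[i] for i in order]), min_depth=5)
        assert c1.seq == c2.seq

    def test_n_excluded_from_depth(self):
        copies = aln("ACGT", "ACGT", "ACGT", "ACGT", "ACGN", "ACGN")
        cons = build_consensus(copies, min_depth=5)
        assert cons.seq == "ACG"

    def test_exact_recovery_from_error_free_copies(self, rng):
        # identity recovery: >=5 error-free copies return the element exactly
        element = "".join(rng.choice(list("ACGT"), size=300))
        cons = build_consensus(aln(*[element] * 6), min_depth=5)
        assert cons.seq == element

    def test_noisy_copy_recovery_below_binomial_bound(self, rng):
        # depth 9, per-site error 0.05: per-column consensus error probability
        # is bounded by P[Bin(9, 0.05) >= 5] (majority overturned needs >=5
        # hits on one wrong residue, an upper bound); check empirically.
        from scipy.stats import binom

        L = 2000
        element = rng.choice(list("ACGT"), size=L)
        copies = []
        for _ in range(9):
            c = element.copy()
            mask = rng.random(L) < 0.05
            c[mask] = rng.choice(list("ACGT"), size=int(mask.sum()))
            copies.append("".join(c))
        cons = build_consensus(aln(*copies), min_depth=5)
        errors = sum(a != b for a, b in zip(cons.seq, element))
        p_col = float(binom.sf(4, 9, 0.05))
        bound = L * p_col + 4 * np.sqrt(L * p_col)
        assert errors <= max(bound, 3)


def brute_force_tir(seq, min_len, max_mismatch):
    best = None
    for L in range(min_len, len(seq) // 2 + 1):
        mm = sum(
            1
            for a, b in zip(seq[:L], revcomp(seq[-L:]))
            if a != b or a == "N"
        )
        if mm <= max_mismatch:
            best = (L, mm)
    return best


class TestDetectTirs:
    def test_constructed_perfect_tir(self, rng):
        p = "".join(rng.choice(list("ACGT"), size=10))
        core = "CCCCCAAAAACCCCC"
        seq = p + core + revcomp(p)
        res = detect_tirs(seq, min_len=10, max_mismatch=0)
        assert res == brute_force_tir(seq, 10, 0)
        assert res[0] >= 10 and res[1] == 0

    def test_seeded_random_sequence_has_none(self):
        rng = np.random.default_rng(99)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        assert detect_tirs(seq, min_len=15, max_mismatch=0) is None

    def test_mismatch_tolerance(self):
        p = "ACGTACGTACGT"
        tail = list(revcomp(p))
        tail[5] = "A" if tail[5] != "A" else "C"
        seq = p + "GGGGCCCCGGGG" + "".join(tail)
        assert detect_tirs(seq, min_len=12, max_mismatch=0) is None
        res = detect_tirs(seq, min_len=12, max_mismatch=1)
        assert res == (12, 1)

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            detect_tirs("ACGTACGT", min_len=10)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            n = int(rng.integers(30, 200))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            for mm in (0, 1, 2):
                assert detect_tirs(seq, 5, mm) == brute_force_tir(seq, 5, mm)


class TestCheckTsd:
    @pytest.mark.parametrize("left,right,expect", [
        ("TA", "TA", True),
        ("TA", "TG", False),
        ("CA", "TA", False),
        ("ta", "ta", True),
    ])
    def test_flanks(self, left, right, expect):
        assert check_tsd(left, right) is expect


class TestFindLongestOrf:
    def test_hand_translatable(self):
        assert find_longest_orf("ATGAAATAA").aa_length == 2  # MK

    def test_minimal_orf(self):
        assert find_longest_orf("ATGTAA").aa_length == 1  # M

    def test_no_atg_gives_zero(self):
        assert find_longest_orf("CCCCCCTAA").aa_length == 0

    def test_orf_without_stop_not_counted(self):
        assert find_longest_orf("ATGAAAAAA").aa_length == 0

    def test_n_codon_translates_to_x_not_stop(self):
        # ATG AAA TNA AAA TAA: the N codon must not terminate the ORF
        assert find_longest_orf("ATGAAATNAAAATAA").aa_length == 4

    def test_reverse_strand_found(self):
        plus = "ATGAAACCCAAATAA"
        seq = revcomp(plus)
        hit = find_longest_orf(seq)
        assert (hit.aa_length, hit.strand) == (4, "-")

    def test_copy_intactness_in_consensus_frame(self):
        cons_seq = "CCATGAAACCCAAATAACC"
        cons_orf = find_longest_orf(cons_seq)
        assert cons_orf.aa_length == 4
        span = 3 * (cons_orf.aa_length + 1)
        intact_copy = "CCATGAAACCAAAATAACC"  # non-stop substitution
        broken_copy = "CCATGTAACCCAAATAACC"  # premature stop
        assert copy_orf_is_intact(intact_copy, cons_orf, span)
        assert not copy_orf_is_intact(broken_copy, cons_orf, span)


class TestSyntheticElementAnatomy:
    """Structural parameter recovery on synthetic Tc1/Mariner-like elements
    built to the published anatomy of the two isopod consensuses."""

    @pytest.mark.parametrize("length,tir,orf", [(1304, 39, 361), (1013, 28, 200)])
    def test_anatomy_recovered_from_sequence_alone(self, length, tir, orf):
        el = synthetic_mariner_element(length=length, tir_len=tir, orf_aa=orf)
        assert len(el.seq) == length
        assert detect_tirs(el.seq, min_len=10, max_mismatch=0) == (tir, 0)
        hit = find_longest_orf(el.seq)
        assert hit.aa_length == orf
        assert hit.is_intact
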