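"""Mapping, folding, hairpin prediction, merging and classification."""

import numpy as np
import pytest

from canemir.config import HairpinParams
from canemir.discovery import (
    Alignment,
    PreMiRNA,
    classify_conserved,
    fold_rna,
    levenshtein,
    map_reads,
    merge_precursors,
    pair_table,
    predict_hairpins,
)
from canemir.io import revcomp

PAIRABLE = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def nussinov_oracle(seq: str, min_loop: int = 3) -> int:
    """Exhaustive maximum base-pair count by plain recursion (no DP table):
    an implementation-independent oracle for short sequences."""

    def rec(i, j):
        if j - i <= min_loop:
            return 0
        best = rec(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in PAIRABLE:
                best = max(best, 1 + rec(i + 1, k - 1) + rec(k + 1, j))
        return best

    return rec(0, len(seq) - 1)


def random_seqs(rng, n, lo, hi):
    return [
        "".join(rng.choice(list("ACGT"), size=rng.integers(lo, hi + 1)))
        for _ in range(n)
    ]


class TestFoldRNA:
    def test_poly_a_has_no_pairs(self):
        structure, energy = fold_rna("A" * 10)
        assert structure == "." * 10 and energy == 0.0

    def test_simple_stem_pairs_five(self):
        structure, score = fold_rna("GGGGGAAAAACCCCC", objective="pairs")
        assert structure.count("(") == 5 and score == -5.0

    def test_pair_counts_match_exhaustive_oracle(self):
        """Pair-maximisation folding equals brute-force enumeration for
        every sequence up to 25 nt in a seeded random corpus."""
        rng = np.random.default_rng(42)
        corpus = ["GGGGGAAAAACCCCC", "A" * 12, "GCGCGCAAAAGCGCGC"]
        corpus += random_seqs(rng, 30, 10, 25)
        for seq in corpus:
            structure, score = fold_rna(seq, objective="pairs")
            assert structure.count("(") == -score
            assert -score == nussinov_oracle(seq), seq

    def test_structure_is_valid_nesting_with_min_loop(self):
        rng = np.random.default_rng(7)
        for seq in random_seqs(rng, 10, 15, 40):
            structure, _ = fold_rna(seq)
            partners = pair_table(structure)  # raises if unbalanced
            for i, j in enumerate(partners):
                if j > i:
                    assert j - i > 3  # hairpin loop of at least 3
                    assert (seq[i], seq[j]) in PAIRABLE

    def test_energy_decreases_with_added_complementarity(self):
        core = "AAAGAAACAAAGAAAC"
        energies = []
        for stem in range(3, 9):
            seq = "G" * stem + core + "C" * stem
            _, e = fold_rna(seq)
            energies.append(e)
        assert all(b < a for a, b in zip(energies, energies[1:]))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fold_rna("ACGTNNACGTA")
        with pytest.raises(ValueError):
            fold_rna("ACGTACG")  # below the 10 nt minimum
        with pytest.raises(ValueError):
            fold_rna("ACGTACGTACGT", objective="bogus")

    def test_engine_plugin_overrides_builtin(self):
        structure, energy = fold_rna("ACGT", engine=lambda s: ("....", -1.5))
        assert (structure, energy) == ("....", -1.5)

    def test_u_and_t_fold_identically(self):
        assert fold_rna("GGGGGAAAAACCCCC") == fold_rna("GGGGGAAAAACCCCC".replace("T", "U"))


class TestMapReads:
    TX = {"t1": "ACGTACGTAACCGGTTACGTACGTAACCGGTTACGT" + "GATTACA" * 10}

    def test_exact_substring_maps_with_zero_mismatches(self):
        read = self.TX["t1"][5:27]
        aln, flagged = map_reads([read], self.TX)
        assert not flagged
        hits = aln[read]
        assert any(a.start == 6 and a.mismatches == 0 for a in hits)

    def test_three_substitutions_rejected(self):
        read = list(self.TX["t1"][40:61])
        for i in (2, 9, 16):
            read[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[i]]
        aln, _ = map_reads(["".join(read)], self.TX)
        assert "".join(read) not in aln

    def test_two_substitutions_accepted(self):
        read = list(self.TX["t1"][0:21])
        read[3] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[3]]
        aln, _ = map_reads(["".join(read)], self.TX)
        assert any(a.mismatches == 1 for a in aln["".join(read)])

    def test_copy_cap_flags_multi_locus_reads(self):
        unit = "ACGGTTCAACGGATCCAGTTAG"
        tx = {"rep": ("NNNN".replace("N", "A") + unit) * 25}
        aln, flagged = map_reads([unit], tx, max_loci=20)
        assert unit in flagged
        assert len(aln[unit]) > 20

    def test_empty_read_table(self):
        aln, flagged = map_reads([], self.TX)
        assert aln == {} and flagged == set()

    def test_empty_transcripts_is_an_error(self):
        with pytest.raises(ValueError):
            map_reads(["ACGTACGTACGTACGTAC"], {})


def _hairpin_transcript(mature, loop_len, flank=30, seed=5):
    rng = np.random.default_rng(seed)
    rand = lambda n: "".join(rng.choice(list("ACGT"), size=n))
    loop = rand(loop_len)
    return rand(flank) + mature + loop + revcomp(mature) + rand(flank)


class TestPredictHairpins:
    MATURE = "ATGGTCTCAAGGCATTCAGAC"  # 21 nt

    def _predict(self, tx, read, count=50, params=HairpinParams()):
        aln, flagged = map_reads([read], tx)
        return predict_hairpins(aln, {read: count}, tx, params, frozenset(flagged))

    def test_planted_hairpin_recovered_exactly(self):
        tx = {"t": _hairpin_transcript(self.MATURE, loop_len=20)}
        cands = self._predict(tx, self.MATURE)
        assert len(cands) == 1
        p = cands[0]
        assert tx["t"][p.mature[0] - 1 : p.mature[1]] == self.MATURE
        assert p.arm == "5p"
        assert p.energy <= -18.0
        assert p.star[0] - p.mature[1] - 1 == 20  # planted loop length

    def test_mature_length_26_rejected(self):
        long_mature = self.MATURE + "ACGTA"  # 26 nt
        tx = {"t": _hairpin_transcript(long_mature, loop_len=20)}
        assert self._predict(tx, long_mature) == []

    def test_gap_below_16_rejected(self):
        tx = {"t": _hairpin_transcript(self.MATURE, loop_len=10)}
        assert self._predict(tx, self.MATURE) == []

    def test_gap_16_boundary_accepted(self):
        tx = {"t": _hairpin_transcript(self.MATURE, loop_len=16)}
        assert len(self._predict(tx, self.MATURE)) == 1

    def test_flagged_reads_do_not_seed(self):
        tx = {"t": _hairpin_transcript(self.MATURE, loop_len=20)}
        aln, _ = map_reads([self.MATURE], tx)
        assert predict_hairpins(aln, {self.MATURE: 50}, tx, flagged={self.MATURE}) == []

    def test_star_arm_read_support_recorded(self):
        tx = {"t": _hairpin_transcript(self.MATURE, loop_len=20)}
        star_read = revcomp(self.MATURE)
        aln, flagged = map_reads([self.MATURE, star_read], tx)
        cands = predict_hairpins(
            aln, {self.MATURE: 50, star_read: 5}, tx, flagged=frozenset(flagged)
        )
        mature_led = [c for c in cands if c.mature_seq == self.MATURE]
        assert mature_led and mature_led[0].star_count == 5


def _mk(pid, tid, start, length, count):
    seq = "A" * length
    return PreMiRNA(
        id=pid, transcript_id=tid, start=start, sequence=seq, structure="." * length,
        energy=-20.0, mature=(start, start + 20), star=(start + 40, start + 60),
        arm="5p", mature_seq="A" * 21, mature_count=count,
    )


class TestMergePrecursors:
    def test_identical_duplicates_collapse(self):
        a, b = _mk("a", "t", 1, 100, 10), _mk("b", "t", 1, 100, 5)
        assert [p.id for p in merge_precursors([a, b])] == ["a"]

    def test_81_percent_overlap_merges(self):
        a = _mk("a", "t", 1, 100, 10)
        b = _mk("b", "t", 20, 100, 5)  # overlap 81/100
        assert len(merge_precursors([a, b])) == 1

    def test_79_percent_overlap_keeps_both(self):
        a = _mk("a", "t", 1, 100, 10)
        b = _mk("b", "t", 22, 100, 5)  # overlap 79/100
        assert len(merge_precursors([a, b])) == 2

    def test_exactly_80_percent_keeps_both(self):
        a = _mk("a", "t", 1, 100, 10)
        b = _mk("b", "t", 21, 100, 5)  # overlap 80/100: rule is "> 80%"
        assert len(merge_precursors([a, b])) == 2

    def test_order_invariant_and_idempotent(self):
        cands = [_mk("a", "t", 1, 100, 10), _mk("b", "t", 20, 100, 5),
                 _mk("c", "u", 1, 90, 7)]
        once = merge_precursors(cands)
        assert merge_precursors(cands[::-1]) == once
        assert merge_precursors(once) == once

    def test_higher_count_representative_wins(self):
        a, b = _mk("a", "t", 1, 100, 3), _mk("b", "t", 5, 100, 30)
        assert [p.id for p in merge_precursors([a, b])] == ["b"]


class TestClassifyConserved:
    CATALOG = {"known-1": "ATGGTCTCAAGGCATTCAGAC"}

    def test_exact_match_with_11_reads_is_conserved(self):
        out = classify_conserved({"m": ("ATGGTCTCAAGGCATTCAGAC", 11)}, self.CATALOG)
        assert out["m"][0] == "conserved" and out["m"][1] == "known-1"

    def test_exactly_10_reads_is_novel(self):
        out = classify_conserved({"m": ("ATGGTCTCAAGGCATTCAGAC", 10)}, self.CATALOG)
        assert out["m"][0] == "novel"  # expression rule is strictly > 10

    def test_high_identity_low_reads_is_novel(self):
        seq = "ATGGTCTCAAGGCATTCAGAT"  # 1 substitution: identity 20/21 = 0.952
        out = classify_conserved({"m": (seq, 8)}, self.CATALOG)
        assert out["m"][0] == "novel"

    def test_low_identity_high_reads_is_novel(self):
        seq = "ATGGTCTCAAGGCATTCTTTT"  # 3 edits: identity 18/21 = 0.857
        out = classify_conserved({"m": (seq, 1000)}, self.CATALOG)
        assert out["m"][0] == "novel"
        assert out["m"][2] == pytest.approx(1 - levenshtein(seq, self.CATALOG["known-1"]) / 21)

    def test_empty_catalog_is_an_error(self):
        with pytest.raises(ValueError):
            classify_conserved({"m": ("ACGT" * 5, 50)}, {})


@pytest.mark.parametrize(
    "a,b,d",
    [("kitten", "sitting", 3), ("", "abc", 3), ("ACGT", "ACGT", 0), ("AAAA", "AATA", 1)],
)
def test_levenshtein(a, b, d):
    assert levenshtein(a, b) == d
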