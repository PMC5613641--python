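"""Target-prediction rule engine versus an independently coded oracle."""

import numpy as np
import pytest

from canemir.io import revcomp
from canemir.targets import (
    GU,
    MATCH,
    MISMATCH,
    DuplexSite,
    compare_target_sets,
    duplex_mfe_ratio,
    duplex_states,
    find_candidate_sites,
    predict_targets,
    score_duplex,
)

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# independent oracle: a literal, unoptimised transcription of the six rules
# ---------------------------------------------------------------------------

def oracle_states(mirna, window):
    L = len(mirna)
    states = []
    for i in range(1, L + 1):
        mb, tb = mirna[i - 1], window[L - i]
        if tb == COMP[mb]:
            states.append("match")
        elif (mb, tb) in (("G", "T"), ("T", "G")):
            states.append("gu")
        else:
            states.append("mm")
    return states


def oracle_verdict(states, gu_adjacent=True):
    pen = {"match": 0.0, "gu": 0.5, "mm": 1.0}
    nonmatch = (
        (lambda s: s != "match") if gu_adjacent else (lambda s: s == "mm")
    )
    failed = []
    if sum(pen[s] for s in states) > 3:
        failed.append("i")
    longest = run = 0
    for s in states:
        run = run + 1 if nonmatch(s) else 0
        longest = max(longest, run)
    if longest > 2:
        failed.append("ii")
    adjacent_in_2_12 = False
    for p in range(2, 12):
        if p + 1 > len(states):
            break
        if nonmatch(states[p - 1]) and nonmatch(states[p]):
            adjacent_in_2_12 = True
    if adjacent_in_2_12:
        failed.append("iii")
    if states[9] != "match" or states[10] != "match":
        failed.append("iv")
    if sum(pen[s] for s in states[:12]) > 2.5:
        failed.append("v")
    return failed


def oracle_energy_ratio(mirna, states):
    pair_e = {"G": 3.0, "C": 3.0, "A": 2.0, "T": 2.0}
    duplex = sum(
        pair_e[b] if s == "match" else (1.0 if s == "gu" else 0.0)
        for b, s in zip(mirna, states)
    )
    perfect = sum(pair_e[b] for b in mirna)
    return duplex / perfect


def _site(mirna, window):
    return DuplexSite("m", "t", 1, len(mirna), mirna, duplex_states(mirna, window))


def _perfect_window(mirna):
    return revcomp(mirna)


def _mutate(window, mirna, position, kind="mm"):
    """Force a given state at a miRNA position by editing the window."""
    L = len(mirna)
    w = list(window)
    mb = mirna[position - 1]
    if kind == "mm":
        choices = [b for b in "ACGT" if b != COMP[mb]
                   and (mb, b) not in (("G", "T"), ("T", "G"))]
        w[L - position] = choices[0]
    elif kind == "gu":
        assert mb in "GT", "G:U wobble needs a G or U on the miRNA side"
        w[L - position] = "T" if mb == "G" else "G"
    return "".join(w)


MIRNA = "ATGGTCTCAAGGCATTCAGAC"  # 21 nt


class TestDuplexStates:
    def test_perfect_complement_all_match(self):
        states = duplex_states(MIRNA, _perfect_window(MIRNA))
        assert set(states) == {MATCH}

    def test_states_match_oracle_on_random_windows(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            window = "".join(rng.choice(list("ACGT"), size=len(MIRNA)))
            mine = duplex_states(MIRNA, window)
            theirs = oracle_states(MIRNA, window)
            code = {"match": MATCH, "gu": GU, "mm": MISMATCH}
            assert list(mine) == [code[s] for s in theirs]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            duplex_states(MIRNA, "ACGT")


class TestScoreDuplex:
    def test_perfect_complement_passes(self):
        ok, failed = score_duplex(_site(MIRNA, _perfect_window(MIRNA)))
        assert ok and failed == []

    def test_single_mismatch_at_position_10_fails_rule_iv(self):
        window = _mutate(_perfect_window(MIRNA), MIRNA, 10)
        ok, failed = score_duplex(_site(MIRNA, window))
        assert not ok and failed == ["iv"]

    def test_adjacent_mismatches_at_4_5_fail_rule_iii(self):
        window = _perfect_window(MIRNA)
        for pos in (4, 5):
            window = _mutate(window, MIRNA, pos)
        ok, failed = score_duplex(_site(MIRNA, window))
        assert "iii" in failed

    def test_three_runs_of_mismatches_fail_rule_ii(self):
        window = _perfect_window(MIRNA)
        for pos in (14, 15, 16):
            window = _mutate(window, MIRNA, pos)
        ok, failed = score_duplex(_site(MIRNA, window))
        assert "ii" in failed

    def test_three_spread_wobbles_pass(self):
        # GU at non-adjacent positions away from 10-11: score 1.5, passes
        window = _perfect_window(MIRNA)
        gu_positions = (2, 5, 15)  # T bases, pairwise non-adjacent, off 10-11
        assert all(MIRNA[p - 1] in "GT" for p in gu_positions)
        for pos in gu_positions:
            window = _mutate(window, MIRNA, pos, kind="gu")
        site = _site(MIRNA, window)
        ok, failed = score_duplex(site)
        assert ok, failed
        assert site.mismatch_score == 1.5

    def test_seed_half_score_above_2_5_fails_rule_v(self):
        window = _perfect_window(MIRNA)
        for pos in (2, 4, 6):  # 3 full mismatches within 1-12
            window = _mutate(window, MIRNA, pos)
        ok, failed = score_duplex(_site(MIRNA, window))
        assert "v" in failed and "i" not in failed

    def test_gu_relaxation_flag_for_adjacency(self):
        window = _perfect_window(MIRNA)
        window = _mutate(window, MIRNA, 4, kind="mm")
        # position 5 of this miRNA is T -> wobble possible
        window = _mutate(window, MIRNA, 5, kind="gu")
        strict_ok, strict_failed = score_duplex(_site(MIRNA, window), gu_in_adjacency=True)
        lax_ok, lax_failed = score_duplex(_site(MIRNA, window), gu_in_adjacency=False)
        assert "iii" in strict_failed and "iii" not in lax_failed

    def test_adding_a_mismatch_never_repairs_a_rule(self):
        """Strictness monotonicity: extra mismatches only grow the failed set."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            window = list(_perfect_window(MIRNA))
            for pos in rng.choice(np.arange(1, 22), size=3, replace=False):
                if rng.random() < 0.5:
                    window = list(_mutate("".join(window), MIRNA, int(pos)))
            window = "".join(window)
            _, before = score_duplex(_site(MIRNA, window))
            match_positions = [
                p for p in range(1, 22)
                if duplex_states(MIRNA, window)[p - 1] == MATCH
            ]
            pos = int(rng.choice(match_positions))
            _, after = score_duplex(_site(MIRNA, _mutate(window, MIRNA, pos)))
            assert set(before) <= set(after)


class TestRuleEngineOracleEquivalence:
    def test_verdicts_identical_on_random_duplex_corpus(self):
        rng = np.random.default_rng(12)
        for trial in range(2000):
            mirna = "".join(rng.choice(list("ACGT"), size=int(rng.integers(18, 26))))
            window = list(revcomp(mirna))
            # degrade 0-6 random positions
            for pos in rng.choice(np.arange(1, len(mirna) + 1),
                                  size=int(rng.integers(0, 7)), replace=False):
                window[len(mirna) - pos] = str(rng.choice(list("ACGT")))
            window = "".join(window)
            site = _site(mirna, window)
            ok, failed = score_duplex(site)
            assert sorted(failed) == sorted(oracle_verdict(oracle_states(mirna, window)))
            ratio, _ = duplex_mfe_ratio(site)
            assert ratio == pytest.approx(
                oracle_energy_ratio(mirna, oracle_states(mirna, window)), abs=1e-12
            )


class TestMfeRatio:
    def test_perfect_duplex_ratio_one(self):
        ratio, ok = duplex_mfe_ratio(_site(MIRNA, _perfect_window(MIRNA)))
        assert ratio == 1.0 and ok

    def test_boundary_inclusive_at_075(self):
        mirna = "G" * 20  # perfect energy 60
        states = tuple([MISMATCH] * 5 + [MATCH] * 15)  # duplex energy 45
        site = DuplexSite("m", "t", 1, 20, mirna, states)
        ratio, ok = duplex_mfe_ratio(site)
        assert ratio == pytest.approx(0.75) and ok

    def test_just_below_boundary_fails(self):
        mirna = "G" * 10 + "A" * 10  # perfect energy 50
        # duplex energy 37: 3 G-mismatches (-9) and 2 A-mismatches (-4)
        states = tuple(
            [MISMATCH] * 3 + [MATCH] * 7 + [MISMATCH] * 2 + [MATCH] * 8
        )
        site = DuplexSite("m", "t", 1, 20, mirna, states)
        ratio, ok = duplex_mfe_ratio(site)
        assert ratio == pytest.approx(0.74) and not ok


class TestFindCandidateSites:
    def test_exact_reverse_complement_found_with_score_zero(self):
        rng = np.random.default_rng(5)
        flank = "".join(rng.choice(list("ACGT"), size=50))
        tx = flank + revcomp(MIRNA) + flank
        sites = find_candidate_sites("m", MIRNA, "t", tx, max_score=3.0)
        exact = [s for s in sites if s.mismatch_score == 0.0]
        assert len(exact) == 1 and exact[0].start == 51

    def test_short_transcript_gives_empty_list(self):
        assert find_candidate_sites("m", MIRNA, "t", "ACGT") == []

    def test_scan_equals_bruteforce_enumeration(self):
        """Vectorised scan reproduces the all-windows enumeration on a
        random 1-kb transcript."""
        rng = np.random.default_rng(8)
        tx = "".join(rng.choice(list("ACGT"), size=1000))
        pen = {"match": 0.0, "gu": 0.5, "mm": 1.0}
        expected = {}
        for off in range(len(tx) - len(MIRNA) + 1):
            window = tx[off : off + len(MIRNA)]
            score = sum(pen[s] for s in oracle_states(MIRNA, window))
            if score <= 3.0:
                expected[off + 1] = score
        got = {
            s.start: s.mismatch_score
            for s in find_candidate_sites("m", MIRNA, "t", tx, max_score=3.0)
        }
        assert got == expected

    def test_invalid_mirna_length_rejected(self):
        with pytest.raises(ValueError):
            find_candidate_sites("m", "ACGT", "t", "ACGT" * 50)


class TestPlantedSites:
    def test_planted_sites_found_with_designed_score(self, reference):
        transcripts, manifest = reference
        by_id = {h.mirna_id: h for h in manifest.planted_hairpins}
        for planted in manifest.planted_target_sites:
            if planted.for_variant:
                continue
            h = by_id[planted.mirna_id]
            sites = find_candidate_sites(
                h.mirna_id, h.mature_seq, planted.transcript_id,
                transcripts[planted.transcript_id],
            )
            at = [s for s in sites if s.start == planted.start]
            assert at, planted
            assert at[0].mismatch_score == pytest.approx(planted.designed_score)

    def test_runs_ledger_reports_nonmatch_blocks(self):
        window = _perfect_window(MIRNA)
        for pos in (4, 5, 13):
            window = _mutate(window, MIRNA, pos)
        site = _site(MIRNA, window)
        assert site.runs() == [(4, 5), (13, 13)]


class TestCompareTargetSets:
    def test_identity(self):
        shared, lost, gained = compare_target_sets({"a", "b"}, {"a", "b"})
        assert shared == {"a", "b"} and lost == set() and gained == set()

    def test_disjoint(self):
        shared, lost, gained = compare_target_sets({"a"}, {"b"})
        assert shared == set() and lost == {"a"} and gained == {"b"}

    def test_partition_sizes(self):
        a, b = {"a", "b", "c"}, {"b", "c", "d", "e"}
        shared, lost, gained = compare_target_sets(a, b)
        assert len(shared) + len(lost) == len(a)
        assert len(shared) + len(gained) == len(b)


def test_seed_substitution_changes_target_set(reference):
    """A single seed-region substitution retargets at least one planted
    transcript (the engineered normal/variant site pair)."""
    transcripts, manifest = reference
    var = manifest.planted_variants[0]
    assert 2 <= var.position <= 7
    h = manifest.hairpin(var.mirna_id)
    var_seq = h.mature_seq[: var.position - 1] + var.alt + h.mature_seq[var.position :]
    hosts = {
        s.transcript_id: transcripts[s.transcript_id]
        for s in manifest.planted_target_sites
        if s.mirna_id == var.mirna_id
    }
    normal_t = {s.transcript_id for s in predict_targets("n", h.mature_seq, hosts)}
    variant_t = {s.transcript_id for s in predict_targets("v", var_seq, hosts)}
    _, lost, gained = compare_target_sets(normal_t, variant_t)
    assert lost and gained
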