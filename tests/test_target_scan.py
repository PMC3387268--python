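import numpy as np
import pytest

from hypoxamir.core_io import revcomp
from hypoxamir.synthetic_data import SITE_PROFILES, make_site
from hypoxamir.target_scan import (
    MATCH,
    classify_cleavage,
    scan_transcriptome,
    score_duplex,
)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


MIRNA = "TGGAGCTCCCTTCATTCCAAT"  # 21 nt


def _site_with_mismatches(mirna, positions):
    """Perfect reverse-complement site with true mismatches at the given
    1-based miRNA positions (never a wobble)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    wobble = {"G": "T", "T": "G"}
    site = list(revcomp(mirna))
    L = len(mirna)
    for p in positions:
        mb = mirna[p - 1]
        banned = {comp[mb], wobble.get(mb, "")}
        site[L - p] = next(b for b in "ACGT" if b not in banned)
    return "".join(site)


class TestScoreDuplex:
    def test_perfect_reverse_complement_scores_zero_and_is_accepted(self):
        aln = score_duplex(MIRNA, revcomp(MIRNA))
        assert aln.score == 0
        assert aln.accepted
        assert all(s == MATCH for s in aln.states)

    def test_mismatch_at_position_10_rejected_by_slicing_rule(self):
        aln = score_duplex(MIRNA, _site_with_mismatches(MIRNA, [10]))
        assert not aln.accepted
        assert not aln.rule_verdicts["r_no_mm_10_11"]

    def test_mismatch_at_position_11_rejected_by_slicing_rule(self):
        aln = score_duplex(MIRNA, _site_with_mismatches(MIRNA, [11]))
        assert not aln.rule_verdicts["r_no_mm_10_11"]

    def test_three_consecutive_mismatches_after_12_rejected(self):
        aln = score_duplex(MIRNA, _site_with_mismatches(MIRNA, [13, 14, 15]))
        assert not aln.accepted
        assert not aln.rule_verdicts["r_consec_le2_after12"]
        assert aln.rule_verdicts["r_seed_le1"]

    def test_two_seed_region_mismatches_rejected(self):
        aln = score_duplex(MIRNA, _site_with_mismatches(MIRNA, [3, 8]))
        assert not aln.accepted
        assert not aln.rule_verdicts["r_seed_le1"]

    def test_five_total_mismatches_rejected(self):
        aln = score_duplex(MIRNA, _site_with_mismatches(MIRNA, [1, 13, 15, 17, 19]))
        assert not aln.accepted
        assert not aln.rule_verdicts["r_total_le4"]
        assert aln.rule_verdicts["r_seed_le1"]
        assert aln.rule_verdicts["r_consec_le2_after12"]

    def test_wobble_counts_as_scored_position_by_default(self):
        # place a G:U wobble at position 10: miRNA G faces site T
        mirna = list(MIRNA)
        mirna[9] = "G"
        mirna = "".join(mirna)
        site = list(revcomp(mirna))
        site[len(mirna) - 10] = "T"
        aln = score_duplex(mirna, "".join(site))
        assert aln.states[9] == "wobble"
        assert not aln.rule_verdicts["r_no_mm_10_11"]

    def test_wobble_half_score_option_relaxes_rules(self):
        mirna = list(MIRNA)
        mirna[9] = "G"
        mirna = "".join(mirna)
        site = list(revcomp(mirna))
        site[len(mirna) - 10] = "T"
        aln = score_duplex(mirna, "".join(site), wobble_score=0.5)
        assert aln.score == 0.5
        assert not aln.rule_verdicts["r_no_mm_10_11"]  # 10/11 must be clean

    def test_length_mismatch_and_gaps_rejected(self):
        with pytest.raises(ValueError):
            score_duplex(MIRNA, revcomp(MIRNA)[:-1])
        with pytest.raises(ValueError):
            score_duplex(MIRNA[:-1] + "-", revcomp(MIRNA))


class TestSiteClasses:
    @pytest.mark.parametrize(
        "profile", [p for p in SITE_PROFILES if p not in ("all_pass", "distance7")]
    )
    def test_single_rule_violations_rejected_for_exactly_that_rule(self, profile):
        rng = np.random.default_rng(3)
        expected_false = {
            "violate_seed": "r_seed_le1",
            "violate_10_11": "r_no_mm_10_11",
            "violate_consec": "r_consec_le2_after12",
            "violate_total": "r_total_le4",
        }[profile]
        for _ in range(20):
            mirna = _random_seq(rng, 21)
            aln = score_duplex(mirna, make_site(mirna, profile, rng))
            assert not aln.accepted
            for rule, verdict in aln.rule_verdicts.items():
                assert verdict == (rule != expected_false)

    def test_all_pass_sites_always_accepted(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            mirna = _random_seq(rng, 21)
            assert score_duplex(mirna, make_site(mirna, "all_pass", rng)).accepted


def _brute_force_scan(mirna, transcripts, max_mm):
    """Independent oracle: score every window, keep Hamming distance <= max_mm."""
    out = []
    L = len(mirna)
    for tid in sorted(transcripts):
        seq = transcripts[tid]
        for start in range(len(seq) - L + 1):
            window = seq[start : start + L]
            aln = score_duplex(mirna, window, target_id=tid, site_start=start)
            sequence_mismatches = sum(1 for s in aln.states if s != MATCH)
            if sequence_mismatches <= max_mm:
                out.append((tid, start, aln.accepted, aln.score))
    return out


class TestScanTranscriptome:
    def test_planted_perfect_site_found_at_planted_coordinates(self):
        rng = np.random.default_rng(5)
        tx = list(_random_seq(rng, 400))
        tx[100:121] = list(revcomp(MIRNA))
        hits = scan_transcriptome(MIRNA, {"t1": "".join(tx)})
        accepted = [h for h in hits if h.accepted]
        assert len(accepted) == 1
        assert (accepted[0].site_start, accepted[0].site_end) == (100, 121)

    def test_seed_violating_site_present_as_rejected_candidate(self):
        rng = np.random.default_rng(6)
        tx = list(_random_seq(rng, 400))
        tx[50:71] = list(_site_with_mismatches(MIRNA, [3, 8]))
        hits = scan_transcriptome(MIRNA, {"t1": "".join(tx)})
        match = [h for h in hits if h.site_start == 50]
        assert match and not match[0].accepted

    def test_equals_brute_force_oracle_on_random_inputs(self):
        rng = np.random.default_rng(7)
        transcripts = {f"t{i}": _random_seq(rng, 300) for i in range(10)}
        # plant a few sites so the comparison is not vacuous
        for i, profile in enumerate(["all_pass", "violate_seed", "violate_total"]):
            seq = list(transcripts[f"t{i}"])
            seq[40:61] = list(make_site(MIRNA, profile, rng))
            transcripts[f"t{i}"] = "".join(seq)
        for mm in (0, 3, 6):
            hits = scan_transcriptome(MIRNA, transcripts, candidate_max_mm=mm)
            got = [(h.target_id, h.site_start, h.accepted, h.score) for h in hits]
            assert got == _brute_force_scan(MIRNA, transcripts, mm)

    def test_relaxing_candidate_distance_never_removes_accepted_hits(self):
        rng = np.random.default_rng(8)
        transcripts = {f"t{i}": _random_seq(rng, 300) for i in range(5)}
        seq = list(transcripts["t0"])
        seq[40:61] = list(make_site(MIRNA, "all_pass", rng))
        transcripts["t0"] = "".join(seq)
        tight = {
            (h.target_id, h.site_start)
            for h in scan_transcriptome(MIRNA, transcripts, candidate_max_mm=2)
            if h.accepted
        }
        loose = {
            (h.target_id, h.site_start)
            for h in scan_transcriptome(MIRNA, transcripts, candidate_max_mm=6)
            if h.accepted
        }
        assert tight <= loose

    def test_reverse_complement_scan_mirrors_candidate_positions(self):
        # a site for miRNA m on the + strand corresponds to a site for
        # revcomp(m) at the strand-flipped coordinates of the - strand
        rng = np.random.default_rng(9)
        tx = _random_seq(rng, 300)
        tx = tx[:100] + revcomp(MIRNA) + tx[121:]
        n = len(tx)
        fwd = {h.site_start for h in scan_transcriptome(MIRNA, {"t": tx})}
        rev = scan_transcriptome(revcomp(MIRNA), {"t": revcomp(tx)})
        assert {n - h.site_end for h in rev} == fwd

    def test_short_transcripts_skipped(self):
        assert scan_transcriptome(MIRNA, {"short": "ACGT"}) == []


class TestClassifyCleavage:
    def _site(self):
        return score_duplex(
            MIRNA, revcomp(MIRNA), target_id="t1", site_start=100
        )

    def test_canonical_position_opposite_slicing_boundary(self):
        # 21-nt site at [100, 121): miRNA position 10 faces coordinate 111
        site = self._site()
        summary = classify_cleavage(site, [111, 111, 111])
        assert summary.canonical_position == 111
        assert summary.n_canonical == summary.n_in_window == 3

    def test_clone_outside_100nt_window_excluded(self):
        site = self._site()  # center = 110, window [60, 160)
        summary = classify_cleavage(site, [170])
        assert summary.n_in_window == 0

    def test_clone_at_window_edges(self):
        site = self._site()
        summary = classify_cleavage(site, [60, 159, 160])
        assert summary.n_in_window == 2

    def test_counts_are_nested(self):
        site = self._site()
        summary = classify_cleavage(site, [111, 115, 300])
        assert summary.n_canonical <= summary.n_in_window <= len(summary.clone_positions)
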