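import numpy as np
import pytest

from hypoxamir.core_io import revcomp
from hypoxamir.novel_mirna import (
    DiscoveryConfig,
    GenomicLocus,
    HairpinCandidate,
    discover_novel,
    evaluate_hairpin,
    excise_and_fold,
    filter_candidates,
    find_exact_hits,
    min_hamming_window,
)
from hypoxamir.smallrna import TagRecord


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _genome_with_tag(seed=0, n=5000):
    rng = np.random.default_rng(seed)
    genome = {"chr1": _random_seq(rng, n)}
    tag = genome["chr1"][2000:2021]
    return genome, tag


class TestFilterCascade:
    def test_abundance_threshold_is_inclusive_at_100_reads(self):
        genome, tag = _genome_with_tag()
        kept, report = filter_candidates(
            [TagRecord(tag, 99, 0)], genome, [], [], []
        )
        assert kept == [] and report.abundance_pass == 0
        kept, report = filter_candidates(
            [TagRecord(tag, 100, 0)], genome, [], [], []
        )
        assert len(kept) == 1 and report.abundance_pass == 1

    def test_tag_identical_to_known_mirna_removed(self):
        genome, tag = _genome_with_tag()
        kept, report = filter_candidates(
            [TagRecord(tag, 500, 0)], genome, [], [tag], []
        )
        assert kept == []
        assert report.known_filtered == 0

    def test_hamming_two_removed_but_three_retained(self):
        genome, tag = _genome_with_tag()
        flip = str.maketrans("ACGT", "CGTA")  # guaranteed substitutions
        two_off = tag[:2].translate(flip) + tag[2:]
        three_off = tag[:3].translate(flip) + tag[3:]
        assert min_hamming_window(tag, two_off) == 2
        assert min_hamming_window(tag, three_off) == 3
        kept, _ = filter_candidates([TagRecord(tag, 500, 0)], genome, [], [two_off], [])
        assert kept == []
        kept, _ = filter_candidates([TagRecord(tag, 500, 0)], genome, [], [three_off], [])
        assert len(kept) == 1

    def test_repeat_overlap_removed(self):
        genome, tag = _genome_with_tag()
        kept, report = filter_candidates(
            [TagRecord(tag, 500, 0)], genome, [("chr1", 1990, 2010)], [], []
        )
        assert kept == []
        assert report.repeat_filtered == 0

    def test_unmapped_tag_removed_at_genome_stage(self):
        genome, _ = _genome_with_tag()
        alien = "T" * 21
        kept, report = filter_candidates([TagRecord(alien, 500, 0)], genome, [], [], [])
        assert kept == []
        assert report.genome_mapped == 0

    def test_cascade_counts_non_increasing(self, tiny_e2e):
        c = tiny_e2e.cascade.as_dict()
        order = [
            "input_unique",
            "abundance_pass",
            "genome_mapped",
            "repeat_filtered",
            "known_filtered",
            "structure_pass",
        ]
        values = [c[k] for k in order]
        assert values == sorted(values, reverse=True)

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            filter_candidates([], {}, [], [], [])

    def test_minus_strand_hits_found(self):
        genome, tag = _genome_with_tag()
        hits = find_exact_hits(genome, revcomp(tag))
        assert any(h.strand == "-" and h.start == 2000 for h in hits)


class TestExciseAndFold:
    def test_two_windows_containing_the_tag(self):
        genome, _ = _genome_with_tag(seed=3, n=3000)
        locus = GenomicLocus("chr1", 1000, 1021, "+")
        cands = excise_and_fold(genome, locus, flank_up=20, flank_dn=120)
        assert len(cands) == 2
        for cand in cands:
            assert len(cand.precursor_seq) == 161
            ms, me = cand.mature_span
            assert cand.precursor_seq[ms:me] == genome["chr1"][1000:1021]

    def test_minus_strand_precursor_is_reverse_complement(self):
        genome, _ = _genome_with_tag(seed=4, n=3000)
        locus = GenomicLocus("chr1", 1000, 1021, "-")
        (cand, _) = excise_and_fold(genome, locus, flank_up=20, flank_dn=120)
        expected = revcomp(genome["chr1"][1000 - 120 : 1021 + 20])
        assert cand.precursor_seq == expected
        ms, me = cand.mature_span
        assert cand.precursor_seq[ms:me] == revcomp(genome["chr1"][1000:1021])

    def test_window_beyond_contig_clipped_and_flagged(self):
        genome = {"chr1": "ACGT" * 30}
        locus = GenomicLocus("chr1", 5, 26, "+")
        cands = excise_and_fold(genome, locus, flank_up=50, flank_dn=50)
        assert all(c.clipped for c in cands)


def _designed_candidate(seed=0, stem=60):
    """Perfect-complement hairpin with the mature tag on the 5' arm."""
    rng = np.random.default_rng(seed)
    arm = _random_seq(rng, stem)
    loop = "".join(rng.choice(list("AC"), 8))
    precursor = arm + loop + revcomp(arm)
    genome = {"chr1": _random_seq(rng, 500) + precursor + _random_seq(rng, 500)}
    mstart = 500 + 10
    locus = GenomicLocus("chr1", mstart, mstart + 21, "+")
    return genome, locus


class TestEvaluateHairpin:
    def test_designed_hairpin_passes_all_criteria(self):
        genome, locus = _designed_candidate()
        cands = excise_and_fold(genome, locus)
        assert any(evaluate_hairpin(c).passed for c in cands)
        passing = [c for c in cands if c.passed]
        assert passing[0].arm == "5p"
        assert passing[0].mfe <= -18

    def test_star_interval_covers_the_partner_arm(self):
        genome, locus = _designed_candidate(seed=2)
        cands = excise_and_fold(genome, locus)
        cand = next(c for c in cands if evaluate_hairpin(c).passed)
        lo, hi = cand.star_interval
        ms, me = cand.mature_span
        assert hi - lo >= 15
        assert hi <= ms or lo >= me  # star does not overlap the mature span

    def test_mature_straddling_terminal_loop_fails(self):
        # hand-drawn stem-loop: 10 bp stem, 5-nt loop; mature spans the loop
        structure = "(" * 10 + "." * 5 + ")" * 10
        cand = HairpinCandidate(
            tag_seq="X",
            locus=GenomicLocus("chr1", 0, 25, "+"),
            precursor_seq="GGGGGGGGGGAAAAACCCCCCCCCC",
            mature_span=(7, 18),
            structure=structure,
            mfe=-30.0,
        )
        evaluate_hairpin(cand)
        assert not cand.passed
        assert not cand.criteria["loop_overlap"] or not cand.criteria["single_arm"]

    def test_five_unpaired_mature_bases_fail_duplex_criterion(self):
        # 21-nt mature on the 5' arm with 5 internal unpaired bases
        structure = "(((((.....((((((((((((" + "." * 4 + "))))))))))))...)))))"
        seq = "A" * len(structure)
        cand = HairpinCandidate(
            tag_seq="X",
            locus=GenomicLocus("chr1", 0, len(seq), "+"),
            precursor_seq=seq,
            mature_span=(1, 22),
            structure=structure,
            mfe=-30.0,
        )
        evaluate_hairpin(cand)
        assert not cand.criteria["max_unpaired"]

    def test_weak_folding_energy_fails_mfe_criterion(self):
        genome, locus = _designed_candidate(seed=5)
        cands = excise_and_fold(genome, locus)
        cand = next(c for c in cands if evaluate_hairpin(c).passed)
        cand.mfe = -5.0
        evaluate_hairpin(cand)
        assert not cand.criteria["mfe"]
        assert not cand.passed

    def test_unfolded_candidate_rejected(self):
        cand = HairpinCandidate(
            tag_seq="X",
            locus=GenomicLocus("chr1", 0, 21, "+"),
            precursor_seq="ACGT",
            mature_span=(0, 4),
        )
        with pytest.raises(ValueError):
            evaluate_hairpin(cand)


def _dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson shuffle preserving dinucleotide counts."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    for a in edges:
        rng.shuffle(edges[a])
    # ensure connectivity to the last character (Eulerian path condition):
    # retry the naive walk until it consumes every edge
    for _ in range(100):
        trial = {a: list(v) for a, v in edges.items()}
        for a in trial:
            rng.shuffle(trial[a])
        out = [seq[0]]
        while trial.get(out[-1]):
            out.append(trial[out[-1]].pop())
        if len(out) == len(seq):
            return "".join(out)
    return seq


class TestShuffledControls:
    def test_shuffled_precursors_rarely_pass(self):
        genome, locus = _designed_candidate(seed=7)
        cands = excise_and_fold(genome, locus)
        cand = next(c for c in cands if evaluate_hairpin(c).passed)
        rng = np.random.default_rng(11)
        passes = 0
        n = 200
        for _ in range(n):
            shuffled = _dinucleotide_shuffle(cand.precursor_seq, rng)
            trial = HairpinCandidate(
                tag_seq=cand.tag_seq,
                locus=cand.locus,
                precursor_seq=shuffled,
                mature_span=cand.mature_span,
            )
            from hypoxamir.fold import nussinov_fold

            trial.structure, trial.mfe = nussinov_fold(shuffled)
            evaluate_hairpin(trial)
            passes += trial.passed
        assert passes / n <= 0.05


class TestDiscoverNovel:
    def test_planted_hairpins_recovered_and_nothing_else(self, tiny_e2e):
        truth = {h["mature_seq"] for h in tiny_e2e.manifest.planted_hairpins}
        found = set(tiny_e2e.novel_table["mature_seq"])
        assert found == truth

    def test_low_abundance_tags_yield_no_calls(self):
        genome, locus = _designed_candidate(seed=8)
        tag = genome["chr1"][locus.start : locus.end]
        table, report, _ = discover_novel(
            [TagRecord(tag, 30, 20)], genome, [], [], []
        )
        assert len(table) == 0
        assert report.abundance_pass == 0

    def test_tag_near_known_mirna_yields_no_calls(self):
        genome, locus = _designed_candidate(seed=9)
        tag = genome["chr1"][locus.start : locus.end]
        near = "GG" + tag[2:]
        table, _, _ = discover_novel([TagRecord(tag, 500, 0)], genome, [], [near], [])
        assert len(table) == 0
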