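"""End-to-end orchestration of the full analysis on one dataset.

Wires the stages together in study order — libraries -> trimming/collapsing
-> known-miRNA DE -> novel hairpin discovery -> target scan -> promoter
motif enrichment -> expression tables -> network assembly — and, when run on
synthetic data, scores every stage against the truth manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import promoter_motif, smallrna, synthetic_data
from .core_io import dna
from .expression import call_negative_correlation, quantify_ct_table
from .network_builder import build_network, find_feedback_loops, summarize_network
from .novel_mirna import DiscoveryConfig, discover_novel
from .promoter_motif import extract_promoter, motif_enrichment
from .smallrna import annotate_signatures, collapse_tags, de_filter, trim_adapter
from .synthetic_data import (
    GenomeParams,
    LibraryParams,
    simulate_expression_tables,
    simulate_genome,
    simulate_libraries,
    simulate_transcript_targets,
)
from .target_scan import scan_transcriptome


def sample_background_sequences(
    genome: dict[str, str],
    n: int,
    length: int,
    seed: int,
    exclude: list[tuple[str, int, int]] | None = None,
) -> list[str]:
    """Length-matched random genomic windows (the enrichment background).

    Windows overlapping ``exclude`` intervals (normally the foreground
    promoters themselves) are rejected and redrawn, so the background
    estimates the genomic rate outside the regions under test.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    exclude = exclude or []
    out: list[str] = []
    attempts = 0
    while len(out) < n and attempts < 100 * n:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        seq = dna(genome[chrom])
        if len(seq) <= length:
            out.append(seq)
            continue
        start = int(rng.integers(0, len(seq) - length))
        end = start + length
        if any(c == chrom and start < e and s < end for c, s, e in exclude):
            continue
        out.append(seq[start:end])
    if len(out) < n:
        raise RuntimeError("could not sample enough background windows")
    return out


def chi_square_type1_study(
    n_signatures: int = 10_000, rate: float = 100.0, total: int = 1_000_000, seed: int = 0
) -> float:
    """Empirical type-I error of the DE chi-square test at alpha = 0.01.

    Simulates null signatures with equal Poisson rates in two libraries of
    the given total and returns the fraction rejected at P < 0.01.
    """
    rng = np.random.default_rng(seed)
    a = rng.poisson(rate, size=n_signatures)
    b = rng.poisson(rate, size=n_signatures)
    rejected = 0
    for ca, cb in zip(a, b):
        _, p, _ = smallrna.chi_square_de(int(ca), total, int(cb), total)
        if p < 0.01:
            rejected += 1
    return rejected / n_signatures


def target_rule_study(n_per_class: int = 100, mirna_len: int = 21, seed: int = 0) -> dict:
    """Acceptance/rejection rates for sites violating exactly one rule.

    For each scoring rule, ``n_per_class`` random miRNAs get a site violating
    only that rule (expected rejection rate 1.0); all-pass sites measure
    recall (expected acceptance rate 1.0).
    """
    from .synthetic_data import SITE_PROFILES, make_site, _random_seq
    from .target_scan import score_duplex

    rng = np.random.default_rng(seed)
    rates: dict[str, float] = {}
    for profile in SITE_PROFILES:
        if profile == "distance7":
            continue
        accepted = 0
        for _ in range(n_per_class):
            mirna = _random_seq(rng, mirna_len)
            site = make_site(mirna, profile, rng)
            if score_duplex(mirna, site).accepted:
                accepted += 1
        rates[profile] = accepted / n_per_class
    return rates


def motif_null_study(
    n_runs: int = 100,
    n_promoters: int = 5,
    promoter_len: int = 600,
    n_planted: int = 2,
    n_decoys: int = 2,
    n_background: int = 30,
    seed: int = 0,
) -> dict:
    """Repeated planted-vs-decoy enrichment runs on random promoters.

    Each run plants one consensus of every planted PWM three times per
    promoter and leaves decoys unplanted; returns how many runs recover all
    planted PWMs, how many select any decoy, and the run count.
    """
    from .core_io import PositionWeightMatrix
    from .synthetic_data import _random_seq

    rng = np.random.default_rng(seed)
    full_recovery = 0
    runs_with_decoy = 0
    clean_runs = 0
    width = 10
    for _ in range(n_runs):
        pwms = []
        for i in range(n_planted + n_decoys):
            consensus = _random_seq(rng, width)
            matrix = np.full((4, width), 5.0)
            for col, base in enumerate(consensus):
                matrix["ACGT".index(base), col] = 85.0
            pwms.append(
                PositionWeightMatrix(f"M{i + 1}", f"TF{i + 1}", matrix, f"FAM{i + 1}")
            )
        promoters = []
        for p in range(n_promoters):
            seq = list(_random_seq(rng, promoter_len))
            slot = 0
            for pwm in pwms[:n_planted]:
                consensus = pwm.consensus()
                for _ in range(3):
                    pos = slot * (width + 5)
                    seq[pos : pos + width] = list(consensus)
                    slot += 1
            promoters.append(
                promoter_motif.PromoterSequence(f"p{p}", 0, "+", "".join(seq))
            )
        background = [_random_seq(rng, promoter_len) for _ in range(n_background)]
        results = motif_enrichment(promoters, pwms, background)
        selected = {r.motif_id for r in results if r.selected}
        planted_ids = {f"M{i + 1}" for i in range(n_planted)}
        if planted_ids <= selected:
            full_recovery += 1
        if selected - planted_ids:
            runs_with_decoy += 1
        if planted_ids <= selected and not (selected - planted_ids):
            clean_runs += 1
    return {
        "n_runs": n_runs,
        "full_recovery": full_recovery,
        "runs_with_decoy": runs_with_decoy,
        "clean_runs": clean_runs,
    }


@dataclass
class StageScores:
    true_positives: int
    false_positives: int
    false_negatives: int

    @property
    def precision(self) -> float:
        denom = self.true_positives + self.false_positives
        return self.true_positives / denom if denom else 1.0

    @property
    def recall(self) -> float:
        denom = self.true_positives + self.false_negatives
        return self.true_positives / denom if denom else 1.0


def _score_sets(found: set, truth: set) -> StageScores:
    return StageScores(
        true_positives=len(found & truth),
        false_positives=len(found - truth),
        false_negatives=len(truth - found),
    )


@dataclass
class EndToEndResult:
    manifest: synthetic_data.TruthManifest
    library_stats: tuple
    de_signatures: list
    novel_table: pd.DataFrame
    cascade: object
    accepted_sites: list
    enrichment: list
    network: object
    summary: object
    scores: dict[str, StageScores] = field(default_factory=dict)


def run_end_to_end(
    seed: int = 0,
    genome_params: GenomeParams | None = None,
    library_params: LibraryParams | None = None,
    n_transcripts: int = 100,
    n_background_promoters: int = 200,
) -> EndToEndResult:
    """Simulate a dataset and push it through every pipeline stage,
    scoring each planted feature class against the manifest."""
    sim = simulate_genome(genome_params, seed=seed)
    manifest = sim.manifest
    reads_t, reads_c = simulate_libraries(manifest, library_params, seed=seed + 1)
    adapter = manifest.library["adapter"]

    inserts_t = [trim_adapter(r.seq, adapter) for r in reads_t]
    inserts_c = [trim_adapter(r.seq, adapter) for r in reads_c]
    tags, stats_pair = collapse_tags(inserts_t, inserts_c)
    totals = (stats_pair[0].filtered_reads, stats_pair[1].filtered_reads)

    signatures = smallrna.quantify_known(tags, sim.known_catalog)
    annotate_signatures(signatures, totals[0], totals[1])
    de = de_filter(signatures)
    de_found = {s.signature_id for s in de}
    de_truth = {m for m in manifest.de_truth() if not m.startswith("miRn")}

    known_matures = [m for _, m, _ in sim.known_catalog]
    novel_table, cascade, _ = discover_novel(
        tags, sim.genome, sim.repeats, known_matures, sim.ncrna_seqs, DiscoveryConfig()
    )
    novel_found = set(novel_table["mature_seq"])
    novel_truth = {dna(h["mature_seq"]) for h in manifest.planted_hairpins}

    transcripts = simulate_transcript_targets(
        manifest, n_transcripts=n_transcripts, seed=seed + 2
    )
    matures = {m["signature_id"]: m["mature_seq"] for m in manifest.known_mirnas}
    matures.update({h["name"]: h["mature_seq"] for h in manifest.planted_hairpins})
    accepted_sites = []
    de_all = sorted(manifest.de_truth())
    for mirna_id in de_all:
        hits = scan_transcriptome(matures[mirna_id], transcripts, mirna_id=mirna_id)
        accepted_sites.extend(h for h in hits if h.accepted)
    sites_found = {(h.mirna_id, h.target_id, h.site_start) for h in accepted_sites}
    sites_truth = {
        (s["mirna_id"], s["transcript_id"], s["offset"])
        for s in manifest.target_sites
        if s["profile"] == "all_pass"
    }

    promoters = [extract_promoter(sim.genome, t) for t in sim.tss_records]
    promoter_intervals = [
        (t.chrom, t.tss_pos - 1000, t.tss_pos + 500)
        if t.strand == "+"
        else (t.chrom, t.tss_pos - 500, t.tss_pos + 1000)
        for t in sim.tss_records
    ]
    background = sample_background_sequences(
        sim.genome, n_background_promoters, 1500, seed + 3, exclude=promoter_intervals
    )
    enrichment = motif_enrichment(promoters, sim.pwms, background)
    selected = {r.motif_id for r in enrichment if r.selected}
    planted_pwms = {p["motif_id"] for p in manifest.pwms if p["planted"]}

    tf_mirna_rows = []
    for res in enrichment:
        if not res.selected:
            continue
        for gene_id, count in res.per_promoter_counts.items():
            if count >= 3:
                tf_mirna_rows.append({"mirna_id": gene_id, "tf_family": res.tf_family})
    tf_mirna_table = pd.DataFrame(tf_mirna_rows, columns=["mirna_id", "tf_family"])
    tf_edges_found = {(r["tf_family"], r["mirna_id"]) for r in tf_mirna_rows}
    tf_edges_truth = {
        (p["tf_family"], p["gene_id"]) for p in manifest.planted_motifs
    }

    ct_table, _traits = simulate_expression_tables(manifest, seed=seed + 4)
    profiles = quantify_ct_table(ct_table)

    def profile_of(entity: str) -> pd.DataFrame:
        sub = profiles[profiles["entity"] == entity]
        return sub.pivot(index="line", columns="time", values="log2_ratio").sort_index()

    mirna_target_rows = []
    assayable = {
        (h.mirna_id, h.target_id)
        for h in accepted_sites
        if h.target_id in manifest.transcript_tf_family
    }
    for mirna_id, tid in sorted(assayable):
        if mirna_id not in manifest.qpcr_truth or tid not in manifest.qpcr_truth:
            continue
        call, _ = call_negative_correlation(profile_of(mirna_id), profile_of(tid))
        if call:
            mirna_target_rows.append(
                {"mirna_id": mirna_id, "tf_family": manifest.transcript_tf_family[tid]}
            )
    mirna_target_table = pd.DataFrame(
        mirna_target_rows, columns=["mirna_id", "tf_family"]
    )
    target_edges_found = {(r["mirna_id"], r["tf_family"]) for r in mirna_target_rows}
    target_edges_truth = {
        (m, manifest.transcript_tf_family[t]) for m, t in manifest.anticorrelated_pairs
    }

    regulation = pd.DataFrame(
        [
            {"mirna_id": m, "regulation": "up" if f > 1 else "down"}
            for m, f in manifest.fold_map.items()
        ]
    )
    network = build_network(tf_mirna_table, mirna_target_table, regulation)
    summary = summarize_network(network)

    scores = {
        "de": _score_sets(de_found, de_truth),
        "novel": _score_sets(novel_found, novel_truth),
        "target_sites": _score_sets(sites_found, sites_truth),
        "motifs": _score_sets(selected, planted_pwms),
        "tf_mirna_edges": _score_sets(tf_edges_found, tf_edges_truth),
        "mirna_target_edges": _score_sets(target_edges_found, target_edges_truth),
    }
    return EndToEndResult(
        manifest=manifest,
        library_stats=stats_pair,
        de_signatures=de,
        novel_table=novel_table,
        cascade=cascade,
        accepted_sites=accepted_sites,
        enrichment=enrichment,
        network=network,
        summary=summary,
        scores=scores,
    )
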