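"""Promoter extraction and PWM over-representation analysis.

Promoters are taken as the strand-oriented window from 1000 bp upstream to
500 bp downstream of a pri-miRNA TSS.  Binding sites are log-odds PWM hits
(both strands, threshold a fraction of each matrix's maximum attainable
score).  Over-representation compares total foreground hit counts against a
per-position background rate estimated from random genomic sequences using
an upper-tail binomial test, Bonferroni-corrected across motifs; a motif is
selected only if, additionally, at least one promoter carries three or more
occurrences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import PositionWeightMatrix, TssRecord, dna, revcomp

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass
class PromoterSequence:
    gene_id: str
    tss: int
    strand: str
    seq: str
    clipped: bool = False


@dataclass
class MotifHit:
    motif_id: str
    gene_id: str
    offset: int
    strand: str
    score: float


@dataclass
class EnrichmentResult:
    motif_id: str
    tf_family: str
    observed_hits: int
    promoters_ge3: int
    background_rate: float
    p_raw: float
    p_bonferroni: float
    selected: bool
    rate_floored: bool = False
    per_promoter_counts: dict[str, int] = field(default_factory=dict)


def extract_promoter(
    genome: dict[str, str], tss_record: TssRecord, up: int = 1000, down: int = 500
) -> PromoterSequence:
    """Strand-oriented promoter window around a TSS, clipped at contig edges."""
    if tss_record.chrom not in genome:
        raise KeyError(f"unknown chromosome {tss_record.chrom!r}")
    chrom_seq = dna(genome[tss_record.chrom])
    tss = tss_record.tss_pos
    if tss_record.strand == "+":
        lo, hi = tss - up, tss + down
    else:
        lo, hi = tss - down, tss + up
    clipped = lo < 0 or hi > len(chrom_seq)
    lo, hi = max(0, lo), min(len(chrom_seq), hi)
    seq = chrom_seq[lo:hi]
    if tss_record.strand == "-":
        seq = revcomp(seq)
    return PromoterSequence(tss_record.gene_id, tss, tss_record.strand, seq, clipped)


def genome_base_frequencies(genome: dict[str, str]) -> np.ndarray:
    """A/C/G/T frequencies over the genome (N ignored), uniform fallback."""
    counts = np.zeros(4)
    for seq in genome.values():
        s = dna(seq)
        for base, idx in _BASE_INDEX.items():
            if idx < 4:
                counts[idx] += s.count(base)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def log_odds_matrix(
    pwm: PositionWeightMatrix, background_freqs: np.ndarray, pseudocount: float = 0.1
) -> np.ndarray:
    """5xL log2-odds matrix (last row: N, contributing 0)."""
    probs = pwm.normalized(pseudocount).matrix
    q = np.asarray(background_freqs, dtype=float).reshape(4, 1)
    q = np.maximum(q, 1e-9)  # guard degenerate background compositions
    lod = np.log2(probs / q)
    return np.vstack([lod, np.zeros((1, pwm.width))])


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(c, 4) for c in dna(seq)], dtype=np.int64)


def _window_scores(codes: np.ndarray, lod: np.ndarray) -> np.ndarray:
    L = lod.shape[1]
    if len(codes) < L:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return lod[windows, np.arange(L)].sum(axis=1)


def scan_pwm(
    promoter: PromoterSequence,
    pwm: PositionWeightMatrix,
    background_freqs: np.ndarray,
    score_threshold_frac: float = 0.8,
    pseudocount: float = 0.1,
) -> list[MotifHit]:
    """Log-odds scan of both strands; hits score at least
    ``score_threshold_frac`` of the PWM's maximum attainable score.
    Overlapping hits are allowed."""
    lod = log_odds_matrix(pwm, background_freqs, pseudocount)
    threshold = score_threshold_frac * lod[:4].max(axis=0).sum()
    L = pwm.width
    n = len(promoter.seq)
    hits: list[MotifHit] = []
    fwd = _window_scores(_encode(promoter.seq), lod)
    for off in np.nonzero(fwd >= threshold)[0]:
        hits.append(MotifHit(pwm.motif_id, promoter.gene_id, int(off), "+", float(fwd[off])))
    rev = _window_scores(_encode(revcomp(promoter.seq)), lod)
    for off in np.nonzero(rev >= threshold)[0]:
        hits.append(
            MotifHit(pwm.motif_id, promoter.gene_id, int(n - L - off), "-", float(rev[off]))
        )
    return sorted(hits, key=lambda h: (h.offset, h.strand))


def motif_enrichment(
    promoters: list[PromoterSequence],
    pwms: list[PositionWeightMatrix],
    background_promoters: list[str],
    n_motifs_tested: int | None = None,
    background_freqs: np.ndarray | None = None,
    score_threshold_frac: float = 0.8,
    pseudocount: float = 0.1,
    p_max: float = 0.001,
    min_occurrences: int = 3,
    min_promoters_ge3: int = 1,
) -> list[EnrichmentResult]:
    """Binomial over-representation of each PWM in foreground promoters
    versus length-matched background sequences.

    The background per-position hit rate is estimated per motif from
    ``background_promoters``; a motif with zero background hits has its rate
    floored at 0.5 / (total background positions) and is flagged.
    """
    if n_motifs_tested is None:
        n_motifs_tested = len(pwms)
    if n_motifs_tested < len(pwms):
        raise ValueError("n_motifs_tested must cover every PWM tested")
    if background_freqs is None:
        joined = {"bg": "".join(background_promoters)} if background_promoters else {}
        background_freqs = genome_base_frequencies(joined)

    bg_seqs = [
        PromoterSequence(f"bg{i}", 0, "+", s) for i, s in enumerate(background_promoters)
    ]
    results: list[EnrichmentResult] = []
    for pwm in pwms:
        L = pwm.width
        fg_positions = sum(
            2 * max(0, len(p.seq) - L + 1) for p in promoters
        )
        bg_positions = sum(2 * max(0, len(p.seq) - L + 1) for p in bg_seqs)
        per_promoter: dict[str, int] = {}
        observed = 0
        for prom in promoters:
            n_hits = len(
                scan_pwm(prom, pwm, background_freqs, score_threshold_frac, pseudocount)
            )
            per_promoter[prom.gene_id] = n_hits
            observed += n_hits
        bg_hits = sum(
            len(scan_pwm(p, pwm, background_freqs, score_threshold_frac, pseudocount))
            for p in bg_seqs
        )
        floored = bg_hits == 0
        rate = max(bg_hits, 0.5) / bg_positions if bg_positions else 0.5
        p_raw = (
            float(stats.binom.sf(observed - 1, fg_positions, min(rate, 1.0)))
            if observed > 0
            else 1.0
        )
        p_bonf = min(1.0, p_raw * n_motifs_tested)
        promoters_ge3 = sum(1 for c in per_promoter.values() if c >= min_occurrences)
        results.append(
            EnrichmentResult(
                motif_id=pwm.motif_id,
                tf_family=pwm.tf_family,
                observed_hits=observed,
                promoters_ge3=promoters_ge3,
                background_rate=rate,
                p_raw=p_raw,
                p_bonferroni=p_bonf,
                selected=(p_bonf < p_max) and (promoters_ge3 >= min_promoters_ge3),
                rate_floored=floored,
                per_promoter_counts=per_promoter,
            )
        )
    return results
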