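"""Plant miRNA target prediction with positional mismatch rules.

A candidate site is an ungapped transcript window of the miRNA's length
within Hamming distance 6 of the reverse-complemented miRNA.  Each candidate
is scored per miRNA position (1-based from the miRNA 5' end): Watson-Crick
pairs score 0, everything else — including G:U wobbles by default — scores
1.  A site is accepted iff all four rules hold:

* at most one scored position within 2..12 (the seed-proximal region),
* no scored position at 10 or 11 (the slicing positions),
* no run of 3+ consecutive scored positions entirely after position 12,
* at most 4 scored positions over the whole miRNA.

``wobble_score`` may be set to 0.5 (the Schwab convention), in which case
the rule thresholds are compared against summed per-position scores.

Cleavage-clone classification counts cloned mRNA 5' ends inside a 100-nt
window centered on the site and those exactly at the canonical slicing
coordinate, opposite the boundary between miRNA positions 10 and 11.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core_io import dna, revcomp

MATCH = "match"
WOBBLE = "wobble"
MISMATCH = "mismatch"

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE_PAIRS = {("G", "T"), ("T", "G")}  # G:U in DNA space


@dataclass
class DuplexAlignment:
    """One miRNA:target site with per-position states and rule verdicts."""

    mirna_id: str
    mirna_seq: str
    target_id: str
    site_start: int
    site_end: int
    states: list[str]
    scores: list[float]
    score: float
    rule_verdicts: dict[str, bool]
    accepted: bool


@dataclass
class CleavageSummary:
    target_id: str
    site: DuplexAlignment
    clone_positions: list[int]
    window: int
    n_in_window: int
    n_canonical: int
    canonical_position: int


def score_duplex(
    mirna_seq: str,
    site_seq: str,
    mirna_id: str = "",
    target_id: str = "",
    site_start: int = 0,
    wobble_score: float = 1.0,
) -> DuplexAlignment:
    """Score a site against a miRNA and evaluate the positional rules.

    ``site_seq`` is the transcript window 5'->3'; miRNA position ``i``
    (1-based from the miRNA 5' end) faces site position ``L - i`` (0-based).
    """
    m = dna(mirna_seq)
    s = dna(site_seq)
    if len(m) != len(s):
        raise ValueError(f"miRNA length {len(m)} != site length {len(s)}")
    if "-" in mirna_seq or "-" in site_seq:
        raise ValueError("gapped duplexes are not supported")
    L = len(m)
    states: list[str] = []
    scores: list[float] = []
    for i in range(1, L + 1):
        mb = m[i - 1]
        tb = s[L - i]
        if (mb, tb) in _WC:
            states.append(MATCH)
            scores.append(0.0)
        elif (mb, tb) in _WOBBLE_PAIRS:
            states.append(WOBBLE)
            scores.append(wobble_score)
        else:
            states.append(MISMATCH)
            scores.append(1.0)

    total = sum(scores)
    seed_sum = sum(scores[i - 1] for i in range(2, min(12, L) + 1))
    slicing_clean = all(scores[i - 1] == 0 for i in (10, 11) if i <= L)

    # longest run of consecutively scored positions located wholly after 12
    run = longest = 0
    for i in range(13, L + 1):
        if scores[i - 1] > 0:
            run += 1
            longest = max(longest, run)
        else:
            run = 0

    verdicts = {
        "r_seed_le1": seed_sum <= 1.0,
        "r_no_mm_10_11": slicing_clean,
        "r_consec_le2_after12": longest <= 2,
        "r_total_le4": total <= 4.0,
    }
    return DuplexAlignment(
        mirna_id=mirna_id,
        mirna_seq=mirna_seq,
        target_id=target_id,
        site_start=site_start,
        site_end=site_start + L,
        states=states,
        scores=scores,
        score=total,
        rule_verdicts=verdicts,
        accepted=all(verdicts.values()),
    )


def scan_transcriptome(
    mirna_seq: str,
    transcripts: dict[str, str],
    candidate_max_mm: int = 6,
    mirna_id: str = "",
    wobble_score: float = 1.0,
) -> list[DuplexAlignment]:
    """Score every transcript window within ``candidate_max_mm`` Hamming
    distance of the reverse-complemented miRNA.

    Returns all candidates (accepted ones flagged), sorted by
    ``(target_id, site_start)``.  Transcripts shorter than the miRNA are
    skipped.
    """
    query = revcomp(mirna_seq)
    L = len(query)
    hits: list[DuplexAlignment] = []
    for target_id in sorted(transcripts):
        seq = dna(transcripts[target_id])
        if len(seq) < L:
            continue
        for start in range(len(seq) - L + 1):
            window = seq[start : start + L]
            mm = sum(1 for a, b in zip(window, query) if a != b)
            if mm <= candidate_max_mm:
                hits.append(
                    score_duplex(
                        mirna_seq,
                        window,
                        mirna_id=mirna_id,
                        target_id=target_id,
                        site_start=start,
                        wobble_score=wobble_score,
                    )
                )
    return hits


def canonical_cleavage_position(site: DuplexAlignment) -> int:
    """Transcript coordinate of the base facing miRNA position 10.

    Slicing occurs between miRNA positions 10 and 11; the cloned 3' cleavage
    fragment therefore starts at the base opposite position 10, i.e.
    ``site_start + L - 10`` (0-based).
    """
    L = site.site_end - site.site_start
    return site.site_start + L - 10


def classify_cleavage(
    site: DuplexAlignment, clone_positions: list[int], window: int = 100
) -> CleavageSummary:
    """Count cloned 5' ends inside the window centered on the site and at
    the canonical slicing coordinate."""
    L = site.site_end - site.site_start
    center = site.site_start + L // 2
    lo, hi = center - window // 2, center + window // 2
    canonical = canonical_cleavage_position(site)
    in_window = [p for p in clone_positions if lo <= p < hi]
    n_canonical = sum(1 for p in in_window if p == canonical)
    return CleavageSummary(
        target_id=site.target_id,
        site=site,
        clone_positions=list(clone_positions),
        window=window,
        n_in_window=len(in_window),
        n_canonical=n_canonical,
        canonical_position=canonical,
    )
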