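"""Small-RNA tag processing and differential expression.

The processing chain mirrors a two-library (treatment vs control) small-RNA
sequencing experiment: 3' adapter trimming, an 18-26 nt insert size filter,
exact-sequence tag collapsing, reads-per-million (RPM) normalization against
the library's usable (filtered) read total, quantification of known mature
miRNA signatures by perfect sequence match, and a differential-expression
filter combining a 2x2 Pearson chi-square test on raw counts (P < 0.01), a
symmetric 1.5-fold RPM change, and a > 50 RPM abundance floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import dna

MIN_INSERT = 18
MAX_INSERT = 26

# trim_adapter outcome markers
ADAPTER_ONLY = "adapter_only"
UNTRIMMED = "untrimmed"


class CatalogError(ValueError):
    """Raised for an inconsistent mature-miRNA catalog."""


@dataclass
class TagRecord:
    """A unique insert sequence with per-library counts and RPM values."""

    seq: str
    count_treatment: int
    count_control: int
    rpm_treatment: float = 0.0
    rpm_control: float = 0.0

    @property
    def total(self) -> int:
        return self.count_treatment + self.count_control


@dataclass
class LibraryStats:
    """Read-accounting summary for one sequenced library."""

    library_id: str
    total_reads: int = 0
    adapter_only: int = 0
    too_short: int = 0
    too_long: int = 0
    with_n: int = 0
    untrimmed: int = 0
    filtered_reads: int = 0
    unique_tags: int = 0
    size_histogram: dict[int, int] = field(default_factory=dict)

    @property
    def frac_20_24(self) -> float:
        if self.filtered_reads == 0:
            return 0.0
        in_range = sum(self.size_histogram.get(k, 0) for k in range(20, 25))
        return in_range / self.filtered_reads


@dataclass
class SignatureExpression:
    """Expression of one mature miRNA signature (possibly multi-locus)."""

    signature_id: str
    mature_seq: str
    locus_ids: list[str]
    count_treatment: int
    count_control: int
    rpm_treatment: float = 0.0
    rpm_control: float = 0.0
    fold_change: float = math.nan
    chi2: float = math.nan
    p_value: float = math.nan
    low_expectation: bool = False
    passes_filter: bool = False

    @property
    def log2_fold(self) -> float:
        return math.log2(self.fold_change)


def trim_adapter(read_seq: str, adapter3_seq: str, min_overlap: int = 6) -> str:
    """Remove the 3' adapter from a read.

    The leftmost exact occurrence of the adapter's first ``min_overlap``
    bases wins; everything from it onward is removed.  Returns the insert,
    or the :data:`ADAPTER_ONLY` / :data:`UNTRIMMED` marker.
    """
    if not read_seq or not adapter3_seq:
        raise ValueError("read and adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    read = dna(read_seq)
    adapter = dna(adapter3_seq)
    probe = adapter[: min(min_overlap, len(adapter))]
    i = read.find(probe)
    if i == -1:
        return UNTRIMMED
    return ADAPTER_ONLY if i == 0 else read[:i]


def collapse_tags(
    inserts_treatment: list[str], inserts_control: list[str]
) -> tuple[list[TagRecord], tuple[LibraryStats, LibraryStats]]:
    """Size-filter and deduplicate trimmed inserts into tag records.

    Inserts shorter than 18 nt / longer than 26 nt are excluded and counted;
    inserts containing ``N`` are discarded and counted separately.  Survivors
    are collapsed by exact sequence with per-library counts, and RPM is
    computed against each library's filtered-read total.  The special
    markers produced by :func:`trim_adapter` are tallied into the stats.
    """
    counts: dict[str, list[int]] = {}
    stats_pair = (LibraryStats("treatment"), LibraryStats("control"))
    for lib_idx, (inserts, st) in enumerate(
        zip((inserts_treatment, inserts_control), stats_pair)
    ):
        for ins in inserts:
            st.total_reads += 1
            if ins == ADAPTER_ONLY:
                st.adapter_only += 1
                continue
            if ins == UNTRIMMED:
                st.untrimmed += 1
                continue
            seq = dna(ins)
            if "N" in seq:
                st.with_n += 1
                continue
            if len(seq) < MIN_INSERT:
                st.too_short += 1
                continue
            if len(seq) > MAX_INSERT:
                st.too_long += 1
                continue
            st.filtered_reads += 1
            st.size_histogram[len(seq)] = st.size_histogram.get(len(seq), 0) + 1
            counts.setdefault(seq, [0, 0])[lib_idx] += 1
    tags = [
        TagRecord(seq, c[0], c[1]) for seq, c in sorted(counts.items())
    ]
    totals = (stats_pair[0].filtered_reads, stats_pair[1].filtered_reads)
    for tag in tags:
        tag.rpm_treatment = rpm(tag.count_treatment, totals[0])
        tag.rpm_control = rpm(tag.count_control, totals[1])
    stats_pair[0].unique_tags = stats_pair[1].unique_tags = len(tags)
    return tags, stats_pair


def rpm(count: int, library_total: int) -> float:
    """Reads per million of usable (filtered) library reads."""
    if library_total <= 0:
        return 0.0
    return count / library_total * 1e6


def quantify_known(
    tags: list[TagRecord], mature_catalog: list[tuple[str, str, list[str]]]
) -> list[SignatureExpression]:
    """Sum tag counts onto known mature miRNA signatures by perfect match.

    ``mature_catalog`` rows are ``(signature_id, mature_seq, locus_ids)``.
    Matching is exact and T/U-insensitive.  Catalog entries sharing the same
    mature sequence are merged into ONE signature carrying all loci;
    signatures unseen in both libraries are omitted.
    """
    by_seq: dict[str, SignatureExpression] = {}
    id_to_seq: dict[str, str] = {}
    for sig_id, mature_seq, locus_ids in mature_catalog:
        seq = dna(mature_seq)
        if sig_id in id_to_seq and id_to_seq[sig_id] != seq:
            raise CatalogError(
                f"signature {sig_id!r} listed with two different sequences"
            )
        id_to_seq[sig_id] = seq
        if seq in by_seq:
            sig = by_seq[seq]
            for locus in locus_ids:
                if locus not in sig.locus_ids:
                    sig.locus_ids.append(locus)
            if sig_id not in sig.signature_id.split("/"):
                sig.signature_id += f"/{sig_id}"
        else:
            by_seq[seq] = SignatureExpression(
                signature_id=sig_id,
                mature_seq=mature_seq,
                locus_ids=list(locus_ids),
                count_treatment=0,
                count_control=0,
            )
    tag_by_seq = {dna(t.seq): t for t in tags}
    out = []
    for seq, sig in by_seq.items():
        tag = tag_by_seq.get(seq)
        if tag is None or tag.total == 0:
            continue
        sig.count_treatment = tag.count_treatment
        sig.count_control = tag.count_control
        sig.rpm_treatment = tag.rpm_treatment
        sig.rpm_control = tag.rpm_control
        out.append(sig)
    return out


def chi_square_de(
    count_a: int, total_a: int, count_b: int, total_b: int
) -> tuple[float, float, bool]:
    """Pearson chi-square (df=1, no continuity correction) on the 2x2 table
    ``{count_a, total_a-count_a; count_b, total_b-count_b}``.

    Returns ``(chi2, p_value, low_expectation)`` where the flag marks any
    expected cell below 1 (result still computed).
    """
    for count, total in ((count_a, total_a), (count_b, total_b)):
        if total <= 0:
            raise ValueError("library totals must be positive")
        if not 0 <= count <= total:
            raise ValueError("count must satisfy 0 <= count <= total")
    a, b = count_a, total_a - count_a
    c, d = count_b, total_b - count_b
    n = total_a + total_b
    col1, col2 = a + c, b + d
    expected = np.array(
        [
            [total_a * col1 / n, total_a * col2 / n],
            [total_b * col1 / n, total_b * col2 / n],
        ]
    )
    low_expectation = bool((expected < 1).any())
    if col1 == 0 or col2 == 0:
        return 0.0, 1.0, low_expectation
    chi2 = n * (a * d - b * c) ** 2 / (total_a * total_b * col1 * col2)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p, low_expectation


def fold_change(
    count_treatment: int,
    total_treatment: int,
    count_control: int,
    total_control: int,
    pseudocount: float = 0.5,
) -> float:
    """Treatment/control RPM ratio with a pseudocount guarding zero counts.

    The pseudocount (0.5 reads added to both libraries) is used for the fold
    computation only; counts and the chi-square test are untouched.
    """
    num = rpm(count_treatment + pseudocount, total_treatment)
    den = rpm(count_control + pseudocount, total_control)
    return num / den


def annotate_signatures(
    signatures: list[SignatureExpression],
    total_treatment: int,
    total_control: int,
    p_max: float = 0.01,
    fold_min: float = 1.5,
    rpm_min: float = 50.0,
    yates: bool = False,
) -> list[SignatureExpression]:
    """Fill chi-square, P, fold change and the pass/fail verdict in place."""
    for sig in signatures:
        if yates:
            table = [
                [sig.count_treatment, total_treatment - sig.count_treatment],
                [sig.count_control, total_control - sig.count_control],
            ]
            res = stats.chi2_contingency(table, correction=True)
            sig.chi2, sig.p_value = float(res.statistic), float(res.pvalue)
            sig.low_expectation = bool((np.asarray(res.expected_freq) < 1).any())
        else:
            sig.chi2, sig.p_value, sig.low_expectation = chi_square_de(
                sig.count_treatment, total_treatment, sig.count_control, total_control
            )
        sig.fold_change = fold_change(
            sig.count_treatment, total_treatment, sig.count_control, total_control
        )
        sig.passes_filter = (
            sig.p_value < p_max
            and (sig.fold_change >= fold_min or sig.fold_change <= 1.0 / fold_min)
            and max(sig.rpm_treatment, sig.rpm_control) > rpm_min
        )
    return signatures


def de_filter(
    signatures: list[SignatureExpression],
    p_max: float = 0.01,
    fold_min: float = 1.5,
    rpm_min: float = 50.0,
) -> list[SignatureExpression]:
    """Return the signatures passing the DE filter, strongest change first.

    The fold threshold is symmetric (induction or repression); the RPM floor
    applies to the more abundant library.  Assumes chi-square/fold fields
    were filled by :func:`annotate_signatures`.
    """
    for sig in signatures:
        sig.passes_filter = (
            sig.p_value < p_max
            and (sig.fold_change >= fold_min or sig.fold_change <= 1.0 / fold_min)
            and max(sig.rpm_treatment, sig.rpm_control) > rpm_min
        )
    passing = [s for s in signatures if s.passes_filter]
    return sorted(passing, key=lambda s: (-abs(s.log2_fold), s.signature_id))
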