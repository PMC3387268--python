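"""Novel miRNA discovery: candidate filter cascade and hairpin evaluation.

Candidates are abundant small-RNA tags (>= 100 combined reads by default)
that map exactly to the genome at a modest number of loci, avoid annotated
repeats, and are not within Hamming distance 2 of any known miRNA or other
ncRNA.  Each surviving tag's loci are excised with asymmetric flanks, folded,
and screened against hairpin criteria in the miRcheck tradition: the mature
tag must sit in one arm of a single stem-loop, outside the terminal loop,
with at most 4 unpaired mature bases, no asymmetric bulge larger than 2 nt in
the mature:star duplex, and folding energy at or below -18 kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core_io import dna, revcomp
from .fold import Folder, get_folder, pair_table
from .smallrna import TagRecord


@dataclass(frozen=True)
class GenomicLocus:
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class HairpinCandidate:
    """One excised precursor window around a mature tag, with its verdicts."""

    tag_seq: str
    locus: GenomicLocus
    precursor_seq: str
    mature_span: tuple[int, int]  # position of the tag within the precursor
    structure: str = ""
    mfe: float = 0.0
    arm: str = ""
    star_interval: tuple[int, int] | None = None
    clipped: bool = False
    criteria: dict[str, bool] = field(default_factory=dict)
    passed: bool = False


@dataclass
class CascadeReport:
    """Tag counts surviving each stage of the candidate filter cascade."""

    input_unique: int = 0
    abundance_pass: int = 0
    genome_mapped: int = 0
    repeat_filtered: int = 0
    known_filtered: int = 0
    structure_pass: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


@dataclass
class DiscoveryConfig:
    min_reads: int = 100
    max_genome_hits: int = 20
    known_max_mm: int = 2
    flank_up: int = 20
    flank_dn: int = 160
    mfe_max: float = -18.0
    max_unpaired_mature: int = 4
    max_bulge: int = 2
    folder: str = "builtin"


def find_exact_hits(genome: dict[str, str], tag: str) -> list[GenomicLocus]:
    """All exact occurrences of ``tag`` on either strand, in + coordinates."""
    tag = dna(tag)
    queries = ((tag, "+"), (revcomp(tag), "-"))
    hits: list[GenomicLocus] = []
    for chrom, seq in genome.items():
        seq = dna(seq)
        for query, strand in queries:
            start = seq.find(query)
            while start != -1:
                hits.append(GenomicLocus(chrom, start, start + len(query), strand))
                start = seq.find(query, start + 1)
    return hits


def min_hamming_window(query: str, reference: str) -> int:
    """Minimum Hamming distance of the shorter sequence against every
    equal-length window of the longer one."""
    a, b = dna(query), dna(reference)
    if len(a) > len(b):
        a, b = b, a
    best = len(a)
    for off in range(len(b) - len(a) + 1):
        d = sum(1 for x, y in zip(a, b[off : off + len(a)]) if x != y)
        best = min(best, d)
        if best == 0:
            return 0
    return best


def _overlaps_any(locus: GenomicLocus, intervals: list[tuple[str, int, int]]) -> bool:
    for chrom, start, end in intervals:
        if chrom == locus.chrom and locus.start < end and start < locus.end:
            return True
    return False


def filter_candidates(
    tags: list[TagRecord],
    genome: dict[str, str],
    repeat_annotation: list[tuple[str, int, int]],
    known_mirnas: list[str],
    other_ncrnas: list[str],
    min_reads: int = 100,
    max_genome_hits: int = 20,
    known_max_mm: int = 2,
) -> tuple[list[tuple[TagRecord, list[GenomicLocus]]], CascadeReport]:
    """Run the pre-structure filter cascade.

    Removal is attributed to the first failing stage: abundance, genome
    mapping (no exact hit), repetitiveness (too many hits or repeat overlap),
    then known-sequence similarity (Hamming <= ``known_max_mm`` to any known
    miRNA or ncRNA at equal length).
    """
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("genome is empty")
    report = CascadeReport(input_unique=len(tags))
    known_refs = [dna(s) for s in known_mirnas] + [dna(s) for s in other_ncrnas]

    survivors: list[tuple[TagRecord, list[GenomicLocus]]] = []
    abundant = [t for t in tags if t.total >= min_reads]
    report.abundance_pass = len(abundant)

    mapped: list[tuple[TagRecord, list[GenomicLocus]]] = []
    for tag in abundant:
        hits = find_exact_hits(genome, tag.seq)
        if hits:
            mapped.append((tag, hits))
    report.genome_mapped = len(mapped)

    nonrepeat: list[tuple[TagRecord, list[GenomicLocus]]] = []
    for tag, hits in mapped:
        if len(hits) > max_genome_hits:
            continue
        if any(_overlaps_any(h, repeat_annotation) for h in hits):
            continue
        nonrepeat.append((tag, hits))
    report.repeat_filtered = len(nonrepeat)

    for tag, hits in nonrepeat:
        if any(min_hamming_window(tag.seq, ref) <= known_max_mm for ref in known_refs):
            continue
        survivors.append((tag, hits))
    report.known_filtered = len(survivors)
    return survivors, report


def excise_and_fold(
    genome: dict[str, str],
    locus: GenomicLocus,
    flank_up: int = 20,
    flank_dn: int = 160,
    folder: Folder | None = None,
) -> list[HairpinCandidate]:
    """Excise precursor windows around a mature locus and fold them.

    Two windows are generated per flank setting — mature near the 5' end
    (``flank_up`` upstream / ``flank_dn`` downstream) and the mirrored
    placement — so that both arms can host the tag.  Minus-strand loci use
    the reverse complement; windows running off the contig are clipped and
    flagged.
    """
    if flank_up < 0 or flank_dn < 0:
        raise ValueError("flanks must be >= 0")
    folder = folder or get_folder()
    chrom_seq = dna(genome[locus.chrom])
    tag = chrom_seq[locus.start : locus.end]
    if locus.strand == "-":
        tag = revcomp(tag)
    flank_settings = [(flank_up, flank_dn)]
    if (flank_dn, flank_up) != (flank_up, flank_dn):
        flank_settings.append((flank_dn, flank_up))
    out: list[HairpinCandidate] = []
    for up5, dn3 in flank_settings:
        # transcription-order flanks: upstream of the mature 5' end
        if locus.strand == "+":
            gstart, gend = locus.start - up5, locus.end + dn3
        else:
            gstart, gend = locus.start - dn3, locus.end + up5
        clipped = gstart < 0 or gend > len(chrom_seq)
        gstart, gend = max(0, gstart), min(len(chrom_seq), gend)
        window = chrom_seq[gstart:gend]
        if locus.strand == "+":
            precursor = window
            mstart = locus.start - gstart
        else:
            precursor = revcomp(window)
            mstart = gend - locus.end
        structure, mfe = folder(precursor)
        out.append(
            HairpinCandidate(
                tag_seq=tag,
                locus=GenomicLocus(locus.chrom, gstart, gend, locus.strand),
                precursor_seq=precursor,
                mature_span=(mstart, mstart + len(tag)),
                structure=structure,
                mfe=mfe,
                clipped=clipped,
            )
        )
    return out


def evaluate_hairpin(
    candidate: HairpinCandidate,
    mfe_max: float = -18.0,
    max_unpaired_mature: int = 4,
    max_bulge: int = 2,
) -> HairpinCandidate:
    """Score a folded candidate against the hairpin criteria (in place).

    Criteria: ``single_arm`` (no bracket-direction change inside the mature
    span), ``max_unpaired`` (<= ``max_unpaired_mature`` unpaired mature
    bases), ``bulge`` (no asymmetric bulge > ``max_bulge`` nt in the
    mature:star duplex), ``mfe`` (folding energy <= ``mfe_max``), and
    ``loop_overlap`` (mature span outside every terminal loop).
    """
    if not candidate.structure:
        raise ValueError("candidate has not been folded")
    table = pair_table(candidate.structure)
    ms, me = candidate.mature_span
    span = range(ms, me)
    paired = [i for i in span if table[i] != -1]
    directions = {candidate.structure[i] for i in paired}

    single_arm = len(directions) == 1
    unpaired_ok = (me - ms) - len(paired) <= max_unpaired_mature

    bulge_ok = True
    for i1, i2 in zip(paired, paired[1:]):
        gap_m = i2 - i1 - 1
        gap_s = abs(table[i1] - table[i2]) - 1
        if abs(gap_m - gap_s) > max_bulge:
            bulge_ok = False
            break

    mfe_ok = candidate.mfe <= mfe_max

    # terminal loops: interiors of pairs that enclose no other pair
    loop_ok = True
    for i, partner in enumerate(table):
        if partner > i and all(table[k] == -1 for k in range(i + 1, partner)):
            if ms < partner and i + 1 < me:  # mature intersects (i, partner)
                if any(ms <= k < me for k in range(i + 1, partner)):
                    loop_ok = False
                    break

    candidate.criteria = {
        "single_arm": single_arm and bool(paired),
        "max_unpaired": unpaired_ok,
        "bulge": bulge_ok,
        "mfe": mfe_ok,
        "loop_overlap": loop_ok,
    }
    candidate.passed = all(candidate.criteria.values())
    if paired:
        candidate.arm = "5p" if candidate.structure[paired[0]] == "(" else "3p"
        partners = [table[i] for i in paired]
        candidate.star_interval = (min(partners), max(partners) + 1)
    return candidate


def discover_novel(
    tags: list[TagRecord],
    genome: dict[str, str],
    repeat_annotation: list[tuple[str, int, int]],
    known_mirnas: list[str],
    other_ncrnas: list[str],
    config: DiscoveryConfig | None = None,
) -> tuple[pd.DataFrame, CascadeReport, list[HairpinCandidate]]:
    """Full novel-miRNA pipeline: filter cascade, excision, folding, scoring.

    A tag is called novel iff at least one excised window at one of its loci
    passes every hairpin criterion.  The returned table has one row per
    passing (tag, locus) pair: coordinates, mature and precursor sequence.
    """
    config = config or DiscoveryConfig()
    folder = get_folder(config.folder)
    survivors, report = filter_candidates(
        tags,
        genome,
        repeat_annotation,
        known_mirnas,
        other_ncrnas,
        min_reads=config.min_reads,
        max_genome_hits=config.max_genome_hits,
        known_max_mm=config.known_max_mm,
    )
    rows = []
    passing_candidates: list[HairpinCandidate] = []
    novel_tags: set[str] = set()
    for tag, hits in survivors:
        for locus in hits:
            for cand in excise_and_fold(
                genome, locus, config.flank_up, config.flank_dn, folder
            ):
                evaluate_hairpin(
                    cand,
                    mfe_max=config.mfe_max,
                    max_unpaired_mature=config.max_unpaired_mature,
                    max_bulge=config.max_bulge,
                )
                if cand.passed:
                    passing_candidates.append(cand)
                    novel_tags.add(dna(tag.seq))
                    rows.append(
                        {
                            "mature_seq": dna(tag.seq),
                            "chrom": locus.chrom,
                            "start": locus.start,
                            "end": locus.end,
                            "strand": locus.strand,
                            "arm": cand.arm,
                            "precursor_seq": cand.precursor_seq,
                            "mfe": cand.mfe,
                            "count_treatment": tag.count_treatment,
                            "count_control": tag.count_control,
                        }
                    )
                    break  # one passing window per locus suffices
    report.structure_pass = len(novel_tags)
    table = pd.DataFrame(
        rows,
        columns=[
            "mature_seq",
            "chrom",
            "start",
            "end",
            "strand",
            "arm",
            "precursor_seq",
            "mfe",
            "count_treatment",
            "count_control",
        ],
    )
    return table.sort_values(["chrom", "start"]).reset_index(drop=True), report, passing_candidates
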