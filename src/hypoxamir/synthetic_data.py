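"""Synthetic study generator with a ground-truth manifest.

Emulates the shape of a two-library small-RNA waterlogging experiment on a
desk-scale genome: i.i.d.-uniform background contigs with planted known
miRNA loci, designed hairpin precursors for novel miRNAs, tandem-repeat
blocks, other ncRNAs, pri-miRNA TSSs whose promoters carry planted PWM
consensus occurrences, sequencing libraries with configured fold changes,
transcripts with target sites of controlled rule compliance, and qPCR /
phenotype tables.  Every planted feature is recorded in a
:class:`TruthManifest` so each pipeline stage can be scored against truth.

All randomness flows from a single integer seed; identical (params, seed)
yield byte-identical output files.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .core_io import SequenceRecord, dna, revcomp
from .novel_mirna import GenomicLocus, evaluate_hairpin, excise_and_fold, min_hamming_window
from .target_scan import score_duplex

BASES = "ACGT"

# TruSeq-style small-RNA 3' adapter used by default in simulated reads
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

READ_LENGTH = 36

LINES = ("tolerant", "mid", "sensitive")
TIMES = ("1h", "2h", "4h")


class GenerationError(RuntimeError):
    """Raised when a feature cannot be placed without overlap."""


@dataclass
class GenomeParams:
    contig_lengths: tuple[int, ...] = (500_000, 500_000)
    n_known_mirnas: int = 20
    n_shared_signatures: int = 2  # known signatures present at two loci
    n_hairpins: int = 5
    n_repeats: int = 10
    n_ncrnas: int = 5
    n_pwms: int = 10
    n_planted_pwms: int = 5
    n_de_known: int = 8
    n_de_novel: int = 2
    fold_up: float = 3.0
    fold_down: float = 1.0 / 3.0
    mature_len: int = 21
    arm_len: int = 60
    pwm_width: int = 10
    repeat_unit: int = 30
    repeat_copies: int = 10


@dataclass
class LibraryParams:
    depth_treatment: int = 200_000
    depth_control: int = 200_000
    adapter: str = DEFAULT_ADAPTER
    background_frac: float = 0.25
    adapter_only_frac: float = 0.05
    short_frac: float = 0.02
    weight_sigma: float = 0.25  # lognormal spread of per-miRNA base abundance


@dataclass
class TruthManifest:
    """Everything planted, with coordinates valid in the generated data."""

    seed: int
    params: dict = field(default_factory=dict)
    contig_lengths: dict = field(default_factory=dict)
    known_mirnas: list = field(default_factory=list)
    planted_hairpins: list = field(default_factory=list)
    repeats: list = field(default_factory=list)
    ncrnas: list = field(default_factory=list)
    pwms: list = field(default_factory=list)
    pri_mirna_genes: list = field(default_factory=list)
    planted_motifs: list = field(default_factory=list)
    fold_map: dict = field(default_factory=dict)
    library: dict = field(default_factory=dict)
    target_sites: list = field(default_factory=list)
    transcript_tf_family: dict = field(default_factory=dict)
    anticorrelated_pairs: list = field(default_factory=list)
    qpcr_truth: dict = field(default_factory=dict)
    phenotype_truth: dict = field(default_factory=dict)

    def de_truth(self, fold_min: float = 1.5) -> set[str]:
        return {
            mid
            for mid, f in self.fold_map.items()
            if f >= fold_min or f <= 1.0 / fold_min
        }

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as handle:
            json.dump(asdict(self), handle, indent=1, sort_keys=True)
            handle.write("\n")

    @classmethod
    def load(cls, path: str | os.PathLike) -> "TruthManifest":
        with open(path) as handle:
            data = json.load(handle)
        return cls(**data)


@dataclass
class SyntheticGenome:
    genome: dict[str, str]
    tss_records: list  # core_io.TssRecord
    repeats: list[tuple[str, int, int]]
    known_catalog: list[tuple[str, str, list[str]]]
    ncrna_seqs: list[str]
    pwms: list  # core_io.PositionWeightMatrix
    manifest: TruthManifest


def _random_seq(rng: np.random.Generator, length: int, alphabet: str = BASES) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


class _Placer:
    """Non-overlapping interval allocation over the contigs."""

    def __init__(self, rng: np.random.Generator, contig_lengths: dict[str, int]):
        self.rng = rng
        self.lengths = contig_lengths
        self.occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in contig_lengths}

    def place(self, length: int, margin: int = 50, attempts: int = 1000) -> tuple[str, int]:
        chroms = sorted(self.lengths)
        for _ in range(attempts):
            chrom = chroms[int(self.rng.integers(len(chroms)))]
            limit = self.lengths[chrom] - length - margin
            if limit <= margin:
                continue
            start = int(self.rng.integers(margin, limit))
            lo, hi = start - margin, start + length + margin
            if all(hi <= s or e <= lo for s, e in self.occupied[chrom]):
                self.occupied[chrom].append((lo, hi))
                return chrom, start
        raise GenerationError(f"could not place a feature of length {length}")


def _design_hairpin(
    rng: np.random.Generator, params: GenomeParams
) -> tuple[str, str, int, str]:
    """Return (precursor, mature, mature_offset_in_precursor, arm)."""
    arm5 = _random_seq(rng, params.arm_len)
    loop = _random_seq(rng, 8, alphabet="AC")  # A/C-only loop cannot self-pair
    arm3 = revcomp(arm5)
    precursor = arm5 + loop + arm3
    if rng.random() < 0.5:
        offset = int(rng.integers(5, 16))  # within the 5' arm, clear of the loop
        arm = "5p"
    else:
        inner = int(rng.integers(5, 16))
        offset = len(arm5) + len(loop) + (params.arm_len - params.mature_len - inner)
        arm = "3p"
    mature = precursor[offset : offset + params.mature_len]
    return precursor, mature, offset, arm


def simulate_genome(
    params: GenomeParams | None = None, seed: int = 0
) -> SyntheticGenome:
    """Generate the genome, annotations, catalogs, PWMs and the manifest."""
    from .core_io import PositionWeightMatrix, TssRecord

    params = params or GenomeParams()
    rng = np.random.default_rng(seed)
    contigs = {
        f"chr{i + 1}": list(_random_seq(rng, L))
        for i, L in enumerate(params.contig_lengths)
    }
    lengths = {c: len(s) for c, s in contigs.items()}
    placer = _Placer(rng, lengths)
    manifest = TruthManifest(
        seed=seed,
        params={k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(params).items()},
        contig_lengths=dict(lengths),
    )

    def write_into(chrom: str, start: int, seq: str) -> None:
        contigs[chrom][start : start + len(seq)] = list(seq)

    all_matures: list[str] = []

    def mature_is_fresh(seq: str, min_dist: int = 3) -> bool:
        # a mature containing the adapter's seed bases would be truncated at
        # trimming, so such draws are rejected up front
        if DEFAULT_ADAPTER[:6] in seq:
            return False
        return all(min_hamming_window(seq, other) >= min_dist for other in all_matures)

    # --- known miRNA loci -------------------------------------------------
    known_catalog: list[tuple[str, str, list[str]]] = []
    for i in range(params.n_known_mirnas):
        for _ in range(1000):
            mature = _random_seq(rng, params.mature_len)
            if mature_is_fresh(mature):
                break
        else:
            raise GenerationError("could not draw a distinct known mature sequence")
        all_matures.append(mature)
        sig_id = f"miR{101 + i}"
        n_loci = 2 if i < params.n_shared_signatures else 1
        loci = []
        locus_ids = []
        for j in range(n_loci):
            chrom, start = placer.place(params.mature_len)
            write_into(chrom, start, mature)
            locus_ids.append(f"{sig_id}-{j + 1}")
            loci.append([chrom, start, start + params.mature_len, "+"])
        known_catalog.append((sig_id, mature, locus_ids))
        manifest.known_mirnas.append(
            {
                "signature_id": sig_id,
                "mature_seq": mature,
                "locus_ids": locus_ids,
                "loci": loci,
            }
        )

    # --- repeats (planted before hairpins so hairpins avoid them) ---------
    repeats: list[tuple[str, int, int]] = []
    for _ in range(params.n_repeats):
        unit = _random_seq(rng, params.repeat_unit)
        block = unit * params.repeat_copies
        chrom, start = placer.place(len(block))
        write_into(chrom, start, block)
        repeats.append((chrom, start, start + len(block)))
        manifest.repeats.append([chrom, start, start + len(block)])

    # --- other ncRNAs -----------------------------------------------------
    ncrna_seqs: list[str] = []
    for i in range(params.n_ncrnas):
        seq = _random_seq(rng, 80)
        chrom, start = placer.place(len(seq))
        write_into(chrom, start, seq)
        ncrna_seqs.append(seq)
        manifest.ncrnas.append({"id": f"ncRNA{i + 1}", "seq": seq})

    # --- novel hairpins ---------------------------------------------------
    genome_view = {c: "".join(s) for c, s in contigs.items()}
    for i in range(params.n_hairpins):
        name = f"miRn{i + 1}"
        for attempt in range(1000):
            precursor, mature, offset, arm = _design_hairpin(rng, params)
            if not mature_is_fresh(mature):
                continue
            chrom, start = placer.place(len(precursor), margin=200)
            write_into(chrom, start, precursor)
            genome_view[chrom] = "".join(contigs[chrom])
            mstart = start + offset
            locus = GenomicLocus(chrom, mstart, mstart + params.mature_len, "+")
            candidates = excise_and_fold(genome_view, locus)
            if any(evaluate_hairpin(c).passed for c in candidates):
                all_matures.append(mature)
                manifest.planted_hairpins.append(
                    {
                        "name": name,
                        "mature_seq": mature,
                        "chrom": chrom,
                        "start": mstart,
                        "end": mstart + params.mature_len,
                        "strand": "+",
                        "arm": arm,
                        "precursor_seq": precursor,
                        "precursor_start": start,
                    }
                )
                break
            # un-place by scrubbing with fresh background and retry
            write_into(chrom, start, _random_seq(rng, len(precursor)))
            genome_view[chrom] = "".join(contigs[chrom])
        else:
            raise GenerationError(f"could not place a compliant hairpin for {name}")

    # --- fold map (the study conditions) ----------------------------------
    fold_map: dict[str, float] = {}
    for i, (sig_id, _, _) in enumerate(known_catalog):
        if i < params.n_de_known:
            fold_map[sig_id] = params.fold_up if i % 2 == 0 else params.fold_down
        else:
            fold_map[sig_id] = 1.0
    for i, hp in enumerate(manifest.planted_hairpins):
        fold_map[hp["name"]] = params.fold_down if i < params.n_de_novel else 1.0
    manifest.fold_map = fold_map

    # --- PWMs -------------------------------------------------------------
    pwms = []
    consensi: list[str] = []
    families = ["MYB", "bZIP", "HMG", "AP2/ERF", "HD-Zip", "DOF", "MADS", "bHLH", "TCP", "WRKY"]
    for i in range(params.n_pwms):
        for _ in range(1000):
            consensus = _random_seq(rng, params.pwm_width)
            if all(min_hamming_window(consensus, c) >= 3 for c in consensi):
                break
        else:
            raise GenerationError("could not draw distinct PWM consensi")
        consensi.append(consensus)
        matrix = np.full((4, params.pwm_width), 5.0)
        for col, base in enumerate(consensus):
            matrix[BASES.index(base), col] = 85.0
        planted = i < params.n_planted_pwms
        family = families[i % len(families)]
        pwm = PositionWeightMatrix(
            motif_id=f"MA{i + 1:04d}", tf_name=f"TF{i + 1}", matrix=matrix, tf_family=family
        )
        pwms.append(pwm)
        manifest.pwms.append(
            {
                "motif_id": pwm.motif_id,
                "tf_family": family,
                "consensus": consensus,
                "planted": planted,
            }
        )

    # --- pri-miRNA genes: one per DE known signature ----------------------
    de_known = [sid for sid, _, _ in known_catalog if manifest.fold_map[sid] != 1.0]
    tss_records = []
    promoter_span = 1600
    gene_regions: dict[str, tuple[str, int, str]] = {}
    for gene_id in de_known:
        chrom, start = placer.place(promoter_span + 200, margin=100)
        strand = "+" if rng.random() < 0.5 else "-"
        # TSS such that [-1000, +500] sits inside the reserved region
        tss = start + 1050 if strand == "+" else start + 550
        tss_records.append(TssRecord(chrom, tss, strand, gene_id))
        gene_regions[gene_id] = (chrom, tss, strand)
        manifest.pri_mirna_genes.append(
            {"gene_id": gene_id, "chrom": chrom, "tss_pos": tss, "strand": strand}
        )

    # --- plant motif occurrences into designated promoters ----------------
    n_genes_each = max(1, len(de_known) // 2)
    promoter_used: dict[str, list[tuple[int, int]]] = {g: [] for g in de_known}
    for pwm, rec in zip(pwms, manifest.pwms):
        if not rec["planted"]:
            continue
        chosen = sorted(
            rng.choice(len(de_known), size=min(n_genes_each, len(de_known)), replace=False)
        )
        for gi in chosen:
            gene_id = de_known[int(gi)]
            chrom, tss, strand = gene_regions[gene_id]
            lo = tss - 1000 if strand == "+" else tss - 500
            # three non-overlapping slots inside the 1500-nt promoter window
            slots = [lo + 100, lo + 600, lo + 1100]
            offsets = []
            for slot in slots:
                for _ in range(1000):
                    pos = slot + int(rng.integers(0, 300))
                    span = (pos, pos + params.pwm_width)
                    if all(span[1] <= s or e <= span[0] for s, e in promoter_used[gene_id]):
                        promoter_used[gene_id].append(span)
                        break
                else:
                    raise GenerationError("could not place a motif occurrence")
                write_into(chrom, pos, rec["consensus"])
                offsets.append(pos)
            manifest.planted_motifs.append(
                {
                    "motif_id": pwm.motif_id,
                    "tf_family": rec["tf_family"],
                    "gene_id": gene_id,
                    "offsets": offsets,
                }
            )

    genome = {c: "".join(s) for c, s in contigs.items()}
    return SyntheticGenome(
        genome=genome,
        tss_records=tss_records,
        repeats=repeats,
        known_catalog=known_catalog,
        ncrna_seqs=ncrna_seqs,
        pwms=pwms,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# Libraries

def simulate_libraries(
    manifest: TruthManifest,
    library_params: LibraryParams | None = None,
    fold_map: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Draw the treatment and control read sets.

    Per-miRNA counts are multinomial over expression weights honoring the
    fold map; configurable fractions of adapter-only, too-short and random
    background reads are mixed in.  Sampled counts land in the manifest.
    """
    lp = library_params or LibraryParams()
    fold_map = fold_map if fold_map is not None else manifest.fold_map
    rng = np.random.default_rng(seed)

    matures = {m["signature_id"]: m["mature_seq"] for m in manifest.known_mirnas}
    matures.update({h["name"]: h["mature_seq"] for h in manifest.planted_hairpins})
    unknown = set(fold_map) - set(matures)
    if unknown:
        raise ValueError(f"fold_map references unknown miRNAs: {sorted(unknown)}")
    probe = dna(lp.adapter)[:6]
    colliding = sorted(mid for mid, seq in matures.items() if probe in dna(seq))
    if colliding:
        raise GenerationError(
            f"adapter seed {probe} occurs inside mature sequence(s) {colliding}; "
            "their reads would be truncated at trimming — use another adapter"
        )

    ids = sorted(matures)
    folds = np.array([fold_map.get(mid, 1.0) for mid in ids])
    # the background pool absorbs the fold-induced miRNA mass change so that
    # the usable (filtered) read total is identical in both libraries and the
    # expected RPM ratio of each miRNA equals its configured fold; weight
    # draws whose mass shift exceeds the pool are redrawn
    mirna_frac = 1.0 - lp.background_frac - lp.adapter_only_frac - lp.short_frac
    usable_frac = 1.0 - lp.adapter_only_frac - lp.short_frac
    for _ in range(1000):
        base_weights = rng.lognormal(mean=0.0, sigma=lp.weight_sigma, size=len(ids))
        mass_ratio = float((base_weights * folds).sum() / base_weights.sum())
        if mirna_frac * mass_ratio <= usable_frac:
            break
    else:
        raise GenerationError(
            "fold map shifts more miRNA mass than the background pool can absorb"
        )
    counts_record: dict[str, dict[str, int]] = {"treatment": {}, "control": {}}
    libraries: list[list[SequenceRecord]] = []
    for lib_name, depth in (
        ("treatment", lp.depth_treatment),
        ("control", lp.depth_control),
    ):
        records: list[SequenceRecord] = []
        if depth <= 0:
            libraries.append(records)
            continue
        n_adapter = int(round(depth * lp.adapter_only_frac))
        n_short = int(round(depth * lp.short_frac))
        usable = depth - n_adapter - n_short
        base_mirna = int(
            round(depth * (1.0 - lp.background_frac - lp.adapter_only_frac - lp.short_frac))
        )
        if lib_name == "treatment":
            n_mirna = int(round(base_mirna * mass_ratio))
            weights = base_weights * folds
        else:
            n_mirna = base_mirna
            weights = base_weights
        n_bg = usable - n_mirna
        if n_bg < 0:
            raise GenerationError(
                "fold map shifts more miRNA mass than the background pool can absorb"
            )
        counts = rng.multinomial(n_mirna, weights / weights.sum())
        idx = 0
        for mid, count in zip(ids, counts):
            counts_record[lib_name][mid] = int(count)
            insert = matures[mid]
            read = (dna(insert) + dna(lp.adapter))[:READ_LENGTH]
            for _ in range(count):
                records.append(SequenceRecord(f"{lib_name}_{idx}", read, [40] * len(read)))
                idx += 1
        for _ in range(n_bg):
            insert = _random_seq(rng, int(rng.integers(18, 27)))
            read = (insert + dna(lp.adapter))[:READ_LENGTH]
            records.append(SequenceRecord(f"{lib_name}_{idx}", read, [40] * len(read)))
            idx += 1
        for _ in range(n_short):
            insert = _random_seq(rng, int(rng.integers(10, 18)))
            read = (insert + dna(lp.adapter))[:READ_LENGTH]
            records.append(SequenceRecord(f"{lib_name}_{idx}", read, [40] * len(read)))
            idx += 1
        for _ in range(n_adapter):
            read = (dna(lp.adapter) * 2)[:READ_LENGTH]
            records.append(SequenceRecord(f"{lib_name}_{idx}", read, [40] * len(read)))
            idx += 1
        libraries.append(records)

    manifest.library = {
        "depth_treatment": lp.depth_treatment,
        "depth_control": lp.depth_control,
        "adapter": lp.adapter,
        "background_frac": lp.background_frac,
        "adapter_only_frac": lp.adapter_only_frac,
        "short_frac": lp.short_frac,
        "counts": counts_record,
    }
    return libraries[0], libraries[1]


# ---------------------------------------------------------------------------
# Transcripts with target sites

# per class: 1-based miRNA positions to mutate (None marks the >6-distance decoy)
SITE_PROFILES: dict[str, list[int]] = {
    "all_pass": [],
    "violate_seed": [3, 8],
    "violate_10_11": [10],
    "violate_consec": [13, 14, 15],
    "violate_total": [1, 13, 15, 17, 19],
    "distance7": [1, 3, 5, 13, 15, 17, 19],
}

_EXPECTED_FALSE = {
    "violate_seed": "r_seed_le1",
    "violate_10_11": "r_no_mm_10_11",
    "violate_consec": "r_consec_le2_after12",
    "violate_total": "r_total_le4",
}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_WOBBLE_PARTNER = {"G": "T", "T": "G"}


def make_site(mirna_seq: str, profile: str, rng: np.random.Generator | None = None) -> str:
    """Construct a target site of the requested rule-compliance class.

    Starts from the perfect reverse complement and rewrites the site base
    facing each listed miRNA position to a true mismatch (neither the
    Watson-Crick complement nor the wobble partner).
    """
    if profile not in SITE_PROFILES:
        raise ValueError(f"unknown site profile {profile!r}")
    m = dna(mirna_seq)
    L = len(m)
    positions = SITE_PROFILES[profile]
    if any(p > L for p in positions):
        raise ValueError(f"profile {profile} needs a miRNA longer than {L} nt")
    site = list(revcomp(m))
    rng = rng or np.random.default_rng(0)
    for pos in positions:
        mb = m[pos - 1]
        banned = {_COMPLEMENT[mb], _WOBBLE_PARTNER.get(mb, "")}
        choices = [b for b in BASES if b not in banned]
        site[L - pos] = choices[int(rng.integers(len(choices)))]
    out = "".join(site)
    # verify the constructed class against the scorer
    aln = score_duplex(m, out)
    if profile == "all_pass":
        if not aln.accepted:
            raise GenerationError("all_pass site failed verification")
    elif profile == "distance7":
        mm = sum(1 for a, b in zip(out, revcomp(m)) if a != b)
        if mm <= 6:
            raise GenerationError("distance7 site is within candidate range")
    else:
        want_false = _EXPECTED_FALSE[profile]
        ok = all(v != (k == want_false) for k, v in aln.rule_verdicts.items())
        if not ok:
            raise GenerationError(f"{profile} site verification failed: {aln.rule_verdicts}")
    return out


def simulate_transcript_targets(
    manifest: TruthManifest,
    n_transcripts: int = 100,
    transcript_len: int = 500,
    site_profiles: tuple[str, ...] = tuple(SITE_PROFILES),
    mirna_ids: list[str] | None = None,
    seed: int = 0,
) -> dict[str, str]:
    """Random transcripts with one embedded site per (DE miRNA, profile).

    Each DE miRNA gets one site of every requested class, each in its own
    transcript; all-pass transcripts are assigned a TF family (read back by
    the network stage), and the feedback-loop pairing with a promoter motif
    family is honored when one exists.  Sites are recorded in the manifest.
    """
    rng = np.random.default_rng(seed)
    matures = {m["signature_id"]: m["mature_seq"] for m in manifest.known_mirnas}
    matures.update({h["name"]: h["mature_seq"] for h in manifest.planted_hairpins})
    if mirna_ids is None:
        mirna_ids = sorted(manifest.de_truth())
    target_families = ["ARF", "GRF", "NAC", "SBP", "CBF", "TCP", "Zinc-Finger", "cupredoxin"]

    transcripts: dict[str, str] = {}
    t_idx = 0
    # map gene -> families planted in its promoter (for a feedback loop)
    promoter_families = {}
    for rec in manifest.planted_motifs:
        promoter_families.setdefault(rec["gene_id"], []).append(rec["tf_family"])
    feedback_assigned = False
    for mi, mirna_id in enumerate(mirna_ids):
        mature = matures[mirna_id]
        for profile in site_profiles:
            tid = f"tx{t_idx + 1:04d}"
            t_idx += 1
            seq = list(_random_seq(rng, transcript_len))
            offset = int(rng.integers(50, transcript_len - len(mature) - 50))
            site = make_site(mature, profile, rng)
            seq[offset : offset + len(site)] = list(site)
            transcripts[tid] = "".join(seq)
            manifest.target_sites.append(
                {
                    "mirna_id": mirna_id,
                    "transcript_id": tid,
                    "offset": offset,
                    "profile": profile,
                }
            )
            if profile == "all_pass":
                if not feedback_assigned and promoter_families.get(mirna_id):
                    family = promoter_families[mirna_id][0]
                    feedback_assigned = True
                else:
                    family = target_families[mi % len(target_families)]
                manifest.transcript_tf_family[tid] = family
                manifest.anticorrelated_pairs.append([mirna_id, tid])
    # plain background transcripts up to the requested count
    while t_idx < n_transcripts:
        tid = f"tx{t_idx + 1:04d}"
        t_idx += 1
        transcripts[tid] = _random_seq(rng, transcript_len)
    return transcripts


# ---------------------------------------------------------------------------
# Expression tables

def generate_dataset(
    outdir: str | os.PathLike,
    params: GenomeParams | None = None,
    library_params: LibraryParams | None = None,
    n_transcripts: int = 100,
    seed: int = 0,
) -> TruthManifest:
    """Generate and write a complete dataset (all formats the pipeline reads).

    Files: genome.fasta, tss.tsv, repeats.tsv, known_catalog.tsv,
    known_mature.fasta, ncrna.fasta, pwms.pfm, pwm_families.tsv,
    treatment.fastq, control.fastq, transcripts.fasta, ct_table.tsv,
    trait_table.tsv, truth_manifest.json.
    """
    from . import core_io

    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    sim = simulate_genome(params, seed=seed)
    manifest = sim.manifest
    reads_t, reads_c = simulate_libraries(manifest, library_params, seed=seed + 1)
    transcripts = simulate_transcript_targets(
        manifest, n_transcripts=n_transcripts, seed=seed + 2
    )
    ct_table, trait_table = simulate_expression_tables(manifest, seed=seed + 4)

    join = lambda name: os.path.join(outdir, name)
    core_io.write_fasta(
        [SequenceRecord(c, s) for c, s in sim.genome.items()], join("genome.fasta")
    )
    core_io.write_tss_table(sim.tss_records, join("tss.tsv"))
    core_io.write_tsv(
        pd.DataFrame(sim.repeats, columns=["chrom", "start", "end"]), join("repeats.tsv")
    )
    core_io.write_tsv(
        pd.DataFrame(
            [
                {"signature_id": sid, "mature_seq": seq, "locus_ids": ",".join(loci)}
                for sid, seq, loci in sim.known_catalog
            ]
        ),
        join("known_catalog.tsv"),
    )
    core_io.write_fasta(
        [SequenceRecord(sid, seq) for sid, seq, _ in sim.known_catalog],
        join("known_mature.fasta"),
    )
    core_io.write_fasta(
        [SequenceRecord(f"ncRNA{i + 1}", s) for i, s in enumerate(sim.ncrna_seqs)],
        join("ncrna.fasta"),
    )
    core_io.write_pwms(sim.pwms, join("pwms.pfm"))
    core_io.write_tsv(
        pd.DataFrame(
            [{"motif_id": p.motif_id, "tf_family": p.tf_family} for p in sim.pwms]
        ),
        join("pwm_families.tsv"),
    )
    core_io.write_fastq(reads_t, join("treatment.fastq"))
    core_io.write_fastq(reads_c, join("control.fastq"))
    core_io.write_fasta(
        [SequenceRecord(tid, seq) for tid, seq in transcripts.items()],
        join("transcripts.fasta"),
    )
    core_io.write_tsv(ct_table, join("ct_table.tsv"))
    core_io.write_tsv(trait_table, join("trait_table.tsv"))
    manifest.save(join("truth_manifest.json"))
    return manifest


def _mirna_truth_profile(fold: float) -> dict[str, list[float]]:
    """Line x time relative-expression truth for a miRNA with 4-h fold ``fold``.

    Induced miRNAs ramp up early and strongly in the tolerant line, weakly in
    the mid-tolerant line, and are repressed in the sensitive line (the
    pattern is mirrored for repressed miRNAs)."""
    if fold >= 1.0:
        return {
            "tolerant": [1.5, 2.2, fold],
            "mid": [1.2, 1.5, max(1.1, fold / 2)],
            "sensitive": [0.8, 0.7, 0.6],
        }
    return {
        "tolerant": [0.7, 0.5, fold],
        "mid": [0.8, 0.7, min(0.9, fold * 2)],
        "sensitive": [1.2, 1.4, 1.6],
    }


def simulate_expression_tables(
    manifest: TruthManifest,
    qpcr_noise_sd: float = 0.0,
    trait_noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """qPCR Ct table and phenotype trait table from manifest truth.

    Ct = ct_ref + offset - log2(rel_expr) + Normal(0, sd) per replicate;
    targets designated anti-correlated get the reciprocal of their miRNA's
    relative-expression profile.  Trait replicates are control mean x line
    multiplier x lognormal noise, with total dry weight = leaf + root.
    """
    rng = np.random.default_rng(seed)
    ct_ref, ct_offset = 15.0, 25.0

    qpcr_truth: dict[str, dict[str, dict[str, float]]] = {}
    for mirna_id in sorted(manifest.de_truth()):
        prof = _mirna_truth_profile(manifest.fold_map[mirna_id])
        qpcr_truth[mirna_id] = {
            line: dict(zip(TIMES, vals)) for line, vals in prof.items()
        }
    for mirna_id, tid in manifest.anticorrelated_pairs:
        qpcr_truth[tid] = {
            line: {t: 1.0 / v for t, v in times.items()}
            for line, times in qpcr_truth[mirna_id].items()
        }
    for entity, per_line in qpcr_truth.items():
        for line, times in per_line.items():
            for t, rel in times.items():
                if rel <= 0:
                    raise ValueError(f"non-positive truth rel_expr for {entity}")
    manifest.qpcr_truth = qpcr_truth

    ct_rows = []
    for entity in sorted(qpcr_truth) + ["18S"]:
        for line in LINES:
            for time in TIMES:
                for condition in ("treated", "control"):
                    for rep in range(1, n_replicates + 1):
                        if entity == "18S":
                            ct = ct_ref
                        elif condition == "control":
                            ct = ct_offset
                        else:
                            ct = ct_offset - math.log2(qpcr_truth[entity][line][time])
                        ct += float(rng.normal(0.0, qpcr_noise_sd)) if qpcr_noise_sd else 0.0
                        ct_rows.append(
                            {
                                "entity": entity,
                                "line": line,
                                "time": time,
                                "condition": condition,
                                "replicate": rep,
                                "ct": round(ct, 6),
                            }
                        )
    ct_table = pd.DataFrame(ct_rows)

    multipliers = {"tolerant": 0.8, "mid": 0.6, "sensitive": 0.4}
    manifest.phenotype_truth = dict(multipliers)
    control_means = {"RL": 12.0, "LL": 20.0, "RW": 0.8, "LW": 1.6}
    trait_rows = []
    for line in LINES:
        for condition in ("treated", "control"):
            factor = multipliers[line] if condition == "treated" else 1.0
            for rep in range(1, n_replicates + 1):
                noise = {
                    t: float(rng.lognormal(0.0, trait_noise_sd)) if trait_noise_sd else 1.0
                    for t in control_means
                }
                values = {t: control_means[t] * factor * noise[t] for t in control_means}
                values["TW"] = values["LW"] + values["RW"]
                for trait, value in values.items():
                    trait_rows.append(
                        {
                            "line": line,
                            "condition": condition,
                            "trait": trait,
                            "replicate": rep,
                            "value": round(value, 6),
                        }
                    )
    trait_table = pd.DataFrame(trait_rows)
    return ct_table, trait_table
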