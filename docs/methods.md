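# Methods

This note records the models, parameter choices and numerical conventions
behind `hypoxamir`, and what the synthetic-data validation does and does not
demonstrate.

## Coordinates, alphabets, tables

All internal coordinates are 0-based half-open. Sequences may contain
`A C G T U N`; `U` is normalized to `T` for matching and restored only in
the sense that inputs are never rewritten. Result tables are TSV with a
single `#`-prefixed header, UTF-8, `.` decimal — chosen so outputs diff
bit-exactly between runs, which the determinism checks rely on.

## Small-RNA processing and differential expression

Adapter trimming removes everything from the leftmost exact occurrence of
the adapter's first `min_overlap` bases (default 6). An occurrence at read
position 0 marks an adapter-only read; no occurrence marks the read
untrimmed. Mismatch-tolerant adapter alignment is out of scope.

Tag collapsing keeps inserts of 18–26 nt, discards (and counts) inserts
containing `N`, and deduplicates by exact sequence with per-library counts.
**RPM uses the library's filtered (usable) reads as denominator**, not the
raw total — the usable total is the quantity the per-tag table conserves
(Σ RPM = 10⁶), and the choice is stated explicitly because either reading
is defensible.

Known-signature quantification requires perfect, T/U-insensitive sequence
identity between a tag and a catalog mature sequence. Catalog entries that
share a mature sequence are merged into a single signature listing all
loci (a many-loci-to-one-signature mapping).

The DE test is the Pearson χ² on the 2×2 table
`{count_t, total_t − count_t; count_c, total_c − count_c}` with df = 1 and
**no continuity correction** (a Yates-corrected variant is available as a
flag). Expected cells below 1 flag the result without suppressing it.
Fold change is the treatment/control RPM ratio with a 0.5-read pseudocount
added to both libraries **for the fold computation only**, so that zero
counts stay finite while counts and the test itself are untouched. The
filter passes a signature iff P < 0.01, fold ≥ 1.5 or ≤ 1/1.5, and
max(RPM_t, RPM_c) > 50; the `>50 RPM` floor applies to the more abundant
library (the permissive reading; configurable). The empirical type-I error
of the test at α = 0.01 over 10,000 null Poisson signatures is checked to
fall in the exact binomial 99% interval [0.0075, 0.0127].

## Folding and hairpin evaluation

The built-in folder is a maximum base-pairing dynamic program (minimum
hairpin loop 3, G:U allowed) with lonely-pair removal and a stacking-sum
energy: each stacked pair of pairs contributes the mean of the two pair
strengths (GC 3.3, AU 2.1, GU 1.4 kcal/mol), negated. This is deterministic
and dependency-free; it agrees with a thermodynamic folder on designed
perfect hairpins (tested against ViennaRNA as an independent oracle), but
its energies are a coarse proxy, which is why the −18 kcal/mol threshold
is a config key rather than a physical claim. A thermodynamic backend can
be swapped in behind the same `seq -> (structure, energy)` contract.

Candidate precursors are excised with asymmetric flank pairs (20, 160) and
(160, 20) around the mature tag — plant precursors are long and the mature
can sit on either arm — and evaluated against: (a) no bracket-direction
change inside the mature span; (b) ≤ 4 unpaired mature bases; (c) no
asymmetric bulge > 2 nt between consecutive paired mature positions;
(d) energy ≤ −18 kcal/mol; (e) no overlap with any terminal loop. These
thresholds follow common plant-miRNA screening conventions; none is fixed
by an external source, so all are configurable. Dinucleotide-shuffled
precursor controls pass the full criterion set at ≤ 5% (tested over 200
seeded shuffles).

The candidate cascade attributes each removal to its first failing stage:
abundance (< 100 combined reads), genome mapping (no exact hit on either
strand), repetitiveness (> 20 genomic hits or overlap with the repeat
annotation), then similarity to known sequences (Hamming ≤ 2 at equal
length against every window of each known miRNA/ncRNA). Genome mapping is
exact-match only; the 20-hit ceiling stands in for an unreported
repetitiveness threshold and is configurable.

## Target rules

Sites are ungapped. Position *i* counts 1-based from the miRNA 5′ end;
site base `L − i` (0-based) faces it. Watson–Crick pairs score 0; **G:U
wobbles score 1 by default** because the scoring text underlying this rule
set draws no wobble exception — the Schwab-style 0.5 is available via
`wobble_score`, with rules then applied to summed scores. Acceptance
requires: Σ scores over positions 2–12 ≤ 1; positions 10 and 11 clean; no
run of ≥ 3 scored positions wholly after 12; total ≤ 4. Candidate search is
a sliding-window Hamming scan (≤ 6) of the reverse-complemented miRNA;
an exhaustive window-scoring oracle in the tests guards the equivalence.

Cleavage-clone classification centers a 100-nt half-open window on the site
midpoint and takes the canonical slicing coordinate as the transcript base
opposite miRNA position 10 (`site_start + L − 10`), i.e. the 5′ end of the
downstream cleavage fragment.

## Promoters and motif enrichment

Promoters span [−1000, +500] around the pri-miRNA TSS, strand-oriented and
clipped (and flagged) at contig edges. PWMs are normalized with a 0.1
pseudocount per cell; scanning is double-stranded log₂-odds against
genome-estimated base frequencies, and a hit requires ≥ 0.8 of the PWM's
maximum attainable score — a width-invariant threshold policy adopted
because the original scanner's is unreported. `N` contributes 0 bits.

Over-representation is an upper-tail binomial test of the total foreground
hit count at a per-position background rate estimated per motif from
length-matched random genomic windows; windows overlapping the foreground
promoters are excluded from the background, since leaving planted (or real)
promoter occurrences in the "random" set inflates the background rate.
Zero background hits floor the rate at 0.5 / (background positions) with a
flag. Bonferroni multiplies by the number of motifs tested; selection
additionally requires ≥ 3 occurrences in at least one promoter
(`min_promoters_ge3`, default 1 — the "three or more occurrences per
promoter" phrasing does not say in how many promoters it must hold).

## Expression and network

Relative expression is 2^−ΔΔCt with replicate Cts averaged before
differencing; efficiency-corrected variants are out of scope. Clustering is
agglomerative (Euclidean, average linkage) cut at k = 4 by default, with
scipy's deterministic ordering. A target is called negatively correlated
with its miRNA iff Pearson r < 0 on log₂ ratios over the time course in
**every** line; with 3 time points per line no significance test is
meaningful, so the call is a sign condition, and zero-variance lines make
the call false with a flag.

Network nodes are miRNA genes and TF families (targets rolled up to
families); edge kinds enforce bipartite typing at build time. A miRNA
family is the maximal `miR<number>` prefix after stripping a species
prefix (`miR159h → miR159`, `miRn6 → miRn6`). Feedback loops are directed
2-cycles at family level. The summary reports whatever the inputs imply —
node totals are never adjusted toward an externally printed figure.

## Synthetic data: what it emulates, and what it does not

The generator plants every feature class the pipeline detects: known
mature-miRNA loci (some shared across two loci to exercise signature
merging), designed perfect-complement hairpins with an A/C-only loop
(verified at generation time through the same excision/evaluation path the
discovery stage uses), tandem-repeat blocks, ncRNAs, pri-miRNA TSSs with
PWM consensus occurrences planted ≥ 3 times in designated promoters, target
sites of six rule-compliance classes (each verified against the scorer at
generation), reciprocal-trend qPCR truth for designated miRNA–target pairs,
and per-line trait multipliers (tolerant 0.8, mid 0.6, sensitive 0.4).

Mature sequences are drawn pairwise-distinct (Hamming ≥ 3) and are rejected
if they contain the adapter's first 6 bases — such a mature would be
truncated at trimming, a confusion real library designs also avoid; the
library simulator additionally refuses a custom adapter whose seed occurs
inside any planted mature.

Library counts are multinomial over lognormal base abundances
(σ = 0.25) times the configured fold changes; the background-read pool
(25% of depth) absorbs the fold-induced miRNA mass change so the usable
read total is identical in both libraries and the expected RPM ratio of
each miRNA equals its configured fold. Weight draws whose mass shift
exceeds the pool are redrawn. Adapter-only (5%) and short-insert (2%)
reads exercise the trimming statistics. DE miRNAs change 3-fold, which at
the desk-scale depth of 2 × 10⁵ reads puts true changes far outside and
null signatures far inside the filter thresholds — that is what makes the
precision = recall = 1 closure meaningful rather than lucky.

Background sequence is i.i.d.-uniform, reads carry no sequencing errors or
quality structure, and transcripts are random — so the closure results
demonstrate the correctness of the decision logic, not robustness to
genomic composition bias, error-containing reads, or paralogous target
families. The desk preset (2 × 500 kb contigs, 20 known miRNAs, 5 hairpins,
100 transcripts, 10 PWMs, 2 × 10⁵ reads per library) runs the whole
pipeline in well under a minute; these sizes were chosen as the smallest at
which every stage still has non-trivial multiplicity.

All randomness flows from one integer seed through `numpy`'s Generator;
identical parameters and seed give byte-identical output files, which the
determinism tests compare file-by-file.

## Known limitations

* The energy model of the built-in folder ranks hairpins sensibly but its
  kcal/mol scale is approximate; borderline precursors should be re-checked
  with a thermodynamic backend.
* Adapter trimming is exact-prefix; reads with sequencing errors inside the
  first 6 adapter bases go untrimmed.
* The binomial enrichment model treats scan positions as independent;
  overlapping-window correlation makes the test slightly conservative for
  self-overlapping motifs.
* Duplexes are ungapped throughout; bulged target sites are invisible to
  the scanner by design.
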