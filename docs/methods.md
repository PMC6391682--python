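# Methods

This note documents the models, conventions and numerical choices behind
`sirnaq`, and what the synthetic-data generator does and does not emulate.

## Scope and data model

The pipeline analyzes small-RNA sequencing libraries from cells expressing
long dsRNA hairpins (inverted repeats on transfected plasmids). Its unit of
analysis is the perfect-match placement: downstream statistics use only
reads that match the reference (genome contigs plus appended plasmid
contigs) exactly, because siRNA quantification, cluster calling and phasing
are all defined on unambiguous sequence identity. Externally mapped data can
be ingested from SAM/BAM, filtered to the same contract (no mismatches
beyond the configured limit, no indels, no clipping), with multimapping
multiplicity recomputed from the retained records. Coordinates are 0-based
half-open internally; SAM and GFF3 converters handle the 1-based
conventions at the boundaries.

## Trimming

NEXTflex-style reads are `4N + insert + 4N + adapter`. Round one removes the
3' adapter by a deterministic leftmost-prefix rule: at read position *i* the
adapter prefix of length `L = min(len(adapter), len(read) − i)` is compared;
a match requires either `L ≥ 19` with at most 1 mismatch, or an exact match
with `8 ≤ L < 19`. This emulates k-mer adapter trimming (k = 19, one
substitution tolerated, exact short end matches) with a rule that a
brute-force scan can verify. Reverse-complement adapter search is
deliberately omitted: 3' adapter read-through in small-RNA data is
sense-strand. Round two removes 4 bases from each end and discards inserts
shorter than 15 nt; stage ordering (adapter first, forced ends second) is
what makes the forced trim act on the insert boundaries. Reads without a
detectable adapter are kept by default (`require_adapter=False`); chimeric
survivors fail perfect-match mapping downstream.

## Alignment and fractional counting

The internal aligner is exact-match only and reports *every* occurrence of a
read on both strands of all contigs, using a 15-mer seed index with full
verification (15 nt is the minimum retained insert). `n_hits` is the total
placement count; each placement carries weight `1/n_hits`, so the sum of
weights over all placements of a library equals its mapped-read count
exactly. No cap is applied to the number of placements.

The RPM denominator is the number of distinct reads with at least one
perfect-match placement on genome + plasmids; plasmid-only mappers count.
Under this policy the whole library is exactly 10⁶ RPM — a property the test
suite asserts. An `all-reads` style denominator (every sequenced read) can be
emulated by overriding `SmallRnaLibrary.denominator`; the mapped-read
definition is the default because it is the one stated precisely for the
density profiles. Duplicate sequences under distinct read ids each count:
reads, not unique sequences, are the counting unit.

## Cluster discovery

Steps, in order: weight (1/n) → collapse transitively overlapping 21–23-nt
placements (strand-agnostic; abutting half-open intervals do not overlap) →
discard regions `< 3 RPM` → join clusters whose gap
(`next.start − prev.end`) is `≤ 50 bp`, re-deriving RPM. Filtering before
joining means a sub-threshold region can never bridge two retained clusters;
the 50/51-bp and 2/3-RPM boundaries are covered by exact tests so the
conventions are explicit.

Replicate handling: a region is kept iff every replicate of the group has at
least one overlapping cluster; kept coordinates are the union of the
overlapping replicate clusters, mirroring the cross-group union-merge rule.
Cross-group merging takes the transitive union of overlapping clusters and
records an RPM for every sample (zero where absent); when libraries are
available the per-sample RPM over the merged region is recomputed from the
length-filtered reads rather than summed from pre-merge clusters.

Annotation uses source-defined categories (miRNA from GFF3, repeats from
RepeatMasker-style BED, exons from GFF3, misc RNA) and resolves positional
conflicts by the fixed hierarchy miRNA > transposable elements > mRNA >
misc. RNA, with "other" for unannotated regions. Overlap is ≥ 1 bp and
strand-agnostic (repeat strand is unreliable for read-level sense calls).
Cluster summaries are the median log₁₀ RPM across samples; zero RPMs are
floored at a pseudovalue (default 0.1 RPM) so clusters absent from one
sample plot at an axis floor rather than −∞. With the floor disabled,
all-zero clusters are reported as missing.

Repeat-class aggregation assigns each 21–23-nt placement's 1/n weight to the
class of the repeat(s) it overlaps — one weight per distinct class per
placement — so a multimapper spread over two classes contributes to both. A
per-class two-sided Welch t-test compares replicate groups (the choice of
test is recorded in output metadata; comparisons with zero variance in both
groups and equal means report p = 1). An `exclusive` switch drops reads that
also overlap miRNA or exon annotation.

## Hairpin profiling and phasing

A `HairpinSpec` names the plasmid contig, the hairpin interval, the 5' arm,
loop and 3' arm, and which strand is antisense to the targeted reporter.
Whether "hairpin start" means the transcription start or the first
base-paired stem nucleotide is a property of the construct, so the spec file
makes it explicit per hairpin.

*Arm density*: per-position CPM of length-filtered reads fully inside the
hairpin, split by arm. Arm membership follows the read's biological 5' end
(a single unambiguous rule for boundary-spanning reads; 5' ends in the loop
are assigned to neither arm). Coverage mode gives every covered base the
read's weight; a 5'-end-count mode is available. 3'-arm values carry
negative sign for plotting below the axis.

*Phasing*: the first hairpin nucleotide defines register 1; a read's scaled
start is its biological 5'-end position (1-based from the hairpin start) and
its register is `((scaled_start − 1) mod 22) + 1`. Both strands are pooled,
each read entering through its own 5' end — Dicer phasing is defined by 5'
ends — with per-strand breakdowns available. The period defaults to 22 and
is configurable for other step sizes. Proportions are fractional-weight
shares and sum to 1 whenever any hairpin read exists; empty profiles are
flagged (`n_reads = 0`, NaN proportions) rather than zero-filled.

## Synthetic data generator

The generator emulates the statistical structure of plasmid-transfection
small-RNA libraries with exact per-read ground truth:

- **miRNA-like loci** (default 30): fixed 5' ends, 21/22/23-nt lengths in a
  0.2/0.6/0.2 mix, relative abundances drawn once per reference from a
  log-normal (μ = 4, σ = 1) — the heavy-tailed abundance spectrum typical of
  miRNA libraries. Exact per-locus read counts can be pinned
  (`mirna_counts`) for threshold-calibration studies.
- **Repeat families** (default 4 families × 4 identical copies of a 300-nt
  consensus): reads from copy interiors multimap with known, integral
  `n_hits`; an optional per-copy mutation rate degrades multimapping
  deliberately.
- **One inverted-repeat plasmid**: backbone | 400-nt 5' arm | 59-nt loop |
  reverse-complemented arm | backbone. The 400-nt arm reflects the >400-bp
  stems of the expression constructs this models. The loop length is chosen
  so that `2·arm + loop ≡ 1 (mod 22)`: a palindromic stem read maps once per
  strand, and this geometry places its mirrored placement in the *same*
  phasing register as its primary one, so the planted terminal-phase signal
  is exact under fractional weighting rather than diluted into a second
  register. This is a simulator design choice, not an estimate of any real
  construct.
- **Hairpin read modes**: `terminal` places 5' ends at scaled positions
  ≡ 1 (mod 22) on both strands with a truncated-geometric number of 22-nt
  phase steps (decay 0.5 per step — most siRNA mass from the first cleavage,
  qualitatively) plus a `noise_fraction` of uniform starts (default 0.1);
  `distributed` draws uniform 5' ends over both arms. The closed forms
  register-1 = 1 (no noise) and `(1 − f) + f/22` (noise fraction f) follow
  directly and are asserted in tests.
- **Library composition** defaults: 70% miRNA, 20% hairpin, 8% repeat, 2%
  random (unmappable) reads; libraries of 100,000 reads; ≥ 2 replicates
  share the reference and resample reads with a replicate-offset seed.
  Reads are wrapped as `4N + insert + 4N + adapter` with constant base
  qualities (quality is unused downstream).

Determinism: one `SeedSequence` per (seed, stage, replicate) spawn key;
identical configurations produce byte-identical FASTA/FASTQ/GFF3/BED/truth
outputs.

What the generator does **not** emulate: sequencing errors, ligation and
PCR bias, isomiR 5'/3' heterogeneity, partial repeat-copy divergence
structure, RNA secondary-structure effects on targeting, and colorspace
reads. Passing tests therefore demonstrate algorithmic correctness on
idealized libraries — exact trimming closure, exact multimapper counts,
exact phasing arithmetic — not robustness to instrument noise; real-data
robustness rests on the perfect-match contract discarding imperfect reads.

## Problem sizes and tolerances

Tests and the acceptance script run desk-scale conditions chosen to make the
thresholds resolvable: cluster plant-and-recover uses 500,000-read libraries
(one read = 2 RPM, just below the 3-RPM discard; recoverable loci planted at
10–100 RPM with exact counts), phasing uses 10,000 hairpin reads (binomial
noise ≈ 0.005 against a ±0.02 assertion band), trimming closure uses 10,000
wrapped reads, and oracle-equivalence checks run 200 randomized instances
against brute-force references (sliding-window alignment scan; overlap graph
+ connected components + exhaustive join for clusters). Floating-point
conservation identities are asserted at 10⁻⁹ relative tolerance; interval
recovery uses Jaccard ≥ 0.9 (a 22-nt locus recovered by a 21–23-nt cluster
has Jaccard ≥ 21/23 ≈ 0.913).

## Known limitations

- The aligner is exact-match by design; mismatch-tolerant mapping must come
  from an external mapper via SAM import.
- Cluster strand is not modeled (per-strand counts are metadata only).
- The Welch test on repeat classes treats replicates as independent and is
  not a substitute for count-based differential models at low counts.
- When one placement overlaps repeats of two different classes its full
  weight goes to each class (classes are not renormalized); planted
  simulations never create this case, and real RepeatMasker overlaps of
  different classes are rare.
- Phasing pools both strands by a single register scale; constructs whose
  geometry makes mirrored placements register-incoherent will show diluted
  register concentration (per-strand profiles are provided for that case).
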