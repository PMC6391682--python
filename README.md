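# sirnaq

Small RNA-seq analysis of siRNA production from expressed long double-stranded
RNA: adapter trimming, perfect-match multimapper placement with fractional
counting, siRNA cluster discovery with hierarchical annotation, repeat-class
aggregation, and hairpin arm-density / phasing-register profiling — plus a
ground-truth synthetic-data generator for validating every stage.

## Who it is for

Groups studying RNAi in mammalian cells from plasmid-expressed RNA hairpins
(inverted repeats in a reporter 3'UTR, or pol III-driven stems) sequence small
RNA libraries and need to answer: how many 21–23-nt siRNAs does the hairpin
yield, where on the stem do they come from, are they phased the way processive
Dicer entry at a blunt terminus would produce them, and which genomic loci
(miRNA, transposon, mRNA) dominate the rest of the library? `sirnaq`
implements that analysis as a tested, reusable library with a thin CLI.

## The method

**Fractional counting.** A read placed perfectly at *n* loci contributes
weight 1/*n* at each locus, so total read mass is conserved. Abundance is
expressed as RPM (reads per million; used interchangeably with CPM): the
denominator is the number of distinct reads perfectly mapping to the genome
plus the transfected plasmid(s), so every library normalizes to exactly 10⁶
RPM.

**Cluster discovery.** For 21–23-nt reads:

1. weight each placement 1/*n*;
2. collapse transitively overlapping placements into unified regions, summing
   fractional counts;
3. discard regions below 3 RPM;
4. join surviving clusters ≤ 50 bp apart.

Only clusters present in **all** replicates of a group (intersect) survive;
overlapping clusters from different groups are merged by coordinate union,
with per-sample RPM re-derived over the merged region. Each final cluster is
annotated by the hierarchy
`miRNA > transposable elements > mRNA > misc. RNA > other`
and summarized as the median log₁₀ RPM across samples.

**Hairpin phasing.** Read 5'-end positions are scaled so the first hairpin
nucleotide is register 1; the register of a read is
`((scaled_start − 1) mod 22) + 1` (22 nt ≈ the Dicer step). The proportion of
fractional reads per register distinguishes end-phased processing (register 1
dominates) from internally initiated processing (flat profile). Arm-density
profiles report per-position CPM separately for 5'-arm reads (plotted up) and
3'-arm reads (plotted down), and reporter-antisense reads are selected by the
hairpin strand complementary to the targeted reporter.

**Trimming.** NEXTflex-style reads are trimmed in two rounds: leftmost 3'
adapter match (full-length matches tolerate one mismatch, ≥ 8-nt end matches
must be exact), then 4 forced bases off each end with a 15-nt minimum insert.

## Worked example

```python
from sirnaq import (SimConfig, simulate_reference, simulate_library, TrimConfig,
                    align_library, call_sample_clusters, phasing_profile,
                    hairpin_length_abundance)
from sirnaq.read_prep import TrimReport, trim_reads

cfg = SimConfig(seed=77, n_contigs=2, contig_length=15_000,
                n_mirna_loci=6, n_repeat_families=2, library_size=4000)
ref = simulate_reference(cfg)
reads, truth = simulate_library(cfg, ref, replicate=1)

report = TrimReport()
trimmed = list(trim_reads(reads, TrimConfig(), report))
print(f"{report.n_retained}/{report.n_input} reads retained after trimming")

lib = align_library(trimmed, ref.reference, sample_id="s1", group="ctrl")
print(f"{lib.denominator} mapped reads, {len(lib.alignments)} placements")

clusters = call_sample_clusters(lib)
print(f"{len(clusters)} clusters at >= 3 RPM")

prof = phasing_profile(lib, ref.hairpin)
print(f"hairpin phasing register 1: {prof.register(1):.3f}")

ab = hairpin_length_abundance(lib, ref.hairpin)
print("hairpin RPM by length:", {k: round(v) for k, v in ab.items()})
```

prints

```
4000/4000 reads retained after trimming
3923 mapped reads, 5685 placements
16 clusters at >= 3 RPM
hairpin phasing register 1: 0.905
hairpin RPM by length: {19: 0, 20: 0, 21: 43589, 22: 129493, 23: 39765, 24: 0}
```

Reading the numbers: every simulated NEXTflex read recovered its planted
insert (trimming never lost a read at these insert lengths); 3,923 of 4,000
reads map perfectly (the rest are planted unmappable noise), producing 5,685
placements because repeat- and hairpin-derived reads multimap; 16 loci pass
the 3-RPM cluster filter; the hairpin was simulated in terminal-phased mode
with 10% positional noise, so register 1 holds ≈ 0.9 of hairpin reads
(expected (1 − f) + f/22 ≈ 0.905 at f = 0.1); and hairpin siRNAs concentrate
at 21–23 nt with the planted 1:3:1 length mix.

The same flow is available from the shell:

```sh
sirnaq simulate --seed 77 --replicates 2 --out simdata/
sirnaq trim   --fastq simdata/lib_rep1.fastq --out trimmed.fastq
sirnaq align  --ref simdata/genome.fa --plasmid simdata/plasmid.fa \
              --fastq trimmed.fastq --out aln.tsv
sirnaq phase  --aln aln.tsv --spec simdata/hairpin.yaml
sirnaq run    --manifest run.yaml --out results/   # full multi-sample pipeline
```

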