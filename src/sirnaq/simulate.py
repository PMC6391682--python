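"""Synthetic small-RNA study generator with exact ground truth.

Emulates the statistical structure of plasmid-transfection small-RNA
libraries: reads of 15-30 nt dominated by miRNA-like loci with fixed 5'
ends and log-normal abundances, hairpin-derived 21-23-nt siRNAs in two
positional modes, repeat-derived multimappers spread over planted repeat
families, NEXTflex-style 4-nt randomized ends plus a 3' adapter, and a
replicate structure.  Every emitted read is traceable to one
ground-truth source.

Hairpin positional modes
------------------------
``terminal``
    Read 5' ends sit at scaled positions congruent to 1 modulo 22 on
    both strands, with geometrically decaying abundance per 22-nt phase
    step away from the open stem terminus, plus a configurable fraction
    of uniform-start noise.  Models processive Dicer entry at a blunt
    stem end (pol III hairpins).
``distributed``
    Uniform read 5' ends along both arms, modeling internally initiated
    cleavage of hairpins with long single-stranded overhangs (pol II
    hairpins).

The default hairpin geometry (arm 400 nt, loop 59 nt) satisfies
``2*arm + loop = 1 (mod 22)``, so the mirrored placement of a palindromic
stem read falls in the same phasing register as its primary placement;
the planted terminal-phase signal is then exact under fractional
multimapper weighting instead of being diluted by mirror registers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from ._util import revcomp
from .alignment import ReferenceSet
from .hairpin import HairpinSpec
from .quantify import AnnotationSet, GenomicInterval
from .read_prep import DEFAULT_ADAPTER, Read

REPEAT_CLASSES = ("SINE_B2", "LINE1", "ERVK", "ERVL", "SINE_B1", "MaLR")

_BASES = np.array(list("ACGT"))

#: siRNA/miRNA length distribution: 22-mers dominate, 21/23 flank.
_LENGTHS = np.array([21, 22, 23])
_LENGTH_PROBS = np.array([0.2, 0.6, 0.2])


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated study.

    Defaults describe one desk-scale condition: a 3 x 50-kb genome with
    30 miRNA-like loci (log-normal abundance), 4 repeat families of 4
    identical copies, one inverted-repeat plasmid with 400-nt arms, and
    100,000-read libraries of which 70% are miRNA-like, 20% hairpin
    siRNAs, 8% repeat-derived and 2% unmappable.
    """

    seed: int = 1
    # reference
    n_contigs: int = 3
    contig_length: int = 50_000
    n_mirna_loci: int = 30
    mirna_mu: float = 4.0
    mirna_sigma: float = 1.0
    n_repeat_families: int = 4
    copies_per_family: int = 4
    repeat_length: int = 300
    repeat_mutation_rate: float = 0.0
    plasmid_backbone: int = 500
    arm_length: int = 400
    loop_length: int = 59
    # library
    library_size: int = 100_000
    frac_mirna: float = 0.70
    frac_hairpin: float = 0.20
    frac_repeat: float = 0.08
    frac_random: float = 0.02
    hairpin_mode: str = "terminal"
    strand_bias: float = 0.5
    decay: float = 0.5
    noise_fraction: float = 0.1
    #: exact per-locus miRNA read counts; overrides abundance sampling
    mirna_counts: Optional[tuple[int, ...]] = None
    # read wrapping
    adapter: str = DEFAULT_ADAPTER
    randomized_end_length: int = 4

    def __post_init__(self) -> None:
        if self.hairpin_mode not in ("terminal", "distributed"):
            raise ValueError(f"unknown hairpin_mode {self.hairpin_mode!r}")
        for name in ("frac_mirna", "frac_hairpin", "frac_repeat", "frac_random",
                     "noise_fraction", "strand_bias", "repeat_mutation_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        total = self.frac_mirna + self.frac_hairpin + self.frac_repeat + self.frac_random
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {total}")
        if not 0.0 < self.decay <= 1.0:
            raise ValueError("decay must be in (0, 1]")
        if self.mirna_counts is not None and len(self.mirna_counts) != self.n_mirna_loci:
            raise ValueError("mirna_counts must have one entry per miRNA locus")


@dataclass
class GroundTruth:
    """Planted features and (after library simulation) per-read truth."""

    mirna: pd.DataFrame
    repeats: pd.DataFrame
    hairpin: HairpinSpec
    reads: Optional[pd.DataFrame] = None


@dataclass
class SimulatedReference:
    genome: dict[str, str]
    plasmid: dict[str, str]
    reference: ReferenceSet
    annotations: AnnotationSet
    hairpin: HairpinSpec
    truth: GroundTruth


def _rng(config: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=key))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
    return "".join(chars)


def simulate_reference(config: SimConfig) -> SimulatedReference:
    """Build the toy genome, plasmid, annotations and planted-feature truth.

    Contigs are random-composition; repeat-family copies are written over
    the background so multimappers have known, integral ``n_hits``;
    miRNA loci keep the (unique) background sequence at their position.
    The plasmid carries backbone | 5' arm | loop | revcomp(5' arm) |
    backbone.
    """
    rng = _rng(config, 0)
    if config.arm_length + config.loop_length <= 0:
        raise ValueError("hairpin arms must be non-empty")
    genome = {
        f"chr{i + 1}": _random_seq(rng, config.contig_length)
        for i in range(config.n_contigs)
    }

    # allocate non-overlapping feature slots, round-robin over contigs
    features: list[tuple[str, int, int]] = []  # (kind, index, length)
    features += [("mirna", i, 22) for i in range(config.n_mirna_loci)]
    features += [
        ("repeat", fam * config.copies_per_family + copy, config.repeat_length)
        for fam in range(config.n_repeat_families)
        for copy in range(config.copies_per_family)
    ]
    rng.shuffle(features)
    contig_names = list(genome)
    cursors = {name: 0 for name in contig_names}
    placements: dict[tuple[str, int], tuple[str, int]] = {}
    ci = 0
    for kind, idx, length in features:
        placed = False
        for _ in range(len(contig_names)):
            name = contig_names[ci % len(contig_names)]
            ci += 1
            start = cursors[name] + int(rng.integers(200, 1500))
            if start + length <= len(genome[name]):
                cursors[name] = start + length
                placements[(kind, idx)] = (name, start)
                placed = True
                break
        if not placed:
            raise ValueError("contigs too short for the requested feature count")

    # repeat families: identical copies of a family consensus
    consensus = [_random_seq(rng, config.repeat_length)
                 for _ in range(config.n_repeat_families)]
    mutable = {name: list(seq) for name, seq in genome.items()}
    repeat_rows = []
    for fam in range(config.n_repeat_families):
        cls = REPEAT_CLASSES[fam % len(REPEAT_CLASSES)]
        for copy in range(config.copies_per_family):
            contig, start = placements[("repeat", fam * config.copies_per_family + copy)]
            copy_seq = _mutate(rng, consensus[fam], config.repeat_mutation_rate)
            mutable[contig][start : start + config.repeat_length] = list(copy_seq)
            repeat_rows.append({
                "contig": contig, "start": start,
                "end": start + config.repeat_length,
                "name": f"{cls}_f{fam}c{copy}", "family": cls, "strand": "+",
            })
    genome = {name: "".join(chars) for name, chars in mutable.items()}

    # miRNA loci: fixed 5' end at `start`, log-normal relative abundance
    weights = rng.lognormal(config.mirna_mu, config.mirna_sigma, config.n_mirna_loci)
    mirna_rows = []
    for i in range(config.n_mirna_loci):
        contig, start = placements[("mirna", i)]
        mirna_rows.append({
            "name": f"sim-mir-{i + 1}", "contig": contig, "start": start,
            "end": start + 22, "strand": "+",
            "weight": weights[i] / weights.sum(),
        })

    # inverted-repeat plasmid
    arm5_seq = _random_seq(rng, config.arm_length)
    loop_seq = _random_seq(rng, config.loop_length)
    backbone5 = _random_seq(rng, config.plasmid_backbone)
    backbone3 = _random_seq(rng, config.plasmid_backbone)
    plasmid_seq = backbone5 + arm5_seq + loop_seq + revcomp(arm5_seq) + backbone3
    a5s = config.plasmid_backbone
    a5e = a5s + config.arm_length
    a3s = a5e + config.loop_length
    a3e = a3s + config.arm_length
    hairpin = HairpinSpec(
        plasmid_contig="plasmid_IR",
        hairpin_start=a5s, hairpin_end=a3e,
        arm5=(a5s, a5e), loop=(a5e, a3s), arm3=(a3s, a3e),
        reporter_antisense_strand="-",
    )
    plasmid = {"plasmid_IR": plasmid_seq}

    reference = ReferenceSet({**genome, **plasmid}, plasmids=["plasmid_IR"])
    mirna_frame = pd.DataFrame(mirna_rows)
    repeat_frame = pd.DataFrame(repeat_rows)
    annotations = AnnotationSet(
        mirna=[GenomicInterval(r.contig, r.start, r.end, r.strand, r.name)
               for r in mirna_frame.itertuples(index=False)],
        repeats=[GenomicInterval(r.contig, r.start, r.end, r.strand, r.name, r.family)
                 for r in repeat_frame.itertuples(index=False)],
    )
    truth = GroundTruth(mirna=mirna_frame, repeats=repeat_frame, hairpin=hairpin)
    return SimulatedReference(genome, plasmid, reference, annotations, hairpin, truth)


def _sample_lengths(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(_LENGTHS, size=n, p=_LENGTH_PROBS)


def _hairpin_batch(rng: np.random.Generator, config: SimConfig,
                   ref: SimulatedReference, n: int, uniform_all: bool
                   ) -> list[tuple[str, int, str, int]]:
    """Draw n hairpin reads as (insert, start, strand, scaled_start) tuples.

    Terminal mode places 5' ends at scaled positions congruent to 1
    modulo 22 on both strands (register 1), a truncated-geometric number
    of phase steps from the open stem terminus; uniform draws (all of
    them in distributed mode, a ``noise_fraction`` share otherwise) place
    5' ends uniformly within either arm.
    """
    spec = ref.hairpin
    plasmid = ref.plasmid[spec.plasmid_contig]
    A = config.arm_length
    lengths = _sample_lengths(rng, n)
    strands = np.where(rng.random(n) < config.strand_bias, "+", "-")
    uniform = np.ones(n, bool) if uniform_all else rng.random(n) < config.noise_fraction
    kmax = (A - 23) // 22
    probs = config.decay ** np.arange(kmax + 1)
    ks = rng.choice(kmax + 1, size=n, p=probs / probs.sum())
    arm3 = rng.random(n) < 0.5
    offsets = rng.integers(0, A - lengths + 1)
    out = []
    for i in range(n):
        length = int(lengths[i])
        strand = str(strands[i])
        if uniform[i]:
            arm = spec.arm3 if arm3[i] else spec.arm5
            start = int(arm[0] + offsets[i])
        elif strand == "+":
            # 5' end at scaled position 1 + 22k, inside the 5' arm
            start = spec.arm5[0] + 22 * int(ks[i])
        else:
            # 5' end at scaled position 2A + loop - 22k, inside the 3' arm
            p5 = spec.arm3[1] - 1 - 22 * int(ks[i])
            start = p5 - length + 1
        seq = plasmid[start : start + length]
        if strand == "-":
            seq = revcomp(seq)
        p5 = start if strand == "+" else start + length - 1
        out.append((seq, start, strand, p5 - spec.hairpin_start + 1))
    return out


def simulate_inserts(
    config: SimConfig,
    reference: SimulatedReference,
    replicate: int = 1,
) -> tuple[list[Read], pd.DataFrame]:
    """Draw one library's insert sequences plus the per-read truth table.

    Inserts are the mappable sequences (no adapter, no randomized ends);
    :func:`simulate_library` wraps them into raw NEXTflex-style reads.
    Replicates share the reference and planted loci but sample reads
    independently (seed offset by replicate index).
    """
    rng = _rng(config, 1, replicate)
    N = config.library_size
    mirna_t = reference.truth.mirna

    if config.mirna_counts is not None:
        locus_draws = np.repeat(np.arange(config.n_mirna_loci),
                                np.asarray(config.mirna_counts, dtype=int))
        rng.shuffle(locus_draws)
        n_mirna = len(locus_draws)
        rest = N - n_mirna
        if rest < 0:
            raise ValueError("mirna_counts exceed library_size")
        other = np.array([config.frac_hairpin, config.frac_repeat, config.frac_random])
        other = other / other.sum() if other.sum() > 0 else other
        n_hairpin, n_repeat, n_random = (rng.multinomial(rest, other)
                                         if other.sum() > 0 else (0, 0, 0))
    else:
        n_mirna, n_hairpin, n_repeat, n_random = rng.multinomial(
            N, [config.frac_mirna, config.frac_hairpin, config.frac_repeat,
                config.frac_random])
        locus_draws = rng.choice(config.n_mirna_loci, size=n_mirna,
                                 p=mirna_t["weight"].to_numpy())

    reads: list[Read] = []
    rows: dict[str, list] = {k: [] for k in
                             ("read_id", "source", "insert", "length", "contig",
                              "start", "strand", "scaled_start", "mirna_locus",
                              "repeat_family")}

    def add(source, insert, contig, start, strand, scaled=-1, locus=-1, family=""):
        rid = f"sim{replicate}_{len(reads):07d}"
        reads.append(Read(rid, insert))
        rows["read_id"].append(rid)
        rows["source"].append(source)
        rows["insert"].append(insert)
        rows["length"].append(len(insert))
        rows["contig"].append(contig)
        rows["start"].append(start)
        rows["strand"].append(strand)
        rows["scaled_start"].append(scaled)
        rows["mirna_locus"].append(locus)
        rows["repeat_family"].append(family)

    loci = list(mirna_t.itertuples(index=False))
    mirna_lengths = _sample_lengths(rng, len(locus_draws))
    for locus, length in zip(locus_draws, mirna_lengths):
        row = loci[int(locus)]
        start = int(row.start)  # fixed 5' end
        insert = reference.genome[row.contig][start : start + int(length)]
        add("mirna", insert, row.contig, start, "+", locus=int(locus))

    uniform_all = config.hairpin_mode == "distributed"
    for insert, start, strand, scaled in _hairpin_batch(
            rng, config, reference, n_hairpin, uniform_all):
        add("hairpin", insert, reference.hairpin.plasmid_contig, start, strand,
            scaled=scaled)

    copies = list(reference.truth.repeats.itertuples(index=False))
    fams = rng.integers(0, config.n_repeat_families, size=n_repeat)
    copy_idx = rng.integers(0, config.copies_per_family, size=n_repeat)
    rep_lengths = _sample_lengths(rng, n_repeat)
    rep_offsets = rng.integers(0, config.repeat_length - rep_lengths + 1)
    for i in range(n_repeat):
        copy = copies[int(fams[i]) * config.copies_per_family + int(copy_idx[i])]
        start = int(copy.start) + int(rep_offsets[i])
        insert = reference.genome[copy.contig][start : start + int(rep_lengths[i])]
        add("repeat", insert, copy.contig, start, "+", family=copy.family)

    for length in _sample_lengths(rng, n_random):
        add("random", _random_seq(rng, int(length)), "", -1, "+")

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = pd.DataFrame(rows).iloc[order].reset_index(drop=True)
    return reads, truth


def wrap_reads(config: SimConfig, inserts: Sequence[Read],
               replicate: int = 1) -> list[Read]:
    """Wrap inserts as 4N + insert + 4N + adapter raw reads."""
    rng = _rng(config, 2, replicate)
    k = config.randomized_end_length
    wrapped = []
    for read in inserts:
        seq = (_random_seq(rng, k) + read.sequence + _random_seq(rng, k)
               + config.adapter)
        wrapped.append(Read(read.read_id, seq, "I" * len(seq)))
    return wrapped


def simulate_library(
    config: SimConfig,
    reference: SimulatedReference,
    replicate: int = 1,
) -> tuple[list[Read], pd.DataFrame]:
    """One raw FASTQ-ready library (adapter-bearing reads) plus truth."""
    inserts, truth = simulate_inserts(config, reference, replicate)
    return wrap_reads(config, inserts, replicate), truth


def make_replicates(
    config: SimConfig,
    k: int,
    reference: Optional[SimulatedReference] = None,
) -> tuple[SimulatedReference, list[tuple[list[Read], pd.DataFrame]]]:
    """k independently sampled libraries over one shared reference."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if reference is None:
        reference = simulate_reference(config)
    return reference, [simulate_library(config, reference, rep)
                       for rep in range(1, k + 1)]


# ---------------------------------------------------------------------------
# serialization of the simulated study


def write_fasta(contigs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as out:
        for name, seq in contigs.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def write_mirna_gff3(mirna: pd.DataFrame, path) -> None:
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for r in mirna.itertuples(index=False):
            out.write(
                f"{r.contig}\tsirnaq_sim\tmiRNA\t{r.start + 1}\t{r.end}\t.\t"
                f"{r.strand}\t.\tID={r.name};Name={r.name}\n"
            )


def write_repeat_bed(repeats: pd.DataFrame, path) -> None:
    repeats[["contig", "start", "end", "name", "family", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_study(config: SimConfig, reference: SimulatedReference, outdir) -> dict:
    """Write FASTA/GFF3/BED/YAML reference files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "plasmid": outdir / "plasmid.fa",
        "mirna_gff3": outdir / "mirna.gff3",
        "repeats_bed": outdir / "repeats.bed",
        "hairpin_yaml": outdir / "hairpin.yaml",
        "config_yaml": outdir / "sim_config.yaml",
        "mirna_truth": outdir / "truth_mirna.tsv",
        "repeat_truth": outdir / "truth_repeats.tsv",
    }
    write_fasta(reference.genome, paths["genome"])
    write_fasta(reference.plasmid, paths["plasmid"])
    write_mirna_gff3(reference.truth.mirna, paths["mirna_gff3"])
    write_repeat_bed(reference.truth.repeats, paths["repeats_bed"])
    reference.hairpin.to_yaml(paths["hairpin_yaml"])
    with open(paths["config_yaml"], "w") as handle:
        data = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(config).items()}
        yaml.safe_dump(data, handle, sort_keys=False)
    reference.truth.mirna.to_csv(paths["mirna_truth"], sep="\t", index=False)
    reference.truth.repeats.to_csv(paths["repeat_truth"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
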