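"""Hairpin-arm siRNA profiling and the modulo-22 phasing statistic.

An expressed inverted repeat folds into a long dsRNA hairpin: a 5' arm,
a loop, and a 3' arm that is the reverse complement of the 5' arm.
Dicer processing leaves two distinct signatures in small-RNA data:

* processive cleavage from the open stem terminus concentrates read 5'
  ends in one residue class modulo 22 (the Dicer step size), while
  internally initiated cleavage distributes 5' ends along the stem;
* the strand of a hairpin read determines whether it can act as guide
  against a complementary reporter transcript.

Phasing convention: the first nucleotide of the hairpin defines register
1; a read's scaled start is its biological 5'-end position relative to
the hairpin start (1-based), and its register is
``((scaled_start - 1) mod period) + 1`` with period 22 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from .alignment import Alignment
from .quantify import SmallRnaLibrary, rpm


@dataclass(frozen=True)
class HairpinSpec:
    """Coordinates of an expressed inverted repeat on its plasmid.

    All intervals are 0-based half-open plasmid coordinates with
    ``arm5 < loop < arm3`` inside ``[hairpin_start, hairpin_end)``.
    ``reporter_antisense_strand`` names the strand whose reads are
    antisense to (and can guide cleavage of) the targeted reporter.
    """

    plasmid_contig: str
    hairpin_start: int
    hairpin_end: int
    arm5: tuple[int, int]
    loop: tuple[int, int]
    arm3: tuple[int, int]
    reporter_antisense_strand: str = "-"
    arm_length_tolerance: int = 0

    def __post_init__(self) -> None:
        a5s, a5e = self.arm5
        ls, le = self.loop
        a3s, a3e = self.arm3
        if not (self.hairpin_start <= a5s < a5e <= ls < le <= a3s < a3e <= self.hairpin_end):
            raise ValueError("require arm5 < loop < arm3 within the hairpin interval")
        if abs((a5e - a5s) - (a3e - a3s)) > self.arm_length_tolerance:
            raise ValueError(
                f"arm lengths differ ({a5e - a5s} vs {a3e - a3s}) beyond tolerance "
                f"{self.arm_length_tolerance}"
            )
        if self.reporter_antisense_strand not in ("+", "-"):
            raise ValueError("reporter_antisense_strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.hairpin_end - self.hairpin_start

    @classmethod
    def from_yaml(cls, path) -> "HairpinSpec":
        with open(path) as handle:
            data = yaml.safe_load(handle)
        return cls(
            plasmid_contig=data["plasmid_contig"],
            hairpin_start=int(data["hairpin_start"]),
            hairpin_end=int(data["hairpin_end"]),
            arm5=tuple(data["arm5"]),
            loop=tuple(data["loop"]),
            arm3=tuple(data["arm3"]),
            reporter_antisense_strand=data.get("reporter_antisense_strand", "-"),
            arm_length_tolerance=int(data.get("arm_length_tolerance", 0)),
        )

    def to_yaml(self, path) -> None:
        data = {
            "plasmid_contig": self.plasmid_contig,
            "hairpin_start": self.hairpin_start,
            "hairpin_end": self.hairpin_end,
            "arm5": list(self.arm5),
            "loop": list(self.loop),
            "arm3": list(self.arm3),
            "reporter_antisense_strand": self.reporter_antisense_strand,
            "arm_length_tolerance": self.arm_length_tolerance,
        }
        with open(path, "w") as handle:
            yaml.safe_dump(data, handle, sort_keys=False)


@dataclass
class DensityProfile:
    """Per-position CPM along the hairpin for one arm.

    ``sign`` is +1 for the 5' arm (plotted upward) and -1 for the 3' arm
    (plotted downward); ``cpm`` magnitudes are non-negative.
    """

    positions: np.ndarray  # hairpin-relative, 0-based
    cpm: np.ndarray
    arm: str  # "arm5" | "arm3"
    sign: int

    @property
    def signed_cpm(self) -> np.ndarray:
        return self.sign * self.cpm


@dataclass
class PhasingProfile:
    """Proportion of fractional reads in each phasing register (1..period)."""

    proportions: np.ndarray
    n_reads: float
    period: int = 22

    @property
    def defined(self) -> bool:
        return self.n_reads > 0

    def register(self, r: int) -> float:
        if not 1 <= r <= self.period:
            raise ValueError(f"register must be in 1..{self.period}")
        return float(self.proportions[r - 1])


def hairpin_alignments(
    library: SmallRnaLibrary,
    spec: HairpinSpec,
    lengths: Optional[tuple[int, int]] = (21, 23),
) -> list[Alignment]:
    """Length-filtered placements fully inside the hairpin interval."""
    if not any(a.contig == spec.plasmid_contig for a in library.alignments):
        # a plasmid with zero reads is legitimate downstream (empty profiles)
        pass
    out = []
    for aln in library.alignments:
        if aln.contig != spec.plasmid_contig:
            continue
        if not (spec.hairpin_start <= aln.start and aln.end <= spec.hairpin_end):
            continue
        if lengths is not None and not (lengths[0] <= aln.read_length <= lengths[1]):
            continue
        out.append(aln)
    return out


def _contains(interval: tuple[int, int], pos: int) -> bool:
    return interval[0] <= pos < interval[1]


def arm_density(
    library: SmallRnaLibrary,
    spec: HairpinSpec,
    lengths: tuple[int, int] = (21, 23),
    *,
    mode: str = "coverage",
) -> tuple[DensityProfile, DensityProfile]:
    """Per-position CPM of hairpin reads, split by arm.

    Reads are assigned to the 5' or 3' arm by the plasmid position of
    their biological 5' end (reads whose 5' end lies in the loop are
    assigned to neither).  In ``"coverage"`` mode every covered position
    receives the read's 1/n weight; ``"five_prime"`` mode counts weights
    at the 5'-end position only.  3'-arm values carry negative sign for
    plotting below the axis.
    """
    if spec.plasmid_contig not in {a.contig for a in library.alignments} and library.alignments:
        raise ValueError(
            f"plasmid contig {spec.plasmid_contig!r} absent from library "
            f"{library.sample_id!r} alignments"
        )
    if mode not in ("coverage", "five_prime"):
        raise ValueError(f"unknown density mode {mode!r}")
    length = spec.length
    up = np.zeros(length)
    down = np.zeros(length)
    for aln in hairpin_alignments(library, spec, lengths):
        p5 = aln.five_prime
        if _contains(spec.arm5, p5):
            target = up
        elif _contains(spec.arm3, p5):
            target = down
        else:
            continue
        if mode == "coverage":
            lo = aln.start - spec.hairpin_start
            hi = aln.end - spec.hairpin_start
            target[lo:hi] += aln.weight
        else:
            target[p5 - spec.hairpin_start] += aln.weight
    scale = 1e6 / library.denominator if library.denominator else 0.0
    positions = np.arange(length)
    return (
        DensityProfile(positions, up * scale, "arm5", +1),
        DensityProfile(positions, down * scale, "arm3", -1),
    )


def select_reporter_targeting(
    library: SmallRnaLibrary,
    spec: HairpinSpec,
    lengths: Optional[tuple[int, int]] = None,
) -> list[Alignment]:
    """Hairpin placements antisense to the targeted reporter.

    These are the guide-strand candidates for reporter cleavage: reads on
    the hairpin whose strand equals ``spec.reporter_antisense_strand``.
    """
    return [
        aln for aln in hairpin_alignments(library, spec, lengths)
        if aln.strand == spec.reporter_antisense_strand
    ]


def scaled_start(aln: Alignment, spec: HairpinSpec) -> int:
    """1-based position of a read's biological 5' end from the hairpin start."""
    return aln.five_prime - spec.hairpin_start + 1


def phasing_profile(
    library: SmallRnaLibrary,
    spec: HairpinSpec,
    lengths: tuple[int, int] = (21, 23),
    period: int = 22,
    strand: Optional[str] = None,
) -> PhasingProfile:
    """Distribution of fractional reads over phasing registers.

    ``register = ((scaled_start - 1) mod period) + 1`` where scaled start
    1 is the first hairpin nucleotide.  Both strands are pooled by
    default, each read entering through its own biological 5' end;
    ``strand`` restricts to one strand for per-strand breakdowns.
    Proportions sum to 1 whenever any read is present; an empty profile
    has ``n_reads = 0`` and NaN proportions.
    """
    if period < 2:
        raise ValueError("period must be >= 2")
    sums = np.zeros(period)
    for aln in hairpin_alignments(library, spec, lengths):
        if strand is not None and aln.strand != strand:
            continue
        register = (scaled_start(aln, spec) - 1) % period
        sums[register] += aln.weight
    total = float(sums.sum())
    if total == 0:
        return PhasingProfile(np.full(period, np.nan), 0.0, period)
    return PhasingProfile(sums / total, total, period)


def hairpin_length_abundance(
    library: SmallRnaLibrary,
    spec: HairpinSpec,
    lengths: tuple[int, int] = (19, 24),
) -> dict[int, float]:
    """RPM per read length of reads perfectly mapping within the hairpin."""
    lo, hi = lengths
    sums = {length: 0.0 for length in range(lo, hi + 1)}
    for aln in hairpin_alignments(library, spec, (lo, hi)):
        sums[aln.read_length] += aln.weight
    return {length: rpm(total, library) for length, total in sums.items()}
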