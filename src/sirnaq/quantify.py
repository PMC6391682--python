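"""Fractional counting, library normalization and repeat-class aggregation.

A read placed at *n* loci contributes weight 1/n at each locus, so total
read mass is conserved: summing weights over all placements recovers the
mapped-read count exactly.  Abundances are expressed as reads per
million (RPM, used interchangeably with CPM here): the denominator is
the number of distinct reads perfectly mapping to genome + plasmid
contigs, so a whole library always normalizes to 10^6 RPM.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from ._util import open_text
from .alignment import Alignment


@dataclass
class SmallRnaLibrary:
    """One sample's perfect-match alignment set plus normalization metadata.

    Under the default policy the denominator equals the number of
    distinct mapped read ids in ``alignments`` (reads mapping only to
    plasmids included).
    """

    sample_id: str
    alignments: list[Alignment]
    denominator: int
    group: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if self.denominator < 0:
            raise ValueError("denominator must be >= 0")

    def filter_lengths(self, length_range: tuple[int, int]) -> list[Alignment]:
        lo, hi = length_range
        return [a for a in self.alignments if lo <= a.read_length <= hi]


def fractional_weight(n_hits: int) -> float:
    """Weight 1/n of a read mapping to ``n_hits`` loci."""
    if n_hits <= 0:
        raise ValueError(f"n_hits must be positive, got {n_hits}")
    return 1.0 / n_hits


def rpm(count: float, library: SmallRnaLibrary) -> float:
    """Reads-per-million of a (possibly fractional) count in a library."""
    if library.denominator <= 0:
        raise ValueError(
            f"library {library.sample_id!r} has zero denominator; RPM undefined"
        )
    return count / library.denominator * 1e6


def _in_filter(aln: Alignment, contig_filter) -> bool:
    if contig_filter is None:
        return True
    if isinstance(contig_filter, str):
        return aln.contig == contig_filter
    contig, start, end = contig_filter
    return aln.contig == contig and aln.start >= start and aln.end <= end


def length_histogram(
    library: SmallRnaLibrary,
    contig_filter=None,
    length_range: tuple[int, int] = (15, 30),
) -> dict[int, float]:
    """RPM per read length for alignments inside a contig/region filter.

    ``contig_filter`` is ``None`` (whole reference), a contig name, or a
    ``(contig, start, end)`` region requiring full containment of the
    alignment interval.  A region filter with non-positive extent raises.
    """
    if isinstance(contig_filter, tuple):
        _, start, end = contig_filter
        if end <= start:
            raise ValueError(f"empty filter region [{start}, {end})")
    lo, hi = length_range
    sums = {length: 0.0 for length in range(lo, hi + 1)}
    for aln in library.alignments:
        if lo <= aln.read_length <= hi and _in_filter(aln, contig_filter):
            sums[aln.read_length] += aln.weight
    return {length: rpm(total, library) for length, total in sums.items()}


# ---------------------------------------------------------------------------
# annotations


@dataclass(frozen=True)
class GenomicInterval:
    contig: str
    start: int
    end: int
    strand: str = "."
    label: str = ""
    family: str = ""  # repeat class/family where applicable


#: Annotation categories in hierarchy order (highest priority first),
#: followed implicitly by "other".
CATEGORY_PRIORITY = ("miRNA", "transposable_elements", "mRNA", "misc_RNA")

_SOURCE_TO_CATEGORY = {
    "mirna": "miRNA",
    "repeats": "transposable_elements",
    "exons": "mRNA",
    "misc_rna": "misc_RNA",
}


class AnnotationSet:
    """miRNA / exon / repeat / misc-RNA interval sets with overlap lookup.

    Category membership is defined by annotation source; positional
    conflicts between categories are resolved downstream by the
    classification hierarchy, not here.
    """

    def __init__(
        self,
        mirna: Sequence[GenomicInterval] = (),
        exons: Sequence[GenomicInterval] = (),
        repeats: Sequence[GenomicInterval] = (),
        misc_rna: Sequence[GenomicInterval] = (),
    ):
        self.mirna = list(mirna)
        self.exons = list(exons)
        self.repeats = list(repeats)
        self.misc_rna = list(misc_rna)
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for source in ("mirna", "exons", "repeats", "misc_rna"):
            for iv in getattr(self, source):
                key = (source, iv.contig)
                self._trees.setdefault(key, IntervalTree()).addi(iv.start, iv.end, iv)

    def overlapping(self, source: str, contig: str, start: int, end: int
                    ) -> list[GenomicInterval]:
        """Intervals of one source overlapping [start, end) by >= 1 bp."""
        tree = self._trees.get((source, contig))
        if tree is None or end <= start:
            return []
        return [hit.data for hit in tree.overlap(start, end)]

    def categories_overlapping(self, contig: str, start: int, end: int) -> set[str]:
        found = set()
        for source, category in _SOURCE_TO_CATEGORY.items():
            if self.overlapping(source, contig, start, end):
                found.add(category)
        return found

    @classmethod
    def from_files(cls, mirna_gff3=None, exons_gff3=None, repeats_bed=None,
                   misc_gff3=None) -> "AnnotationSet":
        return cls(
            mirna=load_gff3(mirna_gff3, feature_types=("miRNA", "miRNA_primary_transcript"))
            if mirna_gff3 else (),
            exons=load_gff3(exons_gff3, feature_types=("exon",)) if exons_gff3 else (),
            repeats=load_repeat_bed(repeats_bed) if repeats_bed else (),
            misc_rna=load_gff3(misc_gff3) if misc_gff3 else (),
        )


def load_gff3(path, feature_types: Optional[Sequence[str]] = None
              ) -> list[GenomicInterval]:
    """Read GFF3 intervals (miRBase / Ensembl dialects; Name/ID honored).

    GFF3 is 1-based closed; intervals are converted to 0-based half-open.
    When ``feature_types`` is given but matches nothing, all features are
    used (miRBase-style files sometimes collapse types).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    wanted = set(feature_types) if feature_types else None
    intervals: list[GenomicInterval] = []
    for feat in db.all_features():
        if wanted is not None and feat.featuretype not in wanted:
            continue
        label = (feat.attributes.get("Name", [None])[0]
                 or feat.attributes.get("ID", [feat.featuretype])[0])
        intervals.append(GenomicInterval(
            contig=feat.seqid, start=feat.start - 1, end=feat.end,
            strand=feat.strand or ".", label=label,
        ))
    if not intervals and wanted is not None:
        return load_gff3(path, feature_types=None)
    return intervals


def load_repeat_bed(path) -> list[GenomicInterval]:
    """Read a RepeatMasker-style BED6+: chrom start end name class strand."""
    frame = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "name", "family", "strand"],
        usecols=range(6), dtype={"chrom": str},
    )
    return [
        GenomicInterval(str(r.chrom), int(r.start), int(r.end),
                        str(r.strand), str(r.name), str(r.family))
        for r in frame.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# repeat-class aggregation and replicate comparison


def aggregate_by_repeat_class(
    library: SmallRnaLibrary,
    annotations: AnnotationSet,
    length_range: tuple[int, int] = (21, 23),
    *,
    exclusive: bool = False,
) -> pd.Series:
    """RPM of reads per repeat class (SINE B2, LINE1, ERVK, ...).

    Each placement overlapping a repeat interval (>= 1 bp, strand-agnostic)
    contributes its 1/n weight to the class of that repeat; a multimapper
    whose placements fall in different classes contributes to each.  With
    ``exclusive=True`` reads that also overlap miRNA or exon annotation
    are excluded.
    """
    totals: dict[str, float] = defaultdict(float)
    for aln in library.filter_lengths(length_range):
        hits = annotations.overlapping("repeats", aln.contig, aln.start, aln.end)
        if not hits:
            continue
        if exclusive and (
            annotations.overlapping("mirna", aln.contig, aln.start, aln.end)
            or annotations.overlapping("exons", aln.contig, aln.start, aln.end)
        ):
            continue
        # one weight per distinct class overlapped by this placement
        for family in {h.family for h in hits}:
            totals[family] += aln.weight
    series = pd.Series({cls: rpm(total, library) for cls, total in sorted(totals.items())},
                       dtype=float)
    series.index.name = "repeat_class"
    series.name = library.sample_id
    return series


def compare_groups(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch t-test per repeat class between two replicate groups.

    Inputs are class-by-replicate RPM tables.  Classes absent from one
    group are treated as zero in that group.  Degenerate comparisons
    (zero variance in both groups with equal means) report p = 1.
    """
    if group_a.shape[1] < 2 or group_b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per group for a t-test")
    classes = sorted(set(group_a.index) | set(group_b.index))
    a = group_a.reindex(classes, fill_value=0.0)
    b = group_b.reindex(classes, fill_value=0.0)
    rows = []
    for cls in classes:
        x = a.loc[cls].to_numpy(dtype=float)
        y = b.loc[cls].to_numpy(dtype=float)
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            p = 1.0 if x[0] == y[0] else 0.0
        else:
            p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
            if math.isnan(p):
                p = 1.0
        rows.append((cls, float(x.mean()), float(y.mean()), p, p < alpha))
    return pd.DataFrame(
        rows, columns=["repeat_class", "mean_a", "mean_b", "p_value", "significant"]
    ).set_index("repeat_class")


def total_fractional_count(alignments: Iterable[Alignment]) -> float:
    """Sum of 1/n weights over placements; equals the mapped-read count."""
    return sum(a.weight for a in alignments)
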