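"""21-23-nt small-RNA cluster discovery with hierarchical annotation.

The per-sample algorithm has four steps:

1. weight every placement by its fractional count 1/n;
2. collapse transitively overlapping placements (strand-agnostic) into
   unified regions, summing their fractional counts;
3. discard regions below 3 RPM;
4. join surviving clusters separated by at most 50 bp, re-deriving RPM.

Only clusters present in all replicates of a group (intersect) survive;
overlapping clusters from different groups are then merged by coordinate
union.  Final clusters are annotated by the classification hierarchy
miRNA > transposable elements > mRNA > misc. RNA > other, and summarized
as the median log10 RPM across samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from statistics import median
from typing import Iterable, Mapping, Optional, Sequence

from .alignment import Alignment
from .quantify import (
    CATEGORY_PRIORITY,
    AnnotationSet,
    SmallRnaLibrary,
    rpm,
)


@dataclass(frozen=True)
class ClusterParams:
    """Tunables of the cluster algorithm (defaults follow the method)."""

    read_lengths: tuple[int, int] = (21, 23)
    rpm_threshold: float = 3.0
    join_distance: int = 50
    log_floor: float = 0.1  # RPM pseudovalue for log10 summaries

    def __post_init__(self) -> None:
        if self.rpm_threshold <= 0:
            raise ValueError("rpm_threshold must be > 0")
        if self.join_distance < 0:
            raise ValueError("join_distance must be >= 0")


@dataclass
class Cluster:
    """A genomic region of collapsed 21-23-nt reads."""

    contig: str
    start: int
    end: int
    fractional_count: float = 0.0
    rpm: float = 0.0
    sample_rpms: dict[str, float] = field(default_factory=dict)
    replicate_rpms: dict[int, float] = field(default_factory=dict)
    category: Optional[str] = None
    strand_counts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"cluster requires start < end, got [{self.start}, {self.end})")

    def overlaps(self, other: "Cluster") -> bool:
        return self.contig == other.contig and self.start < other.end and other.start < self.end

    @property
    def span(self) -> tuple[str, int, int]:
        return (self.contig, self.start, self.end)


def collapse_regions(
    alignments: Sequence[Alignment],
) -> list[tuple[str, int, int, float]]:
    """Collapse overlapping placements into (contig, start, end, count) regions.

    Regions are maximal sets of transitively overlapping intervals
    (strand-agnostic); abutting half-open intervals do not overlap.  Each
    region's count is the sum of its members' 1/n weights.
    """
    items = sorted(alignments, key=lambda a: (a.contig, a.start, a.end))
    regions: list[tuple[str, int, int, float]] = []
    cur = None  # [contig, start, end, count]
    for aln in items:
        if cur is not None and aln.contig == cur[0] and aln.start < cur[2]:
            cur[2] = max(cur[2], aln.end)
            cur[3] += aln.weight
        else:
            if cur is not None:
                regions.append(tuple(cur))
            cur = [aln.contig, aln.start, aln.end, aln.weight]
    if cur is not None:
        regions.append(tuple(cur))
    return regions


def call_sample_clusters(
    library: SmallRnaLibrary,
    params: ClusterParams = ClusterParams(),
) -> list[Cluster]:
    """Run steps 1-4 of the cluster algorithm on one library.

    Order matters: the RPM filter is applied before joining, so two
    sub-threshold regions can never rescue each other by proximity.
    A join requires gap = next.start - prev.end <= join_distance.
    """
    if library.denominator <= 0:
        raise ValueError(
            f"library {library.sample_id!r} has zero denominator; cannot call clusters"
        )
    filtered = library.filter_lengths(params.read_lengths)
    regions = collapse_regions(filtered)

    retained = [
        (contig, start, end, count)
        for contig, start, end, count in regions
        if rpm(count, library) >= params.rpm_threshold
    ]

    joined: list[list] = []
    for contig, start, end, count in retained:  # already coordinate-sorted
        if (
            joined
            and joined[-1][0] == contig
            and start - joined[-1][2] <= params.join_distance
        ):
            joined[-1][2] = max(joined[-1][2], end)
            joined[-1][3] += count
        else:
            joined.append([contig, start, end, count])

    by_contig: dict[str, list[Alignment]] = {}
    for aln in filtered:
        by_contig.setdefault(aln.contig, []).append(aln)
    for alns in by_contig.values():
        alns.sort(key=lambda a: a.start)
    max_len = max((a.read_length for a in filtered), default=0)

    clusters = []
    for contig, start, end, count in joined:
        value = rpm(count, library)
        clusters.append(Cluster(
            contig=contig, start=start, end=end, fractional_count=count,
            rpm=value,
            sample_rpms={library.sample_id: value},
            replicate_rpms={library.replicate: value},
            strand_counts=_strand_counts(by_contig.get(contig, []), start, end,
                                         max_len),
        ))
    return clusters


def _strand_counts(sorted_alns: list[Alignment], start: int, end: int,
                   max_len: int) -> dict[str, float]:
    # sorted_alns is start-sorted; only starts in [start - max_len, end) can overlap
    from bisect import bisect_left

    counts = {"+": 0.0, "-": 0.0}
    i = bisect_left(sorted_alns, start - max_len, key=lambda a: a.start)
    while i < len(sorted_alns) and sorted_alns[i].start < end:
        aln = sorted_alns[i]
        if aln.end > start:
            counts[aln.strand] += aln.weight
        i += 1
    return counts


def _union_components(cluster_lists: Sequence[Sequence[Cluster]]
                      ) -> list[tuple[str, int, int, list[tuple[int, Cluster]]]]:
    """Transitive-overlap components across lists, tagging member origin.

    Returns (contig, start, end, members) with members as (list_index,
    cluster) pairs; coordinates are the union of member intervals.
    """
    tagged = [
        (c.contig, c.start, c.end, idx, c)
        for idx, clusters in enumerate(cluster_lists)
        for c in clusters
    ]
    tagged.sort(key=lambda t: (t[0], t[1], t[2]))
    components = []
    cur = None  # [contig, start, end, members]
    for contig, start, end, idx, cluster in tagged:
        if cur is not None and contig == cur[0] and start < cur[2]:
            cur[2] = max(cur[2], end)
            cur[3].append((idx, cluster))
        else:
            if cur is not None:
                components.append((cur[0], cur[1], cur[2], cur[3]))
            cur = [contig, start, end, [(idx, cluster)]]
    if cur is not None:
        components.append((cur[0], cur[1], cur[2], cur[3]))
    return components


def intersect_replicates(cluster_sets: Sequence[Sequence[Cluster]]) -> list[Cluster]:
    """Keep regions supported by every replicate of a group.

    A region (the union of transitively overlapping replicate clusters)
    is retained iff every replicate contributes at least one overlapping
    cluster.  Per-replicate RPMs over the region are recorded.  A single
    replicate passes through with union semantics applied vacuously.
    """
    if not cluster_sets:
        raise ValueError("need at least one replicate cluster set")
    n_reps = len(cluster_sets)
    result = []
    for contig, start, end, members in _union_components(cluster_sets):
        reps_present = {idx for idx, _ in members}
        if len(reps_present) < n_reps:
            continue
        replicate_rpms: dict[int, float] = {}
        sample_rpms: dict[str, float] = {}
        count = 0.0
        for _, cluster in members:
            count += cluster.fractional_count
            for rep, value in cluster.replicate_rpms.items():
                replicate_rpms[rep] = replicate_rpms.get(rep, 0.0) + value
            for sample, value in cluster.sample_rpms.items():
                sample_rpms[sample] = sample_rpms.get(sample, 0.0) + value
        result.append(Cluster(
            contig=contig, start=start, end=end, fractional_count=count,
            rpm=float(median(replicate_rpms.values())),
            sample_rpms=sample_rpms, replicate_rpms=replicate_rpms,
        ))
    return result


def merge_between_samples(
    group_cluster_sets: Mapping[str, Sequence[Cluster]],
    libraries: Optional[Sequence[SmallRnaLibrary]] = None,
    params: ClusterParams = ClusterParams(),
) -> list[Cluster]:
    """Merge overlapping clusters across groups by coordinate union.

    Every merged cluster carries an RPM for every sample (0 where the
    sample has no reads there).  When ``libraries`` are provided,
    per-sample RPMs over the merged region are recomputed from the
    length-filtered reads; otherwise pre-merge cluster RPMs are summed.
    """
    group_names = list(group_cluster_sets)
    components = _union_components([group_cluster_sets[g] for g in group_names])
    all_samples: set[str] = set()
    for clusters in group_cluster_sets.values():
        for c in clusters:
            all_samples.update(c.sample_rpms)
    if libraries is not None:
        all_samples.update(lib.sample_id for lib in libraries)

    merged = []
    for contig, start, end, members in components:
        if libraries is not None:
            sample_rpms = {
                lib.sample_id: rpm(
                    sum(a.weight for a in lib.filter_lengths(params.read_lengths)
                        if a.contig == contig and a.start < end and start < a.end),
                    lib,
                )
                for lib in libraries
            }
            count = sum(
                sum(a.weight for a in lib.filter_lengths(params.read_lengths)
                    if a.contig == contig and a.start < end and start < a.end)
                for lib in libraries
            )
        else:
            sample_rpms = {s: 0.0 for s in all_samples}
            count = 0.0
            for _, cluster in members:
                count += cluster.fractional_count
                for sample, value in cluster.sample_rpms.items():
                    sample_rpms[sample] += value
        merged.append(Cluster(
            contig=contig, start=start, end=end, fractional_count=count,
            rpm=float(median(sample_rpms.values())) if sample_rpms else 0.0,
            sample_rpms=sample_rpms,
        ))
    merged.sort(key=lambda c: (c.contig, c.start, c.end))
    return merged


def annotate_cluster(cluster: Cluster, annotations: AnnotationSet) -> str:
    """Highest-priority annotation category overlapping the cluster.

    Hierarchy: miRNA > transposable_elements > mRNA > misc_RNA; clusters
    overlapping nothing are "other".  Overlap is >= 1 bp, strand-agnostic.
    """
    found = annotations.categories_overlapping(cluster.contig, cluster.start, cluster.end)
    for category in CATEGORY_PRIORITY:
        if category in found:
            cluster.category = category
            return category
    cluster.category = "other"
    return "other"


def summarize_cluster(cluster: Cluster, log_floor: Optional[float] = 0.1) -> float:
    """Median log10 RPM across samples, flooring zeros at ``log_floor``.

    With ``log_floor=None`` zero RPMs are dropped; an all-zero cluster is
    then reported as NaN (missing).
    """
    values = list(cluster.sample_rpms.values()) or [cluster.rpm]
    if log_floor is None:
        values = [v for v in values if v > 0]
        if not values:
            return float("nan")
    else:
        values = [max(v, log_floor) for v in values]
    return float(median(math.log10(v) for v in values))


def clusters_to_bed(clusters: Sequence[Cluster], log_floor: float = 0.1) -> str:
    """BED6 text: score = median log10 RPM x 100, rounded; strand '.'."""
    lines = []
    for i, c in enumerate(sorted(clusters, key=lambda c: (c.contig, c.start, c.end)), 1):
        score = int(round(summarize_cluster(c, log_floor) * 100))
        name = c.category or f"cluster_{i}"
        lines.append(f"{c.contig}\t{c.start}\t{c.end}\t{name}\t{score}\t.")
    return "\n".join(lines) + ("\n" if lines else "")
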