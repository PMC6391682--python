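"""Cluster algorithm: oracle equivalence, boundaries, intersect/merge, hierarchy."""

from __future__ import annotations

import math

import numpy as np
import pytest

from _factories import aln, lib
from _oracles import brute_force_clusters
from sirnaq import (
    AnnotationSet,
    Cluster,
    ClusterParams,
    annotate_cluster,
    call_sample_clusters,
    collapse_regions,
    intersect_replicates,
    merge_between_samples,
    summarize_cluster,
)
from sirnaq.clusters import clusters_to_bed
from sirnaq.quantify import GenomicInterval


def random_instance(rng, n_reads=None, denominator=None):
    n = int(rng.integers(1, 500)) if n_reads is None else n_reads
    denominator = int(rng.integers(50, 5000)) if denominator is None else denominator
    alignments = []
    for i in range(n):
        contig = f"c{rng.integers(0, 3)}"
        start = int(rng.integers(0, 5000))
        length = int(rng.integers(21, 24))
        n_hits = int(rng.integers(1, 5))
        alignments.append(aln(contig=contig, start=start, length=length,
                              n_hits=n_hits, read_id=f"r{i}"))
    return lib(alignments, denominator=denominator)


def as_regions(clusters):
    return sorted((c.contig, c.start, c.end, round(c.fractional_count, 9))
                  for c in clusters)


def test_cluster_calls_match_brute_force_200_instances():
    """Full pipeline equals overlap-graph + exhaustive-join reference."""
    rng = np.random.default_rng(2024)
    params = ClusterParams()
    for _ in range(200):
        library = random_instance(rng)
        got = as_regions(call_sample_clusters(library, params))
        expected = sorted(
            (c, s, e, round(cnt, 9))
            for c, s, e, cnt in brute_force_clusters(
                library.alignments, library.denominator)
        )
        assert got == expected


@pytest.mark.parametrize(
    "intervals, expected",
    [
        # overlapping reads collapse to one region with summed counts
        ([(100, 122), (110, 132)], [(100, 132, 2.0)]),
        # abutting half-open intervals do not overlap
        ([(100, 122), (122, 144)], [(100, 122, 1.0), (122, 144, 1.0)]),
        ([], []),
    ],
)
def test_collapse_regions(intervals, expected):
    alignments = [aln(start=s, length=e - s, read_id=f"r{i}")
                  for i, (s, e) in enumerate(intervals)]
    got = [(s, e, c) for _, s, e, c in collapse_regions(alignments)]
    assert got == expected


def test_collapse_conserves_total_weight():
    rng = np.random.default_rng(5)
    library = random_instance(rng, n_reads=300)
    regions = collapse_regions(library.alignments)
    assert sum(c for *_, c in regions) == pytest.approx(
        sum(a.weight for a in library.alignments))


def test_rpm_threshold_boundary():
    """2-RPM regions are discarded, 3-RPM regions retained."""
    two = [aln(start=100, read_id=f"a{i}") for i in range(2)]
    three = [aln(start=1000, read_id=f"b{i}") for i in range(3)]
    clusters = call_sample_clusters(lib(two + three, denominator=10**6))
    assert as_regions(clusters) == [("chr1", 1000, 1022, 3.0)]
    assert clusters[0].rpm == pytest.approx(3.0)


def test_join_distance_boundary():
    """Gap of exactly 50 bp joins; 51 bp stays separate."""
    def clusters_for(gap):
        left = [aln(start=100, read_id=f"l{i}") for i in range(5)]
        right = [aln(start=122 + gap, read_id=f"r{i}") for i in range(5)]
        return call_sample_clusters(lib(left + right, denominator=10**6))

    joined = clusters_for(50)
    assert as_regions(joined) == [("chr1", 100, 194, 10.0)]
    split = clusters_for(51)
    assert [c.span for c in split] == [("chr1", 100, 122), ("chr1", 173, 195)]


def test_filter_before_join():
    """A sub-threshold region cannot bridge two retained clusters."""
    left = [aln(start=100, read_id=f"l{i}") for i in range(5)]
    middle = [aln(start=160, read_id="m0")]  # 1 RPM, discarded first
    right = [aln(start=230, read_id=f"r{i}") for i in range(5)]
    clusters = call_sample_clusters(lib(left + middle + right, denominator=10**6))
    # gaps via the middle region would be 38 and 48 bp, but it is discarded
    # before joining; the direct left-right gap is 108 bp, so they stay split
    assert [c.span for c in clusters] == [("chr1", 100, 122), ("chr1", 230, 252)]


def test_monotonicity_in_threshold_and_join():
    rng = np.random.default_rng(17)
    library = random_instance(rng, n_reads=400, denominator=200)
    base = len(call_sample_clusters(library, ClusterParams()))
    stricter = len(call_sample_clusters(library, ClusterParams(rpm_threshold=30)))
    wider = len(call_sample_clusters(library, ClusterParams(join_distance=500)))
    assert stricter <= base
    assert wider <= base


def test_zero_denominator_refused():
    with pytest.raises(ValueError):
        call_sample_clusters(lib([aln()], denominator=0))


def cluster(contig="chr1", start=100, end=200, rpm_value=10.0, sample="s1",
            replicate=1):
    return Cluster(contig=contig, start=start, end=end, fractional_count=rpm_value,
                   rpm=rpm_value, sample_rpms={sample: rpm_value},
                   replicate_rpms={replicate: rpm_value})


def test_intersect_replicates_rules():
    rep1 = [cluster(start=100, end=150, replicate=1, sample="r1"),
            cluster(start=900, end=950, replicate=1, sample="r1")]
    rep2 = [cluster(start=140, end=190, replicate=2, sample="r2")]
    rep3 = [cluster(start=120, end=160, replicate=3, sample="r3")]
    kept = intersect_replicates([rep1, rep2, rep3])
    # the shared locus survives with union coordinates; the rep1-only locus dies
    assert [(c.start, c.end) for c in kept] == [(100, 190)]
    assert set(kept[0].replicate_rpms) == {1, 2, 3}
    # 2/3 replicates is not enough
    assert intersect_replicates([rep1, rep2, [cluster(start=5000, end=5050)]]) == []
    # single replicate passes through
    assert [(c.start, c.end) for c in intersect_replicates([rep1])] == [
        (100, 150), (900, 950)]
    with pytest.raises(ValueError):
        intersect_replicates([])


def test_merge_between_samples_union():
    a = [cluster(start=100, end=150, sample="a1")]
    b = [cluster(start=140, end=190, sample="b1")]
    merged = merge_between_samples({"A": a, "B": b})
    assert [(c.start, c.end) for c in merged] == [(100, 190)]
    assert merged[0].sample_rpms == {"a1": 10.0, "b1": 10.0}
    # non-overlapping clusters stay separate, absent samples report 0
    far = [cluster(start=1000, end=1050, sample="b1")]
    merged2 = merge_between_samples({"A": a, "B": far})
    assert [(c.start, c.end) for c in merged2] == [(100, 150), (1000, 1050)]
    assert merged2[0].sample_rpms == {"a1": 10.0, "b1": 0.0}


def test_merge_three_way_chain():
    """Transitive overlap A-B, B-C merges into a single region."""
    a = [cluster(start=100, end=150, sample="a1")]
    b = [cluster(start=140, end=220, sample="b1")]
    c = [cluster(start=210, end=260, sample="c1")]
    merged = merge_between_samples({"A": a, "B": b, "C": c})
    assert [(x.start, x.end) for x in merged] == [(100, 260)]


def test_merge_recomputes_from_reads():
    """With libraries supplied, per-sample RPM is re-derived over the region."""
    reads_a = [aln(start=100 + i, read_id=f"a{i}") for i in range(4)]
    lib_a = lib(reads_a, denominator=10**6, sample_id="a1")
    lib_b = lib([aln(start=140, read_id="b0")], denominator=10**6, sample_id="b1")
    a = [cluster(start=100, end=126, rpm_value=4.0, sample="a1")]
    b = [cluster(start=120, end=162, rpm_value=1.0, sample="b1")]
    merged = merge_between_samples({"A": a, "B": b}, libraries=[lib_a, lib_b])
    assert [(c.start, c.end) for c in merged] == [(100, 162)]
    assert merged[0].sample_rpms == {"a1": 4.0, "b1": 1.0}


ANNOT = AnnotationSet(
    mirna=[GenomicInterval("chr1", 100, 200, "+", "mir-1")],
    exons=[GenomicInterval("chr1", 150, 400, "+", "GeneA")],
    repeats=[GenomicInterval("chr1", 300, 500, "+", "L1", "LINE1")],
    misc_rna=[GenomicInterval("chr1", 450, 600, "+", "snoRNA")],
)


@pytest.mark.parametrize(
    "start, end, expected",
    [
        (120, 180, "miRNA"),                   # miRNA + mRNA -> miRNA
        (350, 420, "transposable_elements"),   # repeat + mRNA -> TE
        (470, 520, "transposable_elements"),   # repeat + misc -> TE
        (210, 290, "mRNA"),                    # mRNA only
        (380, 460, "transposable_elements"),   # repeat + mRNA + misc
        (510, 590, "misc_RNA"),                # misc only
        (1000, 1100, "other"),                 # nothing
    ],
)
def test_annotation_hierarchy(start, end, expected):
    c = cluster(start=start, end=end)
    assert annotate_cluster(c, ANNOT) == expected
    assert c.category == expected


def test_summarize_cluster_median_log10():
    c = Cluster("chr1", 0, 10, sample_rpms={"a": 1.0, "b": 10.0, "c": 100.0})
    assert summarize_cluster(c) == pytest.approx(1.0)
    single = Cluster("chr1", 0, 10, sample_rpms={"a": 1000.0})
    assert summarize_cluster(single) == pytest.approx(3.0)
    floored = Cluster("chr1", 0, 10, sample_rpms={"a": 0.0, "b": 10.0})
    # floor 0.1: median of {-1, 1} = 0
    assert summarize_cluster(floored, 0.1) == pytest.approx(0.0)
    assert math.isnan(summarize_cluster(Cluster("chr1", 0, 10,
                                                sample_rpms={"a": 0.0}), None))


def test_bed_export_score_and_sorting():
    clusters = [
        Cluster("chr2", 50, 80, sample_rpms={"a": 100.0}, category="miRNA"),
        Cluster("chr1", 10, 40, sample_rpms={"a": 10.0}, category="other"),
    ]
    bed = clusters_to_bed(clusters)
    lines = bed.strip().split("\n")
    assert lines[0].split("\t") == ["chr1", "10", "40", "other", "100", "."]
    assert lines[1].split("\t") == ["chr2", "50", "80", "miRNA", "200", "."]
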