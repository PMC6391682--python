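"""Independent brute-force references used to check the implementation.

These deliberately use naive strategies (sliding-window scans, explicit
overlap graphs, exhaustive join passes) so they share no code with the
production paths they verify.
"""

from __future__ import annotations

import networkx as nx

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_align(seq: str, contigs: dict[str, str]) -> list[tuple[str, int, int, str]]:
    """All perfect placements of seq via exhaustive scan of both strands."""
    if "N" in seq or not seq:
        return []
    hits = []
    rcseq = rc(seq)
    for name, text in contigs.items():
        for probe, strand in ((seq, "+"), (rcseq, "-")):
            for pos in range(len(text) - len(seq) + 1):
                if text[pos : pos + len(seq)] == probe:
                    hits.append((name, pos, pos + len(seq), strand))
    return hits


def brute_force_clusters(
    alignments,
    denominator: int,
    rpm_threshold: float = 3.0,
    join_distance: int = 50,
    read_lengths: tuple[int, int] = (21, 23),
) -> list[tuple[str, int, int, float]]:
    """Reference cluster calls: overlap graph -> components -> filter -> join.

    Overlap is explicit and pairwise; joining is an exhaustive scan
    repeated to a fixed point.  Returns (contig, start, end, count).
    """
    lo, hi = read_lengths
    alns = [a for a in alignments if lo <= a.read_length <= hi]
    graph = nx.Graph()
    graph.add_nodes_from(range(len(alns)))
    for i in range(len(alns)):
        for j in range(i + 1, len(alns)):
            a, b = alns[i], alns[j]
            if a.contig == b.contig and a.start < b.end and b.start < a.end:
                graph.add_edge(i, j)
    regions = []
    for component in nx.connected_components(graph):
        members = [alns[i] for i in component]
        regions.append((
            members[0].contig,
            min(m.start for m in members),
            max(m.end for m in members),
            sum(1.0 / m.n_hits for m in members),
        ))
    retained = [r for r in regions if r[3] / denominator * 1e6 >= rpm_threshold]
    # exhaustive join to fixed point
    changed = True
    while changed:
        changed = False
        for i in range(len(retained)):
            for j in range(len(retained)):
                if i == j:
                    continue
                a, b = retained[i], retained[j]
                if a[0] != b[0]:
                    continue
                gap = max(a[1], b[1]) - min(a[2], b[2])
                if gap <= join_distance:
                    merged = (a[0], min(a[1], b[1]), max(a[2], b[2]), a[3] + b[3])
                    retained = [r for k, r in enumerate(retained) if k not in (i, j)]
                    retained.append(merged)
                    changed = True
                    break
            if changed:
                break
    return sorted(retained)


def jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union else 0.0
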