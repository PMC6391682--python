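"""Perfect-match placement of trimmed reads on a genome + plasmid reference.

The downstream siRNA analyses use only placements that match the
reference exactly, so the internal aligner is exact-match by design: it
reports *every* occurrence of a read on either strand of every contig
and records the total placement count ``n_hits``, the ``n`` of the
1/n fractional-counting rule.  Externally mapped data (e.g. colorspace
SOLiD libraries) enter through :func:`import_sam`, filtered to the same
perfect-match contract.

Coordinates are 0-based half-open throughout; converters handle the
1-based conventions of SAM and GFF3 at the boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam
from Bio import SeqIO

from ._util import check_alphabet, open_text, revcomp

#: Seed length of the exact-match index; reads shorter than this fall
#: back to a direct scan.  15 nt is the minimum retained insert length.
SEED_LENGTH = 15


@dataclass(frozen=True)
class Alignment:
    """One perfect-match placement of a read on the reference.

    ``n_hits`` is the total number of placements of the same read across
    the whole reference (both strands, all contigs) and is identical on
    every placement of that read.
    """

    read_id: str
    contig: str
    start: int
    end: int
    strand: str
    read_length: int
    n_hits: int

    @property
    def weight(self) -> float:
        """Fractional count contribution of this placement (1/n)."""
        return 1.0 / self.n_hits

    @property
    def five_prime(self) -> int:
        """0-based position of the read's biological 5' end."""
        return self.start if self.strand == "+" else self.end - 1


class ReferenceSet:
    """Genome contigs plus appended plasmid contigs with an exact-match index."""

    def __init__(self, contigs: Mapping[str, str], plasmids: Iterable[str] = ()):
        self.contigs: dict[str, str] = {}
        for name, seq in contigs.items():
            if name in self.contigs:
                raise ValueError(f"duplicate contig name: {name!r}")
            seq = seq.upper()
            check_alphabet(seq, context=f"contig {name!r}")
            self.contigs[name] = seq
        self.plasmids = frozenset(plasmids)
        missing = self.plasmids - set(self.contigs)
        if missing:
            raise ValueError(f"plasmid contigs absent from contig set: {sorted(missing)}")
        self._index: Optional[dict[str, list[tuple[str, int]]]] = None

    def is_plasmid(self, contig: str) -> bool:
        return contig in self.plasmids

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    @property
    def index(self) -> dict[str, list[tuple[str, int]]]:
        """Forward-strand seed index: k-mer -> [(contig, position), ...]."""
        if self._index is None:
            index: dict[str, list[tuple[str, int]]] = {}
            k = SEED_LENGTH
            for name, seq in self.contigs.items():
                for pos in range(len(seq) - k + 1):
                    index.setdefault(seq[pos : pos + k], []).append((name, pos))
            self._index = index
        return self._index


def build_reference(genome_fasta, plasmid_fastas: Sequence = ()) -> ReferenceSet:
    """Merge genome and plasmid FASTA files into one :class:`ReferenceSet`.

    Contig order is preserved (genome contigs in file order, then
    plasmids); duplicated contig names raise.
    """
    contigs: dict[str, str] = {}
    plasmids: list[str] = []

    def _load(path, is_plasmid: bool) -> None:
        with open_text(path) as handle:
            for rec in SeqIO.parse(handle, "fasta"):
                if rec.id in contigs:
                    raise ValueError(f"duplicate contig name {rec.id!r} in {path}")
                contigs[rec.id] = str(rec.seq).upper()
                if is_plasmid:
                    plasmids.append(rec.id)

    _load(genome_fasta, False)
    for path in plasmid_fastas:
        _load(path, True)
    return ReferenceSet(contigs, plasmids)


def _occurrences(ref: ReferenceSet, seq: str) -> list[tuple[str, int]]:
    """All forward-strand occurrences of ``seq`` in the reference."""
    k = SEED_LENGTH
    hits: list[tuple[str, int]] = []
    if len(seq) >= k:
        for contig, pos in ref.index.get(seq[:k], ()):  # verified seed extension
            if ref.contigs[contig][pos : pos + len(seq)] == seq:
                hits.append((contig, pos))
    else:
        for contig, text in ref.contigs.items():
            pos = text.find(seq)
            while pos != -1:
                hits.append((contig, pos))
                pos = text.find(seq, pos + 1)
    return hits


def align_exact(read, ref: ReferenceSet) -> list[Alignment]:
    """Every perfect-match placement of a read, both strands, all contigs.

    Reads containing ``N`` yield no placements.  ``n_hits`` equals the
    length of the returned list and is shared by all placements.
    """
    seq = read.sequence if hasattr(read, "sequence") else str(read)
    read_id = read.read_id if hasattr(read, "read_id") else ""
    if "N" in seq or not seq:
        return []
    placements: list[tuple[str, int, str]] = []
    for contig, pos in _occurrences(ref, seq):
        placements.append((contig, pos, "+"))
    rc = revcomp(seq)
    for contig, pos in _occurrences(ref, rc):
        placements.append((contig, pos, "-"))
    n = len(placements)
    return [
        Alignment(read_id, contig, pos, pos + len(seq), strand, len(seq), n)
        for contig, pos, strand in placements
    ]


def align_reads(reads: Iterable, ref: ReferenceSet) -> tuple[list[Alignment], int, int]:
    """Align a read stream; returns (alignments, n_mapped, n_total).

    Placement lookups are cached per distinct sequence, but every FASTQ
    record is counted separately (reads, not unique sequences, are the
    counting unit).
    """
    cache: dict[str, list[Alignment]] = {}
    alignments: list[Alignment] = []
    n_mapped = 0
    n_total = 0
    for read in reads:
        n_total += 1
        hits = cache.get(read.sequence)
        if hits is None:
            hits = align_exact(read, ref)
            cache[read.sequence] = hits
        if hits:
            n_mapped += 1
            if hits[0].read_id == read.read_id:
                alignments.extend(hits)
            else:
                alignments.extend(
                    Alignment(read.read_id, h.contig, h.start, h.end, h.strand,
                              h.read_length, h.n_hits)
                    for h in hits
                )
    return alignments, n_mapped, n_total


def align_library(reads: Iterable, ref: ReferenceSet, *, sample_id: str,
                  group: str = "", replicate: int = 1):
    """Align a trimmed library and assemble a :class:`~sirnaq.quantify.SmallRnaLibrary`.

    The normalization denominator is the number of distinct reads with at
    least one perfect-match placement on genome + plasmids (plasmid-only
    mappers count).
    """
    from .quantify import SmallRnaLibrary

    alignments, n_mapped, _ = align_reads(reads, ref)
    return SmallRnaLibrary(
        sample_id=sample_id,
        group=group,
        replicate=replicate,
        alignments=alignments,
        denominator=n_mapped,
    )


def _cigar_is_full_match(segment: pysam.AlignedSegment) -> bool:
    # perfect-match contract: a single M/=/X run, no indels, no clipping
    if segment.cigartuples is None:
        return False
    return all(op in (0, 7, 8) for op, _ in segment.cigartuples)


def _mismatches(segment: pysam.AlignedSegment) -> int:
    if segment.has_tag("NM"):
        return int(segment.get_tag("NM"))
    if segment.has_tag("MD"):
        md = str(segment.get_tag("MD"))
        return sum(1 for c in md if c in "ACGTN")
    raise ValueError(
        f"record {segment.query_name!r} lacks NM/MD tags needed to enforce the "
        "mismatch limit"
    )


def import_sam(sam_path, ref: ReferenceSet, max_mismatch: int = 0
               ) -> tuple[list[Alignment], dict[str, int]]:
    """Import externally mapped reads, keeping perfect matches only.

    Records with mismatches above ``max_mismatch``, indels, or clipping
    are skipped and tallied in the returned report.  ``n_hits`` is
    recomputed as the number of *retained* placements per read id.
    """
    report = {"n_records": 0, "n_retained": 0, "n_unmapped": 0,
              "n_clipped_or_indel": 0, "n_mismatch_filtered": 0}
    per_read: dict[str, list[Alignment]] = {}
    bad_contigs: set[str] = set()
    mode = "rb" if str(sam_path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(sam_path), mode, check_sq=False) as handle:
        for seg in handle:
            report["n_records"] += 1
            if seg.is_unmapped:
                report["n_unmapped"] += 1
                continue
            if seg.reference_name not in ref:
                bad_contigs.add(seg.reference_name)
                continue
            if not _cigar_is_full_match(seg):
                report["n_clipped_or_indel"] += 1
                continue
            if _mismatches(seg) > max_mismatch:
                report["n_mismatch_filtered"] += 1
                continue
            length = seg.reference_end - seg.reference_start
            aln = Alignment(
                read_id=seg.query_name,
                contig=seg.reference_name,
                start=seg.reference_start,
                end=seg.reference_end,
                strand="-" if seg.is_reverse else "+",
                read_length=length,
                n_hits=1,  # recomputed below
            )
            per_read.setdefault(seg.query_name, []).append(aln)
    if bad_contigs:
        raise ValueError(
            f"SAM records reference contigs absent from the reference set: "
            f"{sorted(bad_contigs)}"
        )
    alignments: list[Alignment] = []
    for read_id, hits in per_read.items():
        n = len(hits)
        for h in hits:
            alignments.append(Alignment(read_id, h.contig, h.start, h.end,
                                        h.strand, h.read_length, n))
    report["n_retained"] = len(alignments)
    return alignments, report


_TSV_COLUMNS = ["read_id", "contig", "start", "end", "strand", "length", "n_hits"]


def alignments_to_frame(alignments: Sequence[Alignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.read_id, a.contig, a.start, a.end, a.strand, a.read_length, a.n_hits)
         for a in alignments],
        columns=_TSV_COLUMNS,
    )


def write_alignments(alignments: Sequence[Alignment], path, *,
                     header_meta: Optional[Mapping[str, object]] = None) -> None:
    """Serialize alignments as TSV; metadata goes into '#key=value' lines."""
    with open_text(path, "wt") as out:
        if header_meta:
            for key, value in header_meta.items():
                out.write(f"#{key}={value}\n")
        frame = alignments_to_frame(alignments)
        frame.to_csv(out, sep="\t", index=False)


def read_alignments(path) -> tuple[list[Alignment], dict[str, str]]:
    meta: dict[str, str] = {}
    with open_text(path) as handle:
        pos = handle.tell()
        line = handle.readline()
        while line.startswith("#"):
            key, _, value = line[1:].rstrip("\n").partition("=")
            meta[key] = value
            pos = handle.tell()
            line = handle.readline()
        handle.seek(pos)
        frame = pd.read_csv(handle, sep="\t")
    alignments = [
        Alignment(str(r.read_id), str(r.contig), int(r.start), int(r.end),
                  str(r.strand), int(r.length), int(r.n_hits))
        for r in frame.itertuples(index=False)
    ]
    return alignments, meta
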