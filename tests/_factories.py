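"""Tiny constructors for hand-built alignment fixtures."""

from __future__ import annotations

from sirnaq import Alignment, SmallRnaLibrary


def aln(contig="chr1", start=100, length=22, strand="+", n_hits=1,
        read_id="r1") -> Alignment:
    return Alignment(read_id=read_id, contig=contig, start=start,
                     end=start + length, strand=strand, read_length=length,
                     n_hits=n_hits)


def lib(alignments, denominator=1_000_000, sample_id="S1", group="G",
        replicate=1) -> SmallRnaLibrary:
    return SmallRnaLibrary(sample_id=sample_id, group=group,
                           replicate=replicate, alignments=list(alignments),
                           denominator=denominator)
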