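"""Deterministic trimming of NEXTflex-style small-RNA reads.

NEXTflex small-RNA libraries carry a fixed 3' adapter and 4 randomized
bases on each side of the insert.  Trimming runs in two stages that must
be applied in order:

1. :func:`trim_adapter` — remove the 3' adapter by a leftmost-prefix
   match (full-length adapter matches tolerate one mismatch; shorter
   end-of-read matches of at least ``min_match_end`` nt must be exact).
2. :func:`force_trim` — remove the 4 randomized bases from each end and
   discard inserts shorter than ``min_length``.

:func:`trim_library` applies both stages to a FASTQ file and reports
conservation counts (input = retained + discarded).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

from ._util import check_alphabet, open_text

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass(frozen=True)
class TrimConfig:
    """Parameters of the two-round trimming procedure.

    Defaults reproduce the standard NEXTflex v3 protocol: 19-nt minimum
    full match with one tolerated mismatch, exact end matches down to
    8 nt, 4 forced bases off each end, 15-nt minimum insert.
    """

    adapter: str = DEFAULT_ADAPTER
    min_match_full: int = 19
    min_match_end: int = 8
    max_mismatch_full: int = 1
    force_trim_5p: int = 4
    force_trim_3p: int = 4
    min_length: int = 15

    def __post_init__(self) -> None:
        check_alphabet(self.adapter, context="adapter")
        if not (0 < self.min_match_end <= self.min_match_full <= len(self.adapter)):
            raise ValueError(
                "require 0 < min_match_end <= min_match_full <= len(adapter); "
                f"got {self.min_match_end}, {self.min_match_full}, {len(self.adapter)}"
            )
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.force_trim_5p < 0 or self.force_trim_3p < 0:
            raise ValueError("force-trim lengths must be >= 0")


@dataclass(frozen=True)
class Read:
    """A sequenced small-RNA record."""

    read_id: str
    sequence: str
    quality: Optional[str] = None

    def __len__(self) -> int:
        return len(self.sequence)


#: Sentinel returned when a read fails the minimum-length filter.
DISCARDED = None


@dataclass
class TrimReport:
    """Read-conservation bookkeeping for one trimmed library."""

    n_input: int = 0
    n_adapter_trimmed: int = 0
    n_discarded: int = 0

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_discarded


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def trim_adapter(read: Read, config: TrimConfig) -> Read:
    """Truncate ``read`` at the leftmost 3' adapter occurrence.

    Scans positions left to right; at position ``i`` the adapter prefix of
    length ``L = min(len(adapter), len(read) - i)`` is compared against the
    read.  A match is declared when ``L >= min_match_full`` with at most
    ``max_mismatch_full`` mismatches, or ``min_match_end <= L <
    min_match_full`` with zero mismatches.  Reads without a match are
    returned unchanged; this stage never discards.
    """
    check_alphabet(read.sequence, context=f"read {read.read_id!r}")
    seq = read.sequence
    adapter = config.adapter
    for i in range(len(seq)):
        L = min(len(adapter), len(seq) - i)
        if L < config.min_match_end:
            break
        mism = _hamming(seq[i : i + L], adapter[:L])
        if L >= config.min_match_full:
            if mism <= config.max_mismatch_full:
                return _truncate(read, i)
        elif mism == 0:
            return _truncate(read, i)
    return read


def _truncate(read: Read, end: int) -> Read:
    return dataclasses.replace(
        read,
        sequence=read.sequence[:end],
        quality=read.quality[:end] if read.quality is not None else None,
    )


def force_trim(read: Read, config: TrimConfig) -> Optional[Read]:
    """Remove the randomized end bases; discard short remnants.

    Returns ``None`` (:data:`DISCARDED`) when fewer than ``min_length``
    bases remain after removing ``force_trim_5p`` bases from the left and
    ``force_trim_3p`` from the right.
    """
    lo = config.force_trim_5p
    hi = len(read.sequence) - config.force_trim_3p
    if hi - lo < config.min_length:
        return DISCARDED
    return dataclasses.replace(
        read,
        sequence=read.sequence[lo:hi],
        quality=read.quality[lo:hi] if read.quality is not None else None,
    )


def trim_read(read: Read, config: TrimConfig, *, require_adapter: bool = False) -> Optional[Read]:
    """Full two-stage trim of one read; ``None`` when discarded."""
    trimmed = trim_adapter(read, config)
    if require_adapter and len(trimmed) == len(read):
        return DISCARDED
    return force_trim(trimmed, config)


def trim_reads(
    reads: Iterable[Read],
    config: TrimConfig,
    report: Optional[TrimReport] = None,
    *,
    require_adapter: bool = False,
) -> Iterator[Read]:
    """Lazily trim an in-memory read stream, filling ``report`` if given."""
    if report is None:
        report = TrimReport()
    for read in reads:
        report.n_input += 1
        trimmed = trim_adapter(read, config)
        adapter_found = len(trimmed) < len(read)
        if adapter_found:
            report.n_adapter_trimmed += 1
        if require_adapter and not adapter_found:
            report.n_discarded += 1
            continue
        final = force_trim(trimmed, config)
        if final is DISCARDED:
            report.n_discarded += 1
            continue
        yield final


def read_fastq(path) -> Iterator[Read]:
    """Iterate FASTQ records (plain or gzipped) as :class:`Read`."""
    with open_text(path) as handle:
        for i, rec in enumerate(SeqIO.parse(handle, "fastq")):
            seq = str(rec.seq).upper()
            try:
                check_alphabet(seq, context=f"FASTQ record {i} ({rec.id})")
            except ValueError as exc:
                raise IOError(str(exc)) from exc
            quals = rec.letter_annotations.get("phred_quality")
            quality = "".join(chr(q + 33) for q in quals) if quals else None
            yield Read(rec.id, seq, quality)


def write_fastq(reads: Iterable[Read], path) -> int:
    n = 0
    with open_text(path, "wt") as out:
        for read in reads:
            qual = read.quality if read.quality is not None else "I" * len(read)
            out.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")
            n += 1
    return n


def trim_library(
    fastq_in,
    config: TrimConfig,
    fastq_out=None,
    *,
    require_adapter: bool = False,
) -> tuple[list[Read], TrimReport]:
    """Trim a FASTQ library; optionally write the retained reads.

    Returns the retained reads and a :class:`TrimReport` satisfying
    ``n_input == n_retained + n_discarded``.
    """
    report = TrimReport()
    retained = list(
        trim_reads(read_fastq(fastq_in), config, report, require_adapter=require_adapter)
    )
    if fastq_out is not None:
        write_fastq(retained, fastq_out)
    return retained, report
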