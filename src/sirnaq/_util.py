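"""Small shared helpers (sequence alphabet, reverse complement, gzip-aware IO)."""

from __future__ import annotations

import gzip
from typing import IO

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase ACGTN sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def check_alphabet(seq: str, *, context: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"{context} is empty")
    bad = set(seq) - VALID_ALPHABET
    if bad:
        raise ValueError(f"{context} contains invalid characters: {sorted(bad)}")


def open_text(path, mode: str = "rt") -> IO[str]:
    """Open plain or gzip-compressed text transparently (by .gz suffix)."""
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)
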