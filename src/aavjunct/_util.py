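"""Small shared helpers: DNA alphabet, reverse complement, file openers."""

from __future__ import annotations

import gzip
import hashlib
from typing import IO

DNA_BASES = "ACGT"
VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, name: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"{name} is empty")
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"{name} contains non-ACGTN characters: {sorted(bad)!r}")


def open_text(path: str, mode: str = "rt") -> IO[str]:
    """Open a plain or gzip-compressed text file based on the suffix."""
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def file_md5(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
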