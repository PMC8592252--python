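"""Shared constants and small sequence/interval helpers."""

from __future__ import annotations

LIBRARIES: tuple[str, ...] = ("0h", "1h", "6h", "12h")
#: heat timepoints compared against the 0 h control
COMPARISONS: tuple[str, ...] = ("1h", "6h", "12h")

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-tolerant)."""
    return seq.translate(_RC)[::-1]


def intervals_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    """True iff two 0-based half-open intervals share >= 1 bp."""
    return a_start < b_end and b_start < a_end


def phred_mean(quality: str) -> float:
    """Mean Phred score of a Phred+33 quality string."""
    if not quality:
        raise ValueError("empty quality string")
    return sum(ord(c) - 33 for c in quality) / len(quality)
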