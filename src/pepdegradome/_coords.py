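"""Shared coordinate convention.

All peptide and topology spans in this package are 1-based, inclusive on
both ends — the convention proteomics tables print. Convert at the numpy
boundary with these two helpers and nowhere else.
"""

from __future__ import annotations


def to_zero_half_open(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive [start, end] -> 0-based half-open [s0, e0)."""
    return start - 1, end


def to_one_inclusive(s0: int, e0: int) -> tuple[int, int]:
    """0-based half-open [s0, e0) -> 1-based inclusive [start, end]."""
    return s0 + 1, e0


def span_length(start: int, end: int) -> int:
    return end - start + 1
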