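"""Genomic coordinate conventions.

All internal intervals are 1-based half-open ``[start, end)`` so that
``end - start`` is the interval length in bp.  VCF positions are 1-based
points; BED input/output is converted at the boundary (BED is 0-based
half-open, so a BED row ``(start0, end0)`` maps to ``[start0 + 1, end0 + 1)``).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def interval_length_bp(start: int, end: int) -> int:
    """Length of the 1-based half-open interval [start, end)."""
    if end <= start:
        raise ValueError("end must exceed start")
    return end - start


def round_kb(length_bp: int | float) -> int:
    """Round a bp length to the nearest kilobase (reporting convention)."""
    return int(round(length_bp / 1000.0))


def bed_to_point(start0: int) -> int:
    """First 1-based position covered by a BED row starting at ``start0``."""
    return start0 + 1
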