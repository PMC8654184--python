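"""Genomic intervals.

All coordinates in this package are 1-based and inclusive at both ends,
matching the ``CHR:START-END`` notation used for gene regions (e.g.
``19:49244073-49250166``). Any half-open arithmetic is internal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

_REGION_RE = re.compile(r"^([^:]+):([\d,]+)[-–]([\d,]+)$")


@dataclass(frozen=True)
class GenomicRegion:
    """A 1-based, inclusive genomic interval."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"region start {self.start} exceeds end {self.end}"
            )
        if self.start < 1:
            raise ValueError("coordinates are 1-based; start must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chromosome: str, position: int) -> bool:
        return chromosome == self.chromosome and self.start <= position <= self.end

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.end
            and other.start <= self.end
        )

    @classmethod
    def parse(cls, text: str) -> "GenomicRegion":
        """Parse ``CHR:START-END`` (commas in numbers and en-dashes accepted)."""
        m = _REGION_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse region string {text!r}")
        chrom, start, end = m.groups()
        return cls(chrom, int(start.replace(",", "")), int(end.replace(",", "")))

    def __str__(self) -> str:
        return f"{self.chromosome}:{self.start}-{self.end}"
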