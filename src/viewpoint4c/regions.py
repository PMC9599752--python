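"""Genomic interval primitives and UCSC-style coordinate parsing.

Coordinates are half-open ``[start, end)`` throughout the package, including
when parsing browser-style strings like ``chr3:131,019,746-131,020,624``:
the interval length is ``end - start`` (878 bp for that example, matching the
printed size of the element it denotes). Thousands separators (commas,
apostrophes, primes) and typographic dashes are accepted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

_COORD_JUNK = re.compile(r"[,\s'′ʹ]")
_RANGE_SEP = re.compile(r"[-–—−]")  # -, en/em dash, minus sign


@dataclass(frozen=True)
class Region:
    """A named genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("Region chromosome must be non-empty")
        if self.start < 0:
            raise ValueError(f"Region start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"Region must satisfy start < end, got {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlaps(self, other: "Region") -> bool:
        """True if the two intervals share >= 1 bp on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: float) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def with_name(self, name: str) -> "Region":
        return Region(self.chrom, self.start, self.end, name)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def parse_region(text: str, name: str | None = None) -> Region:
    """Parse a ``chrom:start-end`` string into a :class:`Region`.

    Accepts commas / apostrophes / prime marks as thousands separators and
    hyphen / en-dash / em-dash as the range separator. The two numbers are
    taken as a half-open interval.

    >>> parse_region("chr3:131,019,746–131,020,624").length
    878
    """
    if not isinstance(text, str) or ":" not in text:
        raise ValueError(f"cannot parse region string {text!r}: expected chrom:start-end")
    chrom, _, span = text.partition(":")
    chrom = chrom.strip()
    span = _COORD_JUNK.sub("", span)
    parts = _RANGE_SEP.split(span)
    if len(parts) != 2 or not parts[0] or not parts[1]:
        raise ValueError(f"cannot parse region string {text!r}: expected chrom:start-end")
    try:
        start, end = int(parts[0]), int(parts[1])
    except ValueError as exc:
        raise ValueError(f"cannot parse region string {text!r}: non-numeric coordinates") from exc
    return Region(chrom, start, end, name)


def as_region(value, name: str | None = None) -> Region:
    """Coerce a Region, string, or (chrom, start, end) tuple into a Region."""
    if isinstance(value, Region):
        return value if name is None else value.with_name(name)
    if isinstance(value, str):
        return parse_region(value, name)
    if isinstance(value, (tuple, list)) and len(value) in (3, 4):
        return Region(*value) if name is None else Region(*value[:3], name)
    raise TypeError(f"cannot interpret {value!r} as a Region")
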