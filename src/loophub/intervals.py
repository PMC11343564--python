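"""Core coordinate types: genomic intervals and chromatin loops.

All coordinates are 0-based, half-open (BED convention) throughout the
package; readers and writers never translate between conventions.
Chromosomes sort naturally (chr1 < chr2 < chr10).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional

_NAT_SPLIT = re.compile(r"(\d+)")

VALID_STRANDS = {"+", "-", "."}


def natural_chrom_key(chrom: str) -> tuple:
    """Sort key placing chr2 before chr10 (numeric runs compared as ints)."""
    parts = _NAT_SPLIT.split(chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)


@dataclass(frozen=True, order=False)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` on ``chrom``.

    Strand is carried for strand-aware window construction but ignored by
    every overlap operation.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of +, -, . — got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two spans share >= 1 bp (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def sort_key(self) -> tuple:
        return (natural_chrom_key(self.chrom), self.start, self.end)


@dataclass(frozen=True)
class Loop:
    """A binary chromatin interaction: two anchors plus PET support.

    Anchors are canonicalised so that ``(chromA, startA) <= (chromB, startB)``
    under natural chromosome order; construction through :meth:`make` enforces
    this and is idempotent.
    """

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    pet_count: int
    p_value: Optional[float] = None
    q_value: Optional[float] = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.pet_count < 0:
            raise ValueError("pet_count must be non-negative")
        for name, v in (("p_value", self.p_value), ("q_value", self.q_value)):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @classmethod
    def make(
        cls,
        anchor_a: GenomicInterval,
        anchor_b: GenomicInterval,
        pet_count: int,
        p_value: Optional[float] = None,
        q_value: Optional[float] = None,
        sample_id: str = "",
    ) -> "Loop":
        """Build a loop with anchors in canonical order."""
        ka = (natural_chrom_key(anchor_a.chrom), anchor_a.start, anchor_a.end)
        kb = (natural_chrom_key(anchor_b.chrom), anchor_b.start, anchor_b.end)
        if kb < ka:
            anchor_a, anchor_b = anchor_b, anchor_a
        return cls(anchor_a, anchor_b, pet_count, p_value, q_value, sample_id)

    @property
    def is_canonical(self) -> bool:
        ka = (natural_chrom_key(self.anchor_a.chrom), self.anchor_a.start, self.anchor_a.end)
        kb = (natural_chrom_key(self.anchor_b.chrom), self.anchor_b.start, self.anchor_b.end)
        return ka <= kb

    @property
    def span(self) -> Optional[int]:
        """Anchor-midpoint distance for intra-chromosomal loops, else None."""
        if self.anchor_a.chrom != self.anchor_b.chrom:
            return None
        return abs(self.anchor_b.midpoint - self.anchor_a.midpoint)

    def anchors(self) -> tuple[GenomicInterval, GenomicInterval]:
        return (self.anchor_a, self.anchor_b)
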