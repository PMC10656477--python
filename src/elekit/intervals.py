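"""Genomic interval primitives and overlap queries.

All coordinates in this package are 0-based, half-open ``[start, end)``;
conversion to/from 1-based inclusive happens only at GFF3 boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded half-open genomic interval.

    ``start`` is 0-based inclusive, ``end`` exclusive; ``end > start`` is
    enforced, so the minimum length is 1 bp.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = field(default="", compare=False)
    score: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (end <= start)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Half-open overlap: ``A.start < B.end and B.start < A.end``."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, position: int) -> bool:
        return self.start <= position < self.end

    def distance_to(self, other: "GenomicInterval") -> int:
        """Gap between two intervals on the same chrom; 0 if they overlap."""
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        if self.overlaps(other):
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end


def sort_key(iv: GenomicInterval) -> tuple:
    """Canonical output order: chrom lexical, start, end, strand."""
    return (iv.chrom, iv.start, iv.end, iv.strand)


class IntervalIndex:
    """Per-chromosome interval index supporting half-open overlap queries."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._items: list[GenomicInterval] = []
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        tree = self._trees.setdefault(iv.chrom, IntervalTree())
        tree.addi(iv.start, iv.end, len(self._items))
        self._items.append(iv)

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self):
        return iter(self._items)

    def overlapping(self, query: GenomicInterval) -> list[GenomicInterval]:
        """All indexed intervals overlapping ``query`` (any strand), sorted
        by (start, end) then insertion order for determinism."""
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        hits = [self._items[h.data] for h in tree.overlap(query.start, query.end)]
        hits.sort(key=lambda iv: (iv.start, iv.end, iv.strand, iv.name))
        return hits

    def at_point(self, chrom: str, position: int) -> list[GenomicInterval]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [self._items[h.data] for h in tree.at(position)]
        hits.sort(key=lambda iv: (iv.start, iv.end, iv.strand, iv.name))
        return hits


def overlap_query(
    query: GenomicInterval, subjects: IntervalIndex | Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Subset of ``subjects`` overlapping ``query`` under half-open semantics."""
    if not isinstance(subjects, IntervalIndex):
        subjects = IntervalIndex(subjects)
    return subjects.overlapping(query)
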