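"""Genomic interval primitives shared across the package.

All internal coordinates are 0-based half-open (BED convention). Printed
coordinates in the literature and in human-readable reports are 1-based
inclusive; :meth:`GenomicInterval.from_1based` / :meth:`GenomicInterval.to_1based`
convert at the boundary, and the two conventions round-trip exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome-anchored half-open interval ``[start, end)`` with strand.

    Parameters
    ----------
    chrom:
        Chromosome / sequence name (case-sensitive).
    start, end:
        0-based half-open coordinates, ``0 <= start < end``.
    strand:
        One of ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}; expected one of {VALID_STRANDS}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @classmethod
    def from_1based(cls, chrom: str, start1: int, end1: int, strand: str = ".") -> "GenomicInterval":
        """Build from 1-based inclusive coordinates (as printed in reports)."""
        return cls(chrom, start1 - 1, end1, strand)

    def to_1based(self) -> tuple[int, int]:
        """1-based inclusive (start, end) as used in human-readable output."""
        return self.start + 1, self.end

    def overlap(self, other: "GenomicInterval") -> int:
        return interval_overlap(self, other)

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)

    def __str__(self) -> str:  # human-readable -> 1-based inclusive
        s1, e1 = self.to_1based()
        return f"{self.chrom}:{s1}-{e1}({self.strand})"


def interval_overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap length in bp between two intervals; 0 on different chromosomes.

    Symmetric and never negative; half-open semantics, so touching
    intervals ([0,10) vs [10,20)) do not overlap.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class GeneModel:
    """A single-isoform gene model: gene span, coding exons and UTRs.

    Exons are the protein-coding exon intervals; UTR segments are kept
    separately (mirroring conservation-browser tracks that colour them
    apart from coding exons). Exons must lie within the gene span and be
    non-overlapping once sorted.
    """

    gene: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()
    utrs: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        exons = tuple(sorted(self.exons, key=lambda e: (e.start, e.end)))
        utrs = tuple(sorted(self.utrs, key=lambda u: (u.start, u.end)))
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "utrs", utrs)
        for part in exons + utrs:
            if not self.gene.contains(part):
                raise ValueError(f"feature {part} extends outside gene span {self.gene}")
        for prev, nxt in zip(exons, exons[1:]):
            if nxt.start < prev.end:
                raise ValueError(f"overlapping exons {prev} and {nxt}")

    @property
    def strand(self) -> str:
        return self.gene.strand

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt.start > prev.end:
                out.append(GenomicInterval(self.gene.chrom, prev.end, nxt.start, self.strand))
        return tuple(out)
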