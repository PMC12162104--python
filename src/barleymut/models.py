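"""In-memory records shared across the pipeline: variants, masks, gene models."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping

from intervaltree import Interval, IntervalTree


class Genotype(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def alt_dosage(self) -> int | None:
        """Non-reference allele count carried by a diploid genotype (None if missing)."""
        return {"hom_ref": 0, "het": 1, "hom_alt": 2, "missing": None}[self.value]


@dataclass
class SampleCall:
    """Per-sample genotype with the QC fields the hard filters consume."""

    gt: Genotype
    dp: int | None = None
    gq: int | None = None
    allele_balance: float | None = None  # alt-read fraction, het calls only


@dataclass
class Variant:
    """One called variant site.

    ``pos`` is 1-based (VCF convention); indel alleles are left-anchored, so
    the first base of ``ref`` and ``alt`` match for indels.  ``support_reads``
    is only populated for SV-caller output.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float | None = None
    calls: dict[str, SampleCall] = field(default_factory=dict)
    support_reads: int | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def length(self) -> int:
        """Signed length change (alt minus ref); 0 for SNVs."""
        return len(self.alt) - len(self.ref)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return not self.is_snv

    @property
    def vtype(self) -> str:
        if self.is_snv:
            return "SNV"
        return "insertion" if self.length > 0 else "deletion"

    def span(self) -> tuple[int, int]:
        """Reference footprint as a 0-based half-open interval."""
        return (self.pos - 1, self.pos - 1 + len(self.ref))


@dataclass
class RegionMask:
    """A labelled set of genomic intervals (0-based half-open, BED-style)."""

    label: str
    trees: dict[str, IntervalTree] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, label: str, intervals: Iterable[tuple[str, int, int]]) -> "RegionMask":
        mask = cls(label)
        for chrom, start, end in intervals:
            mask.add(chrom, start, end)
        mask.normalize()
        return mask

    def add(self, chrom: str, start: int, end: int) -> None:
        if not 0 <= start < end:
            raise ValueError(f"bad interval [{start}, {end}) on {chrom}")
        self.trees.setdefault(chrom, IntervalTree()).add(Interval(start, end))

    def normalize(self) -> None:
        """Merge overlapping/adjacent intervals within each chromosome."""
        for tree in self.trees.values():
            tree.merge_overlaps(strict=False)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self.trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a single 0-based position."""
        return self.overlaps(chrom, pos0, pos0 + 1)

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self.trees):
            for iv in sorted(self.trees[chrom]):
                out.append((chrom, iv.begin, iv.end))
        return out

    def total_bp(self) -> int:
        return sum(end - start for _, start, end in self.intervals())


@dataclass
class GeneModel:
    """A protein-coding gene model with explicit CDS intervals.

    ``cds`` holds 1-based inclusive (start, end) intervals in genomic order;
    for minus-strand genes translation proceeds from the last interval's end.
    Single-transcript models only, which is all the consequence classifier
    needs.
    """

    gene_id: str
    chrom: str
    start: int  # 1-based inclusive gene span
    end: int
    strand: str  # '+' or '-'
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.cds = sorted(self.cds)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def introns(self) -> list[tuple[int, int]]:
        """1-based inclusive intervals between consecutive CDS segments."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.cds, self.cds[1:]):
            out.append((e1 + 1, s2 - 1))
        return out
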