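"""Genomic-interval and structural-variant primitives.

Everything positional in the pipeline is expressed in 0-based half-open
coordinates; VCF's 1-based inclusive POS/END are converted at the I/O
boundary.  The three measures defined here — SV length, reciprocal overlap
and breakpoint distance — are the entire geometric vocabulary used by
stitching, consensus clustering, depth validation and database matching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "SV_TYPES",
    "GenomicInterval",
    "Genotype",
    "SVCall",
    "sv_length",
    "reciprocal_overlap",
    "breakpoint_distance",
    "ins_window",
]

#: Recognized SV type labels.  BND covers unresolved breakends and
#: inter-chromosomal translocations.
SV_TYPES = ("DEL", "DUP", "INS", "INV", "CNV", "BND")


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end < self.start:
            raise ValidationError(
                f"end ({self.end}) must be >= start ({self.start})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Length in bp of the intersection with *other* (0 if disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        """True when *other* lies entirely within this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class Genotype:
    """Diploid genotype as allele counts.

    ``ref_alleles + alt_alleles == ploidy`` unless the genotype is missing.
    """

    ref_alleles: int = 0
    alt_alleles: int = 0
    missing: bool = False
    ploidy: int = 2

    def __post_init__(self) -> None:
        if self.missing:
            return
        if self.ref_alleles < 0 or self.alt_alleles < 0:
            raise ValidationError("allele counts must be non-negative")
        if self.ref_alleles + self.alt_alleles != self.ploidy:
            raise ValidationError(
                f"allele counts {self.ref_alleles}+{self.alt_alleles} "
                f"!= ploidy {self.ploidy}"
            )

    @property
    def dosage(self) -> int | None:
        """Alt-allele dosage (0/1/2), or None when missing."""
        return None if self.missing else self.alt_alleles

    @classmethod
    def from_dosage(cls, dosage: int | None, ploidy: int = 2) -> "Genotype":
        if dosage is None:
            return cls(missing=True, ploidy=ploidy)
        return cls(ref_alleles=ploidy - dosage, alt_alleles=dosage, ploidy=ploidy)


MISSING_GT = Genotype(missing=True)
HOM_REF = Genotype(ref_alleles=2, alt_alleles=0)


@dataclass(frozen=True)
class SVCall:
    """One caller's structural-variant call in one sample.

    For DEL/DUP/INV/CNV the interval spans the affected region and
    ``svlen == end - start``.  Insertions are anchored at a single base
    (``end == start + 1``) and carry the inserted length in ``svlen``.
    """

    interval: GenomicInterval
    svtype: str
    svlen: int
    sample_id: str
    caller_id: str
    quality: float = 0.0
    filter_status: str = "PASS"
    genotype: Genotype = field(default_factory=lambda: Genotype(1, 1))
    record_id: str | None = None
    mate_id: str | None = None
    bnd_orientation: str | None = None  # '+' or '-' for breakends
    mate_chrom: str | None = None
    mate_pos: int | None = None
    tools: tuple[str, ...] | None = None  # set on consensus calls

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValidationError(f"unknown svtype {self.svtype!r}")
        if self.svlen <= 0:
            raise ValidationError(f"svlen must be positive, got {self.svlen}")
        if self.svtype == "INS":
            if len(self.interval) != 1:
                raise ValidationError("INS calls must be point-anchored")
        elif self.svtype != "BND":
            if self.svlen != len(self.interval):
                raise ValidationError(
                    f"{self.svtype} svlen {self.svlen} != interval span "
                    f"{len(self.interval)}"
                )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    def with_(self, **kwargs) -> "SVCall":
        return replace(self, **kwargs)


def sv_length(call: SVCall) -> int:
    """Length of a call in bp: inserted length for INS, span otherwise."""
    if call.svtype == "INS":
        return call.svlen
    return call.interval.end - call.interval.start


def ins_window(call: SVCall) -> GenomicInterval:
    """Padded comparison window for an insertion call.

    A point anchor has no extent, so insertions enter overlap-based
    comparisons through a symmetric window of their inserted length
    centred on the anchor (clipped at the chromosome origin).
    """
    anchor = call.interval.start
    half = call.svlen // 2
    start = max(0, anchor - half)
    return GenomicInterval(call.interval.chrom, start, start + call.svlen)


def _extent(call: SVCall) -> GenomicInterval:
    return ins_window(call) if call.svtype == "INS" else call.interval


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(o/|a|, o/|b|) where o is the overlap in bp; 0 across chromosomes."""
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("reciprocal overlap undefined for zero-length intervals")
    o = a.overlap_bp(b)
    if o == 0:
        return 0.0
    return min(o / len(a), o / len(b))


def call_reciprocal_overlap(a: SVCall, b: SVCall) -> float:
    """Reciprocal overlap between two calls, with INS via padded windows."""
    return reciprocal_overlap(_extent(a), _extent(b))


def breakpoint_distance(a: SVCall, b: SVCall) -> float:
    """max(|Δstart|, |Δend|) in bp; +inf across chromosomes."""
    if a.chrom != b.chrom:
        return math.inf
    return max(abs(a.start - b.start), abs(a.end - b.end))
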