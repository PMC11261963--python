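"""Population summaries over a merged callset.

Allele frequencies are non-reference allele frequencies computed from
genotypes (alt alleles / called alleles); spectra use left-open
right-closed bins, so an AF of exactly 1% falls in the (0–1%] bin.
Monomorphic variants (AF 0) and variants with no called genotype are
excluded from the AF spectrum with a logged count.  Summary statistics
over per-sample counts use the population (n) standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .core import ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "SpectrumBins",
    "AF_EDGES",
    "LENGTH_EDGES",
    "allele_frequency",
    "carrier_frequency",
    "is_singleton",
    "af_spectrum",
    "length_spectrum",
    "type_percentages",
    "per_sample_counts",
    "genotype_matrix",
]

#: Allele-frequency bin edges: (0–1%], (1–2%], (2–5%], (5–10%], then
#: decile bins up to (90–100%].
AF_EDGES = (0.0, 0.01, 0.02, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50,
            0.60, 0.70, 0.80, 0.90, 1.0)

#: Length bin edges in bp: (0–250], (250–500], (500–1000], (1000–2000],
#: (2000–5000], (5000–10000].
LENGTH_EDGES = (0, 250, 500, 1000, 2000, 5000, 10000)


@dataclass
class SpectrumBins:
    """Histogram with left-open right-closed bins."""

    edges: tuple[float, ...]
    counts: tuple[int, ...]
    n_excluded: int = 0

    def __post_init__(self) -> None:
        edges = tuple(self.edges)
        if list(edges) != sorted(set(edges)):
            raise ValidationError("edges must be strictly increasing")
        if len(self.counts) != len(edges) - 1:
            raise ValidationError("need len(edges)-1 counts")
        if any(c < 0 for c in self.counts):
            raise ValidationError("counts must be non-negative")
        self.edges = edges
        self.counts = tuple(int(c) for c in self.counts)

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    @classmethod
    def from_values(cls, values, edges) -> "SpectrumBins":
        edges = tuple(edges)
        counts = [0] * (len(edges) - 1)
        n_excluded = 0
        for v in values:
            if v <= edges[0] or v > edges[-1]:
                n_excluded += 1
                continue
            # left-open right-closed: bin i holds edges[i] < v <= edges[i+1]
            i = int(np.searchsorted(edges, v, side="left")) - 1
            counts[i] += 1
        return cls(edges, tuple(counts), n_excluded)

    def _edge_index(self, edge) -> int:
        try:
            return self.edges.index(edge)
        except ValueError:
            raise ValidationError(
                f"{edge} is not a bin boundary of {self.edges}"
            ) from None

    def fraction_above(self, edge) -> float:
        """Share of binned values strictly above *edge* (a bin boundary)."""
        i = self._edge_index(edge)
        return sum(self.counts[i:]) / self.total

    def fraction_at_most(self, edge) -> float:
        """Share of binned values at most *edge* (a bin boundary)."""
        return 1.0 - self.fraction_above(edge)

    def to_frame(self) -> pd.DataFrame:
        labels = [
            f"({lo:g}–{hi:g}]"
            for lo, hi in zip(self.edges[:-1], self.edges[1:])
        ]
        return pd.DataFrame({"range": labels, "count": self.counts})


def _allele_counts(variant) -> tuple[int, int]:
    """(alt alleles, called alleles) over non-missing genotypes."""
    alt = called = 0
    for g in variant.genotypes.values():
        if g.missing:
            continue
        alt += g.alt_alleles
        called += g.ploidy
    return alt, called


def allele_frequency(variant) -> float:
    """Non-reference allele frequency; raises when no genotype is called."""
    alt, called = _allele_counts(variant)
    if called == 0:
        raise ValidationError(
            f"allele frequency undefined for {variant.id}: all genotypes missing"
        )
    return alt / called


def is_singleton(variant) -> bool:
    """True when exactly one non-reference allele is observed."""
    alt, _ = _allele_counts(variant)
    return alt == 1


def carrier_frequency(variant) -> float:
    """Fraction of called samples carrying >= 1 alt allele.

    Alternative to the allele-frequency definition; note it can never
    distinguish het from hom-alt carriers.
    """
    carriers = called = 0
    for g in variant.genotypes.values():
        if g.missing:
            continue
        called += 1
        if g.alt_alleles > 0:
            carriers += 1
    if called == 0:
        raise ValidationError(
            f"carrier frequency undefined for {variant.id}: all genotypes missing"
        )
    return carriers / called


def af_spectrum(popset, edges=AF_EDGES, carrier: bool = False) -> SpectrumBins:
    """Frequency spectrum; uncallable variants are excluded, logged.

    *carrier=True* bins carrier frequencies instead of allele frequencies.
    """
    freq = carrier_frequency if carrier else allele_frequency
    values = []
    n_uncallable = 0
    for v in popset.variants:
        try:
            values.append(freq(v))
        except ValidationError:
            n_uncallable += 1
    if n_uncallable:
        log.info("af_spectrum: %d variants with no called genotype excluded",
                 n_uncallable)
    bins = SpectrumBins.from_values(values, edges)
    bins.n_excluded += n_uncallable
    return bins


def length_spectrum(popset, edges=LENGTH_EDGES) -> SpectrumBins:
    """Length spectrum over merged variants (INS: inserted length)."""
    return SpectrumBins.from_values(
        (v.svlen for v in popset.variants), edges
    )


def _round_half_up(x: float, decimals: int = 0) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def type_percentages(type_counts: dict[str, int]) -> dict[str, int]:
    """Per-type integer percentages (round half-up) of the total."""
    total = sum(type_counts.values())
    if total <= 0:
        raise ValidationError("type_percentages needs a positive total")
    if any(c < 0 for c in type_counts.values()):
        raise ValidationError("counts must be non-negative")
    return {
        t: int(_round_half_up(100 * c / total))
        for t, c in type_counts.items()
    }


def per_sample_counts(popset):
    """Variant count per sample plus mean/sd/range summary.

    A sample's count is the number of variants where it carries at least
    one alt allele.  Returns ``(counts, summary)`` with *counts* a pandas
    Series indexed by sample and *summary* a dict of mean, sd
    (population-n), min and max.
    """
    counts = {s: 0 for s in popset.sample_ids}
    for v in popset.variants:
        for s, g in v.genotypes.items():
            if not g.missing and g.alt_alleles > 0:
                counts[s] += 1
    series = pd.Series(counts, name="n_variants")
    arr = series.to_numpy(dtype=float)
    summary = {
        "mean": float(arr.mean()) if len(arr) else float("nan"),
        "sd": float(arr.std(ddof=0)) if len(arr) else float("nan"),
        "min": int(arr.min()) if len(arr) else 0,
        "max": int(arr.max()) if len(arr) else 0,
    }
    return series, summary


def genotype_matrix(popset) -> pd.DataFrame:
    """Samples x variants alt-dosage matrix (NaN marks missing calls)."""
    data = np.full((len(popset.sample_ids), len(popset.variants)), np.nan)
    for j, v in enumerate(popset.variants):
        for i, s in enumerate(popset.sample_ids):
            g = v.genotypes[s]
            if not g.missing:
                data[i, j] = g.alt_alleles
    return pd.DataFrame(
        data,
        index=list(popset.sample_ids),
        columns=[v.id for v in popset.variants],
    )
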