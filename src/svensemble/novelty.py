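"""Known/novel classification against a DGV-style reference database.

A merged variant is *known* at reciprocal-overlap threshold t when some
database record matches it with reciprocal overlap >= t, and *novel*
otherwise.  The conventional thresholds are 70/90/95%: the novel set can
only grow as t rises.  Type is ignored by default (reference-database
type vocabularies are inconsistent); a type-aware mode restricts matches
to compatible types, with CNV acting as a wildcard among {DEL, DUP, CNV}.
Translocation breakends have no meaningful length and are excluded from
the comparison, counted separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd
from intervaltree import IntervalTree

from .core import GenomicInterval, ValidationError, reciprocal_overlap
from .io import DGVRecord

__all__ = [
    "NoveltyResult",
    "DGVIndex",
    "match_database",
    "novelty_report",
    "novel_percentage",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = (0.70, 0.90, 0.95)


@dataclass
class NoveltyResult:
    variant_id: str
    best_match_accession: str | None
    best_ro: float
    novel_at: dict[float, bool]


class DGVIndex:
    """Chromosome-indexed interval lookup over database records."""

    def __init__(self, records: list[DGVRecord]):
        self.records = list(records)
        self._trees: dict[str, IntervalTree] = {}
        for rec in self.records:
            if len(rec.interval) == 0:
                continue
            self._trees.setdefault(rec.interval.chrom, IntervalTree()).addi(
                rec.interval.start, rec.interval.end, rec
            )

    def overlapping(self, interval: GenomicInterval) -> list[DGVRecord]:
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        return [h.data for h in tree.overlap(interval.start, interval.end)]


def _variant_extent(variant) -> GenomicInterval:
    """Comparison extent; insertions use a padded window of their length."""
    if variant.svtype == "INS":
        anchor = variant.interval.start
        half = variant.svlen // 2
        start = max(0, anchor - half)
        return GenomicInterval(variant.interval.chrom, start,
                               start + variant.svlen)
    return variant.interval


def _types_compatible(a: str, b: str) -> bool:
    if a == b:
        return True
    return "CNV" in (a, b) and {a, b} <= {"DEL", "DUP", "CNV"}


def match_database(
    variant,
    db: DGVIndex,
    t: float = 0.70,
    match_type: bool = False,
) -> NoveltyResult:
    """Best database match for one variant at threshold *t*.

    Returns the record maximizing reciprocal overlap (ties broken by
    accession order); the variant is novel at *t* iff the best reciprocal
    overlap is below *t*.
    """
    extent = _variant_extent(variant)
    best_acc, best_ro = None, 0.0
    for rec in sorted(db.overlapping(extent), key=lambda r: r.accession):
        if match_type and not _types_compatible(variant.svtype,
                                                rec.variant_type):
            continue
        ro = reciprocal_overlap(extent, rec.interval)
        if ro > best_ro:
            best_acc, best_ro = rec.accession, ro
    return NoveltyResult(
        variant_id=variant.id,
        best_match_accession=best_acc,
        best_ro=best_ro,
        novel_at={t: best_ro < t},
    )


def novelty_report(
    popset,
    db: list[DGVRecord] | DGVIndex,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    match_type: bool = False,
):
    """Novel counts per threshold plus a per-variant table.

    Returns ``(counts, table, n_translocations)`` where *counts* maps each
    threshold to its novel count (non-decreasing in t) and *table* is a
    per-variant DataFrame of best match, best reciprocal overlap and
    novelty flags.
    """
    thresholds = tuple(thresholds)
    if any(not 0 < t <= 1 for t in thresholds):
        raise ValidationError(f"thresholds must lie in (0,1]: {thresholds}")
    if list(thresholds) != sorted(thresholds):
        raise ValidationError("thresholds must be sorted ascending")
    index = db if isinstance(db, DGVIndex) else DGVIndex(db)

    rows = []
    n_tra = 0
    for v in popset.variants:
        if v.svtype == "BND":
            n_tra += 1
            continue
        res = match_database(v, index, t=thresholds[0], match_type=match_type)
        row = {
            "variant_id": v.id,
            "svtype": v.svtype,
            "best_match": res.best_match_accession,
            "best_ro": res.best_ro,
        }
        for t in thresholds:
            row[f"novel_at_{t:g}"] = res.best_ro < t
        rows.append(row)

    table = pd.DataFrame(
        rows,
        columns=["variant_id", "svtype", "best_match", "best_ro"]
        + [f"novel_at_{t:g}" for t in thresholds],
    )
    counts = {
        t: int(table[f"novel_at_{t:g}"].sum()) if len(table) else 0
        for t in thresholds
    }
    return counts, table, n_tra


def novel_percentage(n_novel: int, n_total: int) -> float:
    """100 * n_novel / n_total, rounded half-up to one decimal place."""
    if n_total <= 0:
        raise ValidationError("n_total must be positive")
    if not 0 <= n_novel <= n_total:
        raise ValidationError("n_novel must lie in [0, n_total]")
    pct = Decimal(100 * n_novel) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
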