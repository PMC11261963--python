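"""Validation of long calls (>10 kb) against a read-depth caller.

Split-read and paired-end callers produce implausible lengths above
~10 kb, so long calls are accepted only when a depth-based CNV call of
concordant copy state covers at least 90% of the call.  Depth callers
operate at a fixed window resolution (1,000 bp here) with boundaries
snapped to window multiples, so the fraction is anchored on the SV call
(overlap / call length) rather than reciprocal: window quantization of a
>=10 kb call costs at most 2 windows, i.e. <= 20% of the coarse call but
well under 10% of the SV call itself.  Analysis of validated regions is
capped below 200 kb; longer calls would implicate implausibly many genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .core import GenomicInterval, SVCall, ValidationError
from .io import GeneModel, write_regions

log = logging.getLogger(__name__)

__all__ = [
    "DepthCall",
    "validate_long_call",
    "long_region_report",
    "genes_fully_covered",
    "LongRegionReport",
    "DEPTH_WINDOW",
    "LONG_SV_CUTOFF",
    "MAX_ANALYSIS_LENGTH",
]

DEPTH_WINDOW = 1_000
LONG_SV_CUTOFF = 10_000
MAX_ANALYSIS_LENGTH = 200_000

#: SV types corroborated by each depth copy-state.
_CONCORDANT = {"loss": {"DEL", "CNV"}, "gain": {"DUP", "CNV"}}


@dataclass(frozen=True)
class DepthCall:
    """A depth-caller CNV call at window resolution."""

    interval: GenomicInterval
    copy_state: str  # 'loss' or 'gain'
    sample_id: str
    window: int = DEPTH_WINDOW

    def __post_init__(self) -> None:
        if self.copy_state not in ("loss", "gain"):
            raise ValidationError(f"copy_state {self.copy_state!r}")
        if len(self.interval) == 0:
            raise ValidationError("empty depth call")
        if self.interval.start % self.window or self.interval.end % self.window:
            raise ValidationError(
                f"depth call {self.interval} not aligned to {self.window} bp windows"
            )


def validate_long_call(
    call: SVCall,
    depth_calls: list[DepthCall],
    min_frac: float = 0.9,
    require_state: bool = True,
    reciprocal: bool = False,
) -> bool:
    """True when a single depth call corroborates >= min_frac of the call.

    The fraction is overlap / call length by default (*reciprocal=True*
    additionally requires overlap / depth-call length).  Copy-state
    concordance (DEL with loss, DUP with gain) is required unless
    *require_state* is False.  Only depth calls from the call's own
    sample count.
    """
    call_len = len(call.interval)
    if call_len == 0:
        return False
    best = 0.0
    for dc in depth_calls:
        if dc.sample_id != call.sample_id:
            continue
        if require_state and call.svtype not in _CONCORDANT[dc.copy_state]:
            continue
        o = call.interval.overlap_bp(dc.interval)
        frac = o / call_len
        if reciprocal:
            frac = min(frac, o / len(dc.interval))
        best = max(best, frac)
    return best >= min_frac


@dataclass
class LongRegionReport:
    """Depth-validated long-SV regions below the analysis length cap."""

    regions: list[SVCall]
    per_chrom: dict[str, int]
    n_excluded_by_length: int
    all_calls: list[SVCall] = field(default_factory=list)


def long_region_report(
    validated_calls: list[SVCall],
    max_len: int = MAX_ANALYSIS_LENGTH,
    bed_path=None,
    all_bed_path=None,
) -> LongRegionReport:
    """Report validated long calls shorter than *max_len* (exclusive).

    Calls at or above the cap are excluded from the report but still
    written to the all-calls BED when *all_bed_path* is given.
    """
    kept = [c for c in validated_calls if len(c.interval) < max_len]
    kept.sort(key=lambda c: (c.chrom, c.start, c.end))
    per_chrom: dict[str, int] = {}
    for c in kept:
        per_chrom[c.chrom] = per_chrom.get(c.chrom, 0) + 1
    n_excluded = len(validated_calls) - len(kept)
    if n_excluded:
        log.info("long_region_report: %d calls >= %d bp excluded from analysis",
                 n_excluded, max_len)
    if bed_path is not None:
        write_regions([c.interval for c in kept], bed_path)
    if all_bed_path is not None:
        write_regions(
            sorted((c.interval for c in validated_calls)), all_bed_path
        )
    return LongRegionReport(kept, per_chrom, n_excluded, list(validated_calls))


def genes_fully_covered(
    regions,
    genemodel: GeneModel,
    exclude_chroms: tuple[str, ...] = (),
) -> list[str]:
    """Genes whose full span lies within some region.

    *regions* may be calls or bare intervals; chromosomes listed in
    *exclude_chroms* (e.g. the X, where depth methods misbehave) are
    skipped.
    """
    covered: set[str] = set()
    for r in regions:
        iv = r if isinstance(r, GenomicInterval) else r.interval
        if iv.chrom in exclude_chroms:
            continue
        for g in genemodel.genes_contained_in(iv):
            covered.add(g.gene_id)
    return sorted(covered)
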