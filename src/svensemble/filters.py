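"""Deterministic post-merge exclusions.

Per-type length caps remove implausibly long calls (insertions > 1 kb,
deletions > 10 kb, inversions and duplications > 20 kb by default — long
calls from split-read callers are dominated by artefacts and are handled
by the depth-validation path instead).  Blacklist exclusion drops
variants touching catalogued problematic regions.  The 10 kb split
separates the s-of-k consensus class from the depth-validated class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from intervaltree import IntervalTree

from .core import GenomicInterval, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "LengthCaps",
    "apply_length_caps",
    "exclude_blacklist",
    "split_by_length_class",
    "DEFAULT_LENGTH_CLASS_CUTOFF",
]

DEFAULT_LENGTH_CLASS_CUTOFF = 10_000


@dataclass(frozen=True)
class LengthCaps:
    """Per-type maximum lengths; lengths strictly greater are removed."""

    ins_max: int = 1_000
    del_max: int = 10_000
    inv_max: int = 20_000
    dup_max: int = 20_000

    def __post_init__(self) -> None:
        for f in ("ins_max", "del_max", "inv_max", "dup_max"):
            if getattr(self, f) <= 0:
                raise ValidationError(f"{f} must be positive")

    def cap_for(self, svtype: str) -> int | None:
        return {
            "INS": self.ins_max,
            "DEL": self.del_max,
            "INV": self.inv_max,
            "DUP": self.dup_max,
        }.get(svtype)


def _length(item) -> int:
    """Comparison length of a call or merged variant (INS: inserted bp)."""
    return item.svlen if item.svtype == "INS" else item.end - item.start


def apply_length_caps(items, caps: LengthCaps | None = None,
                      report: dict | None = None):
    """Remove items whose length strictly exceeds their per-type cap.

    Boundary values are retained (a 10,000 bp deletion survives a
    10,000 bp cap).  Types without a cap (CNV, BND) are retained with a
    warning the first time one is seen.  Idempotent.
    """
    caps = caps or LengthCaps()
    kept, removed_by_type = [], {}
    warned: set[str] = set()
    for item in items:
        cap = caps.cap_for(item.svtype)
        if cap is None:
            if item.svtype not in warned and item.svtype not in ("CNV", "BND"):
                log.warning("apply_length_caps: no cap for type %s, retaining",
                            item.svtype)
                warned.add(item.svtype)
            kept.append(item)
        elif _length(item) > cap:
            removed_by_type[item.svtype] = removed_by_type.get(item.svtype, 0) + 1
        else:
            kept.append(item)
    if removed_by_type:
        log.info("apply_length_caps: removed %s", removed_by_type)
    if report is not None:
        report["length_cap_removed"] = removed_by_type
    return kept


def exclude_blacklist(items, blacklist: list[GenomicInterval],
                      min_overlap: int = 1, report: dict | None = None):
    """Remove items overlapping any blacklist interval by >= min_overlap bp."""
    trees: dict[str, IntervalTree] = {}
    for iv in blacklist:
        if len(iv) == 0:
            continue
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    kept, n_removed = [], 0
    for item in items:
        tree = trees.get(item.interval.chrom)
        removed = False
        if tree is not None:
            for hit in tree.overlap(item.start, item.end):
                o = min(hit.end, item.end) - max(hit.begin, item.start)
                if o >= min_overlap:
                    removed = True
                    break
        if removed:
            n_removed += 1
        else:
            kept.append(item)
    if n_removed:
        log.info("exclude_blacklist: removed %d items", n_removed)
    if report is not None:
        report["blacklist_removed"] = n_removed
    return kept


def split_by_length_class(items, cutoff: int = DEFAULT_LENGTH_CLASS_CUTOFF):
    """Partition items into (length <= cutoff, length > cutoff)."""
    short = [i for i in items if _length(i) <= cutoff]
    long_ = [i for i in items if _length(i) > cutoff]
    return short, long_
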