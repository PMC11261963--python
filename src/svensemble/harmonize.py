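"""Per-caller normalization before consensus merging.

Three steps bring heterogeneous caller outputs onto a common footing:

1. ``quality_filter`` keeps only records that passed the caller's own
   quality control.
2. ``resolve_bnd_pairs`` converts same-chromosome breakend mate pairs to
   the simple types they encode (orientation ``+-`` is a deletion,
   ``-+`` a tandem duplication, ``++``/``--`` an inversion);
   inter-chromosomal pairs are retained as translocation breakends.
3. ``stitch`` collapses near-duplicate re-genotyped calls of the same
   underlying variant within one sample, keeping the highest-quality
   record of each cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .core import (
    GenomicInterval,
    SVCall,
    breakpoint_distance,
    call_reciprocal_overlap,
)
from .io import CallSet

__all__ = [
    "quality_filter",
    "resolve_bnd_pairs",
    "stitch",
    "BndMatePair",
    "DEFAULT_PASS_LABELS",
]

log = logging.getLogger(__name__)

#: Filter labels accepted as "passed quality control".  ``.`` covers
#: dialects that leave FILTER unset on good records.
DEFAULT_PASS_LABELS = frozenset({"PASS", "."})


@dataclass(frozen=True)
class BndMatePair:
    """A pair of mated breakend records with their joint orientation."""

    mate_a: SVCall
    mate_b: SVCall
    orientation: str  # one of '+-', '-+', '++', '--'


def quality_filter(
    cs: CallSet,
    pass_labels: frozenset[str] = DEFAULT_PASS_LABELS,
    report: dict | None = None,
) -> CallSet:
    """Retain only calls whose FILTER status is a pass label."""
    kept, removed_by_label = [], {}
    for c in cs:
        if c.filter_status in pass_labels:
            kept.append(c)
        else:
            removed_by_label[c.filter_status] = (
                removed_by_label.get(c.filter_status, 0) + 1
            )
    if removed_by_label:
        log.info("quality_filter[%s]: removed %s", cs.caller_id, removed_by_label)
    if report is not None:
        report["quality_filter_removed"] = removed_by_label
    return cs.replace_calls(kept, quality_filtered=True)


def _pair_orientation(left: SVCall, right: SVCall) -> str | None:
    if left.bnd_orientation is None or right.bnd_orientation is None:
        return None
    return left.bnd_orientation + right.bnd_orientation


_ORIENT_TO_TYPE = {"+-": "DEL", "-+": "DUP", "++": "INV", "--": "INV"}


def resolve_bnd_pairs(cs: CallSet, report: dict | None = None) -> CallSet:
    """Resolve breakend mate pairs into simple SV types.

    Evidence is conserved: every input BND is accounted for as half of a
    converted call, half of a retained translocation, half of an
    inconsistent (dropped) pair, or an unpaired (dropped) singleton.
    """
    non_bnd = [c for c in cs if c.svtype != "BND"]
    bnds = [c for c in cs if c.svtype == "BND"]

    by_key: dict[tuple[str, str], SVCall] = {}
    for c in bnds:
        if c.record_id is not None:
            by_key[(c.sample_id, c.record_id)] = c

    out = list(non_bnd)
    seen: set[tuple[str, str]] = set()
    n_converted = n_translocation = n_unpaired = n_inconsistent = 0

    for c in sorted(bnds, key=lambda x: (x.sample_id, x.chrom, x.start,
                                         x.record_id or "")):
        key = (c.sample_id, c.record_id or "")
        if key in seen:
            continue
        mate = by_key.get((c.sample_id, c.mate_id)) if c.mate_id else None
        if mate is None or mate is c:
            n_unpaired += 1
            seen.add(key)
            continue
        # mates must reference each other
        if mate.mate_id != c.record_id:
            n_inconsistent += 1
            seen.add(key)
            seen.add((mate.sample_id, mate.record_id or ""))
            continue
        seen.add(key)
        seen.add((mate.sample_id, mate.record_id or ""))

        if c.chrom != mate.chrom:
            n_translocation += 1
            out.append(c)  # one representative per translocation pair
            continue

        left, right = sorted((c, mate), key=lambda x: x.start)
        orientation = _pair_orientation(left, right)
        svtype = _ORIENT_TO_TYPE.get(orientation or "")
        span = right.start - left.start
        if svtype is None or span <= 0:
            n_inconsistent += 1
            continue
        out.append(
            SVCall(
                interval=GenomicInterval(left.chrom, left.start, right.start),
                svtype=svtype,
                svlen=span,
                sample_id=c.sample_id,
                caller_id=c.caller_id,
                quality=max(left.quality, right.quality),
                filter_status=c.filter_status,
                genotype=left.genotype,
                record_id=left.record_id,
            )
        )
        n_converted += 1

    counts = {
        "bnd_converted": n_converted,
        "bnd_translocations": n_translocation,
        "bnd_unpaired_dropped": n_unpaired,
        "bnd_inconsistent_dropped": n_inconsistent,
    }
    if any(counts.values()):
        log.info("resolve_bnd_pairs[%s]: %s", cs.caller_id, counts)
    if report is not None:
        report.update(counts)
    return cs.replace_calls(out, bnd_resolved=True)


def stitch(
    cs: CallSet,
    ro_min: float = 0.8,
    max_dist: int = 100,
    report: dict | None = None,
) -> CallSet:
    """Collapse near-duplicate same-type calls within each sample.

    Calls of the same type in the same sample whose reciprocal overlap is
    at least *ro_min* and whose breakpoint distance is at most *max_dist*
    are clustered by transitive closure (single linkage); each cluster is
    replaced by its highest-quality member (ties: leftmost start, then
    shortest length).  The operation is idempotent: representatives of
    distinct clusters never satisfy the collapse criterion.
    """
    groups: dict[tuple[str, str, str], list[SVCall]] = {}
    for c in cs:
        groups.setdefault((c.sample_id, c.svtype, c.chrom), []).append(c)

    out: list[SVCall] = []
    n_collapsed = 0
    for _, members in sorted(groups.items()):
        members = sorted(members, key=lambda c: (c.start, c.end, -c.quality))
        parent = list(range(len(members)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                if b.start - a.start > max_dist:
                    break  # sorted by start; |Δstart| only grows from here
                if (
                    breakpoint_distance(a, b) <= max_dist
                    and call_reciprocal_overlap(a, b) >= ro_min
                ):
                    parent[find(i)] = find(j)

        clusters: dict[int, list[SVCall]] = {}
        for i, c in enumerate(members):
            clusters.setdefault(find(i), []).append(c)
        for cluster in clusters.values():
            best = min(
                cluster,
                key=lambda c: (-c.quality, c.start, c.svlen, c.record_id or ""),
            )
            out.append(best)
            n_collapsed += len(cluster) - 1

    out.sort(key=lambda c: (c.sample_id, c.chrom, c.start, c.end, c.caller_id))
    if n_collapsed:
        log.info("stitch[%s]: collapsed %d near-duplicates", cs.caller_id,
                 n_collapsed)
    if report is not None:
        report["stitch_collapsed"] = n_collapsed
    return cs.replace_calls(out, stitched=True)
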