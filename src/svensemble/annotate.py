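"""Gene-model classification of variants and annotated-region merging.

Each variant receives exactly one genomic-location class under the
precedence full_gene > coding > intronic > intergenic: a variant that
swallows an entire gene is ``full_gene``; otherwise touching any exonic
base (UTR exons included) makes it ``coding``; lying within a gene span
without touching an exon makes it ``intronic``; anything else is
``intergenic``.  The precedence makes the classes mutually exclusive so
class counts over a callset always sum to the callset size.

Annotated regions are merged when they reciprocally overlap by at least
70%, cover exactly the same genes, and have compatible types (identical,
or one of {DUP, CNV} / {DEL, CNV}, in which case the non-CNV type wins).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .core import GenomicInterval, reciprocal_overlap
from .io import GeneModel

__all__ = [
    "AnnotatedRegion",
    "LOCATION_CLASSES",
    "classify_location",
    "genes_overlapped",
    "annotate_variants",
    "merge_annotated_regions",
]

LOCATION_CLASSES = ("coding", "full_gene", "intergenic", "intronic")

_CLASS_SEVERITY = {"full_gene": 0, "coding": 1, "intronic": 2, "intergenic": 3}


@dataclass(frozen=True)
class AnnotatedRegion:
    interval: GenomicInterval
    svtype: str
    genes: tuple[str, ...]  # ordered gene ids
    location_class: str
    acmg_class: str | None = None  # pass-through only, never computed
    region_id: str = ""


def classify_location(variant, genemodel: GeneModel) -> str:
    """Single location class for a variant under the severity precedence."""
    iv = variant.interval if hasattr(variant, "interval") else variant
    hits = genemodel.genes_overlapping(iv)
    if not hits:
        return "intergenic"
    if any(iv.contains(g.interval) for g in hits):
        return "full_gene"
    for g in hits:
        for exon in g.exons:
            if iv.overlap_bp(exon) > 0:
                return "coding"
    return "intronic"


def genes_overlapped(variant, genemodel: GeneModel) -> tuple[str, ...]:
    """Ids of all genes whose span overlaps the variant by >= 1 bp."""
    iv = variant.interval if hasattr(variant, "interval") else variant
    return tuple(g.gene_id for g in genemodel.genes_overlapping(iv))


def annotate_variants(popset, genemodel: GeneModel) -> list[AnnotatedRegion]:
    """Annotate every variant in a population callset."""
    return [
        AnnotatedRegion(
            interval=v.interval,
            svtype=v.svtype,
            genes=genes_overlapped(v, genemodel),
            location_class=classify_location(v, genemodel),
            region_id=v.id,
        )
        for v in popset.variants
    ]


def _types_mergeable(a: str, b: str) -> bool:
    return a == b or {a, b} in ({"DUP", "CNV"}, {"DEL", "CNV"})


def _merged_type(types: set[str]) -> str:
    non_cnv = types - {"CNV"}
    return next(iter(non_cnv)) if non_cnv else "CNV"


def _merge_pass(regions: list[AnnotatedRegion], ro_min: float):
    """One transitive-closure merge pass; returns (regions, changed)."""
    n = len(regions)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(regions):
        by_chrom.setdefault(r.interval.chrom, []).append(i)

    for idxs in by_chrom.values():
        idxs = sorted(idxs, key=lambda i: regions[i].interval.start)
        for a_pos, i in enumerate(idxs):
            ri = regions[i]
            for j in idxs[a_pos + 1:]:
                rj = regions[j]
                if rj.interval.start >= ri.interval.end:
                    break
                if set(ri.genes) != set(rj.genes):
                    continue
                if not _types_mergeable(ri.svtype, rj.svtype):
                    continue
                if len(ri.interval) and len(rj.interval) and \
                        reciprocal_overlap(ri.interval, rj.interval) >= ro_min:
                    parent[find(i)] = find(j)

    groups: dict[int, list[AnnotatedRegion]] = {}
    for i, r in enumerate(regions):
        groups.setdefault(find(i), []).append(r)

    merged: list[AnnotatedRegion] = []
    changed = False
    for members in groups.values():
        if len(members) == 1:
            merged.append(members[0])
            continue
        changed = True
        chrom = members[0].interval.chrom
        start = min(m.interval.start for m in members)
        end = max(m.interval.end for m in members)
        merged.append(
            replace(
                members[0],
                interval=GenomicInterval(chrom, start, end),
                svtype=_merged_type({m.svtype for m in members}),
                location_class=min(
                    (m.location_class for m in members),
                    key=_CLASS_SEVERITY.__getitem__,
                ),
                region_id=min(m.region_id for m in members),
            )
        )
    merged.sort(key=lambda r: (r.interval.chrom, r.interval.start,
                               r.interval.end))
    return merged, changed


def merge_annotated_regions(
    regions: list[AnnotatedRegion],
    ro_min: float = 0.70,
) -> list[AnnotatedRegion]:
    """Merge same-gene, type-compatible regions overlapping >= ro_min.

    Merging iterates to a fixpoint (a merged union span can create new
    qualifying pairs), so the operation is idempotent.
    """
    current = sorted(regions, key=lambda r: (r.interval.chrom,
                                             r.interval.start,
                                             r.interval.end))
    for _ in range(len(regions) + 1):
        current, changed = _merge_pass(current, ro_min)
        if not changed:
            break
    return current
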