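"""The consensus core: s-of-k ensemble merging across tools and samples.

Within each sample, calls from the k tools are clustered by breakpoint
distance (type-agnostically by default, since different callers annotate
the same event as DUP, INS, CNV or BND); clusters supported by at least
``s`` tools emit one consensus call.  The per-sample consensus sets are
then merged across samples with the same distance rule to produce a
population callset with per-sample genotypes and a tool-support vector
per variant.

Note the consequence of running the support rule per sample before the
joint merge: a variant seen by fewer than ``s`` tools in a given
individual is lost for that individual even when the site is confidently
called elsewhere in the cohort, which depresses frequencies of common
variants.  This ordering is intentional and reproduced faithfully.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .core import (
    Genotype,
    GenomicInterval,
    HOM_REF,
    MISSING_GT,
    SVCall,
    ValidationError,
    breakpoint_distance,
    ins_window,
    sv_length,
)
from .io import CallSet

__all__ = [
    "ToolCluster",
    "MergedVariant",
    "PopulationCallSet",
    "cluster_tool_calls",
    "consensus_sample",
    "joint_merge",
    "representative",
    "ensemble_sample",
    "DEFAULT_MAX_DIST",
    "DEFAULT_MIN_SIZE",
]

log = logging.getLogger(__name__)

#: Maximum breakpoint distance for two calls to be considered the same
#: event (SURVIVOR's conventional default).
DEFAULT_MAX_DIST = 1000
#: Minimum SV length considered (SVs are conventionally >= 50 bp).
DEFAULT_MIN_SIZE = 50

#: Tie-break precedence for majority type voting.
TYPE_PRECEDENCE = {"DEL": 0, "DUP": 1, "INS": 2, "INV": 3, "CNV": 4, "BND": 5}


@dataclass
class ToolCluster:
    """Calls from >=1 tools in one sample judged to be the same event."""

    member_calls: list[SVCall]

    @property
    def tools_supporting(self) -> frozenset[str]:
        return frozenset(c.caller_id for c in self.member_calls)


@dataclass
class MergedVariant:
    """A consensus site in the population callset."""

    interval: GenomicInterval
    svtype: str
    svlen: int
    supp_vec: tuple[bool, ...]
    genotypes: dict[str, Genotype]
    id: str

    @property
    def supp(self) -> int:
        return int(sum(self.supp_vec))

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass
class PopulationCallSet:
    """Variants x samples with per-sample genotypes."""

    variants: list[MergedVariant]
    sample_ids: list[str]
    tool_panel: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        known = set(self.sample_ids)
        for v in self.variants:
            missing = known - set(v.genotypes)
            if missing:
                raise ValidationError(
                    f"variant {v.id} lacks genotypes for {sorted(missing)}"
                )

    def __len__(self) -> int:
        return len(self.variants)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _cluster_calls(
    calls: list[tuple[SVCall, str]],
    max_dist: float,
    type_aware: bool,
) -> list[list[SVCall]]:
    """Greedy single-linkage clustering with a one-call-per-key constraint.

    *calls* are (call, key) pairs where *key* is the exclusivity unit (the
    tool for within-sample clustering, the sample for the joint merge).
    Calls are scanned in (chrom, start, end, key) order; each joins the
    nearest open cluster within *max_dist* (same type when *type_aware*).
    When the nearest cluster already holds a call with the same key, the
    nearer of the two keeps the slot and the other seeds a new cluster.
    """
    ordered = sorted(calls, key=lambda ck: (
        ck[0].chrom, ck[0].start, ck[0].end, ck[1], ck[0].svtype))
    clusters: list[dict] = []  # {"members": [(call, key)], "chrom", "type"}

    def dist_to(cluster, call, skip=None) -> float:
        ds = [
            breakpoint_distance(m, call)
            for m, k in cluster["members"]
            if m is not skip
        ]
        return min(ds) if ds else float("inf")

    for call, key in ordered:
        best_i, best_d = None, float("inf")
        for i, cl in enumerate(clusters):
            if cl["chrom"] != call.chrom:
                continue
            if type_aware and cl["type"] != call.svtype:
                continue
            d = dist_to(cl, call)
            if d <= max_dist and d < best_d:
                best_i, best_d = i, d
        if best_i is None:
            clusters.append(
                {"members": [(call, key)], "chrom": call.chrom,
                 "type": call.svtype}
            )
            continue
        cl = clusters[best_i]
        same_key = next(((m, k) for m, k in cl["members"] if k == key), None)
        if same_key is None:
            cl["members"].append((call, key))
            continue
        incumbent = same_key[0]
        d_new = dist_to(cl, call, skip=incumbent)
        d_old = dist_to(cl, incumbent, skip=incumbent)
        if d_new < d_old:
            cl["members"] = [
                (m, k) for m, k in cl["members"] if m is not incumbent
            ] + [(call, key)]
            clusters.append(
                {"members": [(incumbent, key)], "chrom": incumbent.chrom,
                 "type": incumbent.svtype}
            )
        else:
            clusters.append(
                {"members": [(call, key)], "chrom": call.chrom,
                 "type": call.svtype}
            )
    return [[m for m, _ in cl["members"]] for cl in clusters]


def cluster_tool_calls(
    per_tool_calls: list[CallSet],
    max_dist: int = DEFAULT_MAX_DIST,
    type_aware: bool = False,
) -> list[ToolCluster]:
    """Cluster one sample's calls across tools into candidate events."""
    samples = {c.sample_id for cs in per_tool_calls for c in cs}
    if len(samples) > 1:
        raise ValidationError(
            f"cluster_tool_calls expects one sample, got {sorted(samples)}"
        )
    pairs = [
        (call, cs.caller_id) for cs in per_tool_calls for call in cs
    ]
    return [ToolCluster(members) for members in
            _cluster_calls(pairs, max_dist, type_aware)]


# ---------------------------------------------------------------------------
# Representative selection
# ---------------------------------------------------------------------------

def representative(cluster: ToolCluster | list[SVCall]):
    """Medoid coordinates and majority type for a cluster.

    Coordinates come from the member minimizing the summed breakpoint
    distance to the others (ties: leftmost start, then shortest); the
    type is the majority vote with precedence DEL > DUP > INS > INV >
    CNV > BND on ties.  Returns ``(interval, svtype, svlen, medoid)``.
    """
    members = cluster.member_calls if isinstance(cluster, ToolCluster) else cluster
    if not members:
        raise ValidationError("representative of empty cluster")

    def medoid_key(c: SVCall):
        total = sum(breakpoint_distance(c, o) for o in members if o is not c)
        return (total, c.start, c.svlen, c.caller_id, c.sample_id)

    medoid = min(members, key=medoid_key)

    votes: dict[str, int] = {}
    for c in members:
        votes[c.svtype] = votes.get(c.svtype, 0) + 1
    svtype = min(votes, key=lambda t: (-votes[t], TYPE_PRECEDENCE[t]))

    if svtype == "INS" and medoid.svtype != "INS":
        interval = GenomicInterval(medoid.chrom, medoid.start, medoid.start + 1)
        svlen = sv_length(medoid)
    elif svtype != "INS" and medoid.svtype == "INS":
        interval = ins_window(medoid)
        svlen = len(interval)
    else:
        interval, svlen = medoid.interval, medoid.svlen
    return interval, svtype, svlen, medoid


# ---------------------------------------------------------------------------
# Per-sample consensus
# ---------------------------------------------------------------------------

def consensus_sample(
    clusters: list[ToolCluster],
    s: int,
    tool_panel: tuple[str, ...],
) -> CallSet:
    """Emit one consensus call per cluster supported by >= s tools."""
    k = len(tool_panel)
    if not 1 <= s <= k:
        raise ValidationError(f"support threshold s={s} outside 1..{k}")
    sample_id = next(
        (c.sample_id for cl in clusters for c in cl.member_calls), None
    )
    out: list[SVCall] = []
    for cl in clusters:
        tools = cl.tools_supporting
        if len(tools) < s:
            continue
        interval, svtype, svlen, medoid = representative(cl)
        out.append(
            SVCall(
                interval=interval,
                svtype=svtype,
                svlen=svlen,
                sample_id=medoid.sample_id,
                caller_id="consensus",
                quality=max(c.quality for c in cl.member_calls),
                genotype=medoid.genotype,
                tools=tuple(sorted(tools)),
            )
        )
    out.sort(key=lambda c: (c.chrom, c.start, c.end, c.svtype))
    return CallSet(
        out,
        sample_ids=[sample_id] if sample_id is not None else [],
        caller_id="consensus",
        provenance={"s": s, "tool_panel": list(tool_panel)},
    )


def ensemble_sample(
    per_tool_calls: list[CallSet],
    s: int = 3,
    max_dist: int = DEFAULT_MAX_DIST,
    type_aware: bool = False,
    min_size: int = DEFAULT_MIN_SIZE,
) -> CallSet:
    """Full within-sample pipeline: size filter, cluster, s-of-k consensus."""
    filtered = [
        cs.replace_calls([c for c in cs if sv_length(c) >= min_size])
        for cs in per_tool_calls
    ]
    clusters = cluster_tool_calls(filtered, max_dist, type_aware)
    panel = tuple(sorted(cs.caller_id for cs in per_tool_calls))
    return consensus_sample(clusters, s, panel)


# ---------------------------------------------------------------------------
# Cross-sample joint merge
# ---------------------------------------------------------------------------

def joint_merge(
    per_sample: list[CallSet],
    max_dist: int = DEFAULT_MAX_DIST,
    type_aware: bool = False,
    tool_panel: tuple[str, ...] | None = None,
    uncalled_as_ref: bool = False,
) -> PopulationCallSet:
    """Merge per-sample consensus callsets into a population callset.

    Samples without a member in a cluster receive a missing genotype by
    default; ``uncalled_as_ref=True`` codes them hom-ref instead,
    emulating a pipeline that re-genotypes every sample at every merged
    site.  Output is invariant to the order of the input callsets.
    """
    sample_ids: list[str] = []
    for cs in per_sample:
        for sid in cs.sample_ids:
            if sid in sample_ids:
                raise ValidationError(f"duplicate sample id {sid!r}")
            sample_ids.append(sid)
    sample_ids.sort()

    if tool_panel is None:
        seen_tools: set[str] = set()
        for cs in per_sample:
            for c in cs:
                seen_tools.update(c.tools or (c.caller_id,))
        tool_panel = tuple(sorted(seen_tools))

    pairs = [(c, c.sample_id) for cs in per_sample for c in cs]
    clusters = _cluster_calls(pairs, max_dist, type_aware)

    absent = HOM_REF if uncalled_as_ref else MISSING_GT
    variants: list[MergedVariant] = []
    for members in clusters:
        interval, svtype, svlen, _ = representative(members)
        genotypes = {sid: absent for sid in sample_ids}
        tools: set[str] = set()
        for c in members:
            genotypes[c.sample_id] = c.genotype
            tools.update(c.tools or (c.caller_id,))
        supp_vec = tuple(t in tools for t in tool_panel)
        variants.append(
            MergedVariant(
                interval=interval, svtype=svtype, svlen=svlen,
                supp_vec=supp_vec, genotypes=genotypes, id="",
            )
        )

    variants.sort(key=lambda v: (v.chrom, v.start, v.end,
                                 TYPE_PRECEDENCE[v.svtype]))
    for i, v in enumerate(variants):
        v.id = f"{v.chrom}:{v.start}:{v.svtype}:{i}"
    log.info("joint_merge: %d variants across %d samples",
             len(variants), len(sample_ids))
    return PopulationCallSet(variants, sample_ids, tool_panel)
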