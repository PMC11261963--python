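"""Synthetic multi-caller SV data with known truth.

The generator plants a population truth set — non-overlapping SV loci
with configurable allele-frequency, length and type distributions, and
Hardy–Weinberg diploid genotypes — then emulates what each caller would
report: detection with per-type sensitivity, Gaussian breakpoint jitter,
stochastic type confusion (a duplication reported as an insertion, say),
genotype errors, and uniformly placed false positives.  A depth-caller
emulator produces loss/gain calls with boundaries snapped outward to
1,000 bp windows, reproducing the coarse resolution that motivates the
call-anchored 90% validation rule for long SVs.

Every operation is a pure function of its inputs and a seed.  False
positives avoid planted loci by rejection sampling so truth matching is
unambiguous.

The default type mix (75% DEL, 19% DUP, 4% INS, 2% INV) and length range
(50 bp – 10 kb, log-uniform) mirror the composition of short-read
population SV callsets; the default allele-frequency distribution is a
low-frequency-skewed Beta(0.3, 3), matching the singleton-dominated
spectra such cohorts show.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from .core import Genotype, GenomicInterval, SVCall, ValidationError
from .ensemble import (
    DEFAULT_MAX_DIST,
    PopulationCallSet,
    ensemble_sample,
    joint_merge,
)
from .io import CallSet
from .longsv import DEPTH_WINDOW, DepthCall
from .novelty import _variant_extent
from .core import reciprocal_overlap

__all__ = [
    "GenomeSpec",
    "TruthLocus",
    "TruthSet",
    "CallerProfile",
    "simulate_truth",
    "emulate_sv_caller",
    "emulate_depth_caller",
    "evaluate_recovery",
    "carrier_recall",
    "run_end_to_end",
    "DEFAULT_TYPE_MIX",
]

#: Study-condition composition of planted SV types.
DEFAULT_TYPE_MIX = {"DEL": 0.75, "DUP": 0.19, "INS": 0.04, "INV": 0.02}


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names and lengths of the simulated genome."""

    chrom_lengths: tuple[tuple[str, int], ...] = tuple(
        (str(i), 10_000_000) for i in range(1, 6)
    )

    @property
    def total_bp(self) -> int:
        return sum(l for _, l in self.chrom_lengths)

    def length_of(self, chrom: str) -> int:
        return dict(self.chrom_lengths)[chrom]


@dataclass(frozen=True)
class TruthLocus:
    interval: GenomicInterval
    svtype: str
    svlen: int
    af: float

    @property
    def extent(self) -> GenomicInterval:
        """Reserved footprint (INS reserve a window of their length)."""
        if self.svtype == "INS":
            anchor = self.interval.start
            half = self.svlen // 2
            start = max(0, anchor - half)
            return GenomicInterval(self.interval.chrom, start,
                                   start + self.svlen)
        return self.interval


@dataclass
class TruthSet:
    loci: list[TruthLocus]
    genotypes: np.ndarray  # n_samples x n_loci alt dosages
    sample_ids: list[str]
    seed: int
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    subpop_of_sample: tuple[int, ...] = ()  # empty = single population

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def carriers(self, locus_idx: int) -> list[int]:
        return list(np.nonzero(self.genotypes[:, locus_idx] > 0)[0])

    @property
    def carried_loci(self) -> list[int]:
        """Indices of loci with at least one carrier in the cohort."""
        return list(np.nonzero((self.genotypes > 0).any(axis=0))[0])


@dataclass(frozen=True)
class CallerProfile:
    """Error model for one emulated SV caller.

    ``sensitivity`` is either a single probability or a per-svtype map;
    ``type_confusion`` maps a true type to a distribution over reported
    types (rows must sum to 1; missing rows mean no confusion).
    ``fp_rate`` is expected false calls per sample per Mb.
    """

    name: str
    sensitivity: float | dict[str, float] = 1.0
    fp_rate: float = 0.0
    jitter_sd: float = 0.0
    type_confusion: dict[str, dict[str, float]] = field(default_factory=dict)
    genotype_error: float = 0.0
    quality_mu: float = 60.0
    quality_sd: float = 10.0

    def __post_init__(self) -> None:
        for true_type, row in self.type_confusion.items():
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ValidationError(
                    f"confusion row for {true_type} must sum to 1"
                )
        sens = (self.sensitivity.values()
                if isinstance(self.sensitivity, dict) else [self.sensitivity])
        if any(not 0 <= p <= 1 for p in sens):
            raise ValidationError("sensitivities must lie in [0,1]")

    def prob_detect(self, svtype: str, length: int) -> float:
        if isinstance(self.sensitivity, dict):
            return self.sensitivity.get(svtype, self.sensitivity.get("*", 1.0))
        return float(self.sensitivity)

    @classmethod
    def identity(cls, name: str) -> "CallerProfile":
        """Perfect caller: everything detected exactly as planted."""
        return cls(name=name)

    @classmethod
    def realistic(cls, name: str, seed_shift: int = 0) -> "CallerProfile":
        """A plausibly imperfect short-read caller."""
        return cls(
            name=name,
            sensitivity=0.95,
            fp_rate=0.1,
            jitter_sd=20.0,
            type_confusion={"DUP": {"DUP": 0.85, "INS": 0.15}},
            genotype_error=0.01,
        )


# ---------------------------------------------------------------------------
# Truth generation
# ---------------------------------------------------------------------------

def _default_af_dist(rng: np.random.Generator, size: int) -> np.ndarray:
    return rng.beta(0.3, 3.0, size=size)


def _default_length_dist(rng: np.random.Generator, size: int) -> np.ndarray:
    # log-uniform across 50 bp .. 10 kb
    return np.exp(rng.uniform(math.log(50), math.log(10_000), size=size))


def simulate_truth(
    n_samples: int = 20,
    n_loci: int = 200,
    af_dist=None,
    length_dist=None,
    type_mix: dict[str, float] | None = None,
    genome: GenomeSpec | None = None,
    seed: int = 0,
    min_gap: int = 2 * DEFAULT_MAX_DIST,
    n_subpops: int = 1,
) -> TruthSet:
    """Plant a non-overlapping population truth set.

    Loci are separated by at least *min_gap* bp so clustering at the
    default merge distance cannot conflate distinct loci.  Genotypes are
    drawn Binomial(2, AF) per sample (Hardy–Weinberg).  With
    ``n_subpops > 1``, each subpopulation draws its own AF per locus
    (samples split evenly, recorded in ``subpop_of_sample``), giving the
    population structure that genotype-matrix exports should resolve.
    """
    rng = np.random.default_rng(seed)
    genome = genome or GenomeSpec()
    type_mix = type_mix or DEFAULT_TYPE_MIX
    af_dist = af_dist or _default_af_dist
    length_dist = length_dist or _default_length_dist

    types = list(type_mix)
    probs = np.array([type_mix[t] for t in types], dtype=float)
    probs = probs / probs.sum()

    chroms = [c for c, _ in genome.chrom_lengths]
    chrom_w = np.array([l for _, l in genome.chrom_lengths], dtype=float)
    chrom_w /= chrom_w.sum()

    afs = np.clip(af_dist(rng, n_loci), 1e-6, 1.0)
    lengths = np.maximum(50, np.round(length_dist(rng, n_loci))).astype(int)
    locus_types = rng.choice(types, size=n_loci, p=probs)

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def collides(chrom: str, start: int, end: int) -> bool:
        for s, e in occupied[chrom]:
            if start < e + min_gap and s < end + min_gap:
                return True
        return False

    loci: list[TruthLocus] = []
    max_tries = 200 * n_loci
    tries = 0
    for i in range(n_loci):
        svlen = int(lengths[i])
        svtype = str(locus_types[i])
        placed = False
        while tries < max_tries:
            tries += 1
            chrom = str(rng.choice(chroms, p=chrom_w))
            chrom_len = genome.length_of(chrom)
            if chrom_len <= svlen + 2:
                continue
            start = int(rng.integers(1, chrom_len - svlen - 1))
            if svtype == "INS":
                interval = GenomicInterval(chrom, start, start + 1)
                ext = (max(0, start - svlen // 2),
                       max(0, start - svlen // 2) + svlen)
            else:
                interval = GenomicInterval(chrom, start, start + svlen)
                ext = (start, start + svlen)
            if collides(chrom, *ext):
                continue
            occupied[chrom].append(ext)
            loci.append(TruthLocus(interval, svtype, svlen, float(afs[i])))
            placed = True
            break
        if not placed:
            raise ValidationError(
                "genome too small for the requested non-overlapping loci"
            )

    loci.sort(key=lambda l: (l.interval.chrom, l.interval.start))
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    if n_subpops <= 1:
        genotypes = rng.binomial(2, np.array([l.af for l in loci]),
                                 size=(n_samples, len(loci))).astype(np.int8)
        return TruthSet(loci, genotypes, sample_ids, seed, genome)

    # per-subpopulation AFs: the planted AF is subpopulation 0's; the
    # others draw independently, creating differentiated loci
    af_mat = np.empty((n_subpops, len(loci)))
    af_mat[0] = [l.af for l in loci]
    for p in range(1, n_subpops):
        af_mat[p] = np.clip(af_dist(rng, len(loci)), 1e-6, 1.0)
    subpop = tuple(i * n_subpops // n_samples for i in range(n_samples))
    genotypes = np.empty((n_samples, len(loci)), dtype=np.int8)
    for i in range(n_samples):
        genotypes[i] = rng.binomial(2, af_mat[subpop[i]])
    return TruthSet(loci, genotypes, sample_ids, seed, genome,
                    subpop_of_sample=subpop)


# ---------------------------------------------------------------------------
# Caller emulation
# ---------------------------------------------------------------------------

def _jitter_interval(
    locus: TruthLocus, rng: np.random.Generator, sd: float,
    chrom_len: int,
) -> tuple[GenomicInterval, int]:
    if sd <= 0:
        return locus.interval, locus.svlen
    if locus.svtype == "INS":
        shift = int(round(rng.normal(0, sd)))
        a = min(max(0, locus.interval.start + shift), chrom_len - 2)
        return GenomicInterval(locus.interval.chrom, a, a + 1), locus.svlen
    ds = int(round(rng.normal(0, sd)))
    de = int(round(rng.normal(0, sd)))
    start = max(0, locus.interval.start + ds)
    end = min(chrom_len, locus.interval.end + de)
    if end <= start + 1:
        start, end = locus.interval.start, locus.interval.end
    iv = GenomicInterval(locus.interval.chrom, start, end)
    return iv, len(iv)


def _confused_type(svtype: str, profile: CallerProfile,
                   rng: np.random.Generator) -> str:
    row = profile.type_confusion.get(svtype)
    if not row:
        return svtype
    labels = sorted(row)
    return str(rng.choice(labels, p=[row[t] for t in labels]))


def _as_type(interval: GenomicInterval, svlen: int, svtype: str):
    """Coerce an (interval, svlen) pair to the shape a type requires."""
    if svtype == "INS":
        mid = (interval.start + interval.end) // 2
        return GenomicInterval(interval.chrom, mid, mid + 1), svlen
    if len(interval) <= 1:  # came from an INS anchor: expand to a window
        start = max(0, interval.start - svlen // 2)
        return GenomicInterval(interval.chrom, start, start + svlen), svlen
    return interval, len(interval)


def emulate_sv_caller(
    truth: TruthSet, profile: CallerProfile, seed: int = 0,
) -> CallSet:
    """One emulated tool's calls over all samples of the truth set."""
    rng = np.random.default_rng(
        np.random.SeedSequence(
            entropy=(truth.seed, seed, zlib.crc32(profile.name.encode()))
        )
    )
    calls: list[SVCall] = []
    chrom_lens = dict(truth.genome.chrom_lengths)

    for si, sid in enumerate(truth.sample_ids):
        for li, locus in enumerate(truth.loci):
            dosage = int(truth.genotypes[si, li])
            if dosage == 0:
                continue
            if rng.random() > profile.prob_detect(locus.svtype, locus.svlen):
                continue
            chrom_len = chrom_lens[locus.interval.chrom]
            interval, svlen = _jitter_interval(locus, rng, profile.jitter_sd,
                                               chrom_len)
            svtype = _confused_type(locus.svtype, profile, rng)
            interval, svlen = _as_type(interval, svlen, svtype)
            rep_dosage = dosage
            if profile.genotype_error > 0 and rng.random() < profile.genotype_error:
                rep_dosage = 3 - dosage  # het <-> hom-alt flip
            calls.append(
                SVCall(
                    interval=interval, svtype=svtype, svlen=svlen,
                    sample_id=sid, caller_id=profile.name,
                    quality=float(rng.normal(profile.quality_mu,
                                             profile.quality_sd)),
                    genotype=Genotype.from_dosage(rep_dosage),
                )
            )
        # false positives, placed away from planted loci
        n_fp = rng.poisson(profile.fp_rate * truth.genome.total_bp / 1e6)
        for _ in range(int(n_fp)):
            calls.append(_random_fp(truth, profile, rng, sid))

    calls.sort(key=lambda c: (c.sample_id, c.chrom, c.start, c.end))
    return CallSet(
        calls, sample_ids=list(truth.sample_ids), caller_id=profile.name,
        provenance={"profile": profile.name, "seed": seed},
    )


def _random_fp(truth: TruthSet, profile: CallerProfile,
               rng: np.random.Generator, sid: str) -> SVCall:
    chroms = [c for c, _ in truth.genome.chrom_lengths]
    reserved: dict[str, list[GenomicInterval]] = {}
    for l in truth.loci:
        reserved.setdefault(l.interval.chrom, []).append(l.extent)
    for _ in range(1000):
        chrom = str(rng.choice(chroms))
        chrom_len = truth.genome.length_of(chrom)
        svlen = int(np.exp(rng.uniform(math.log(50), math.log(5_000))))
        start = int(rng.integers(1, max(2, chrom_len - svlen - 1)))
        iv = GenomicInterval(chrom, start, start + svlen)
        pad = 2 * DEFAULT_MAX_DIST
        if any(iv.start < r.end + pad and r.start < iv.end + pad
               for r in reserved.get(chrom, [])):
            continue
        svtype = str(rng.choice(["DEL", "DUP", "INV"]))
        return SVCall(
            interval=iv, svtype=svtype, svlen=svlen,
            sample_id=sid, caller_id=profile.name,
            quality=float(rng.normal(profile.quality_mu, profile.quality_sd)),
            genotype=Genotype.from_dosage(1),
        )
    raise ValidationError("could not place false positive away from truth")


def emulate_depth_caller(
    truth: TruthSet,
    window: int = DEPTH_WINDOW,
    min_len: int = 5_000,
    sensitivity: float = 1.0,
    seed: int = 0,
) -> list[DepthCall]:
    """Depth-caller calls: carried DEL/DUP loci at window resolution.

    Boundaries snap outward to multiples of *window*; insertions and
    inversions are depth-invisible and never emitted.
    """
    if window <= 0:
        raise ValidationError("window must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(truth.seed,
                                                                seed, 7)))
    out: list[DepthCall] = []
    for si, sid in enumerate(truth.sample_ids):
        for li, locus in enumerate(truth.loci):
            if truth.genotypes[si, li] == 0:
                continue
            if locus.svtype not in ("DEL", "DUP") or locus.svlen < min_len:
                continue
            if rng.random() > sensitivity:
                continue
            start = (locus.interval.start // window) * window
            end = -(-locus.interval.end // window) * window
            out.append(
                DepthCall(
                    interval=GenomicInterval(locus.interval.chrom, start, end),
                    copy_state="loss" if locus.svtype == "DEL" else "gain",
                    sample_id=sid,
                    window=window,
                )
            )
    return out


# ---------------------------------------------------------------------------
# End-to-end pipeline and recovery scoring
# ---------------------------------------------------------------------------

def _subset_sample(cs: CallSet, sid: str) -> CallSet:
    return CallSet(
        [c for c in cs if c.sample_id == sid],
        sample_ids=[sid], caller_id=cs.caller_id,
        provenance=dict(cs.provenance),
    )


def run_end_to_end(
    truth: TruthSet,
    tool_callsets: list[CallSet],
    s: int = 3,
    max_dist: int = DEFAULT_MAX_DIST,
    type_aware: bool = False,
    min_size: int = 50,
    uncalled_as_ref: bool = False,
    caps=None,
) -> PopulationCallSet:
    """Per-sample s-of-k consensus followed by the cross-sample merge.

    When *caps* (a :class:`~svensemble.filters.LengthCaps`) is given,
    per-type length caps are applied to every per-tool callset before
    clustering and re-asserted on the merged output.
    """
    from .filters import apply_length_caps

    if caps is not None:
        tool_callsets = [
            cs.replace_calls(apply_length_caps(list(cs), caps))
            for cs in tool_callsets
        ]
    per_sample = []
    for sid in truth.sample_ids:
        per_tool = [_subset_sample(cs, sid) for cs in tool_callsets]
        per_sample.append(
            ensemble_sample(per_tool, s=s, max_dist=max_dist,
                            type_aware=type_aware, min_size=min_size)
        )
    # samples with no surviving call still contribute a genotype column
    for cs, sid in zip(per_sample, truth.sample_ids):
        if not cs.sample_ids:
            cs.sample_ids = [sid]
    panel = tuple(sorted(cs.caller_id for cs in tool_callsets))
    pop = joint_merge(per_sample, max_dist=max_dist, type_aware=type_aware,
                      tool_panel=panel, uncalled_as_ref=uncalled_as_ref)
    if caps is not None:
        from .filters import apply_length_caps

        pop.variants = apply_length_caps(pop.variants, caps)
    return pop


def _locus_matches(locus: TruthLocus, variant, ro_min: float) -> bool:
    ext_t = locus.extent
    ext_v = _variant_extent(variant)
    if ext_t.chrom != ext_v.chrom or len(ext_t) == 0 or len(ext_v) == 0:
        return False
    return reciprocal_overlap(ext_t, ext_v) >= ro_min


def evaluate_recovery(
    truth: TruthSet,
    popset: PopulationCallSet,
    ro_min: float = 0.5,
) -> dict:
    """Precision/recall of planted loci plus allele-frequency error.

    A carried truth locus is recovered when some merged variant matches
    it at reciprocal overlap >= *ro_min* (type-agnostic, since confusion
    profiles may relabel).  AF error compares the cohort AF of the
    matching variant with the realized truth AF (dosage mean / 2).
    """
    from .spectra import allele_frequency

    carried = truth.carried_loci
    by_chrom: dict[str, list] = {}
    for v in popset.variants:
        by_chrom.setdefault(v.interval.chrom, []).append(v)

    matched_variants: set[str] = set()
    af_errors: list[float] = []
    recovered_by_type: dict[str, int] = {}
    carried_by_type: dict[str, int] = {}
    n_recovered = 0
    for li in carried:
        locus = truth.loci[li]
        carried_by_type[locus.svtype] = carried_by_type.get(locus.svtype, 0) + 1
        hit = None
        for v in by_chrom.get(locus.interval.chrom, []):
            if _locus_matches(locus, v, ro_min):
                hit = v
                break
        if hit is None:
            continue
        n_recovered += 1
        recovered_by_type[locus.svtype] = (
            recovered_by_type.get(locus.svtype, 0) + 1
        )
        matched_variants.add(hit.id)
        realized_af = float(truth.genotypes[:, li].mean() / 2.0)
        try:
            af_errors.append(abs(allele_frequency(hit) - realized_af))
        except ValidationError:
            pass

    n_carried = len(carried)
    n_variants = len(popset.variants)
    return {
        "n_carried_loci": n_carried,
        "n_recovered": n_recovered,
        "recall": n_recovered / n_carried if n_carried else float("nan"),
        "precision": (len(matched_variants) / n_variants
                      if n_variants else float("nan")),
        "recall_by_type": {
            t: recovered_by_type.get(t, 0) / n
            for t, n in carried_by_type.items()
        },
        "af_mean_abs_error": (float(np.mean(af_errors))
                              if af_errors else float("nan")),
        "af_rmse": (float(np.sqrt(np.mean(np.square(af_errors))))
                    if af_errors else float("nan")),
    }


def carrier_recall(
    truth: TruthSet,
    per_sample_consensus: dict[str, CallSet],
    ro_min: float = 0.5,
) -> float:
    """Fraction of carried (sample, locus) pairs present in the
    per-sample consensus — the quantity the s-of-k binomial closed form
    predicts when tools detect independently."""
    n_pairs = n_hit = 0
    for si, sid in enumerate(truth.sample_ids):
        cs = per_sample_consensus.get(sid)
        calls = list(cs) if cs is not None else []
        for li in np.nonzero(truth.genotypes[si] > 0)[0]:
            locus = truth.loci[li]
            n_pairs += 1
            for c in calls:
                if _locus_matches(locus, _CallView(c), ro_min):
                    n_hit += 1
                    break
    return n_hit / n_pairs if n_pairs else float("nan")


class _CallView:
    """Adapts an SVCall to the variant interface used for matching."""

    def __init__(self, call: SVCall):
        self.interval = call.interval
        self.svtype = call.svtype
        self.svlen = call.svlen
        self.id = call.record_id or ""
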