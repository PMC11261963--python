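# Methods

## Coordinates and geometric primitives

All internal coordinates are 0-based half-open; VCF's 1-based inclusive
POS/END are converted at the I/O boundary. This makes every overlap and
length computation a plain difference with no ±1 bookkeeping.

Reciprocal overlap is `min(o/|a|, o/|b|)` — symmetric, 0 across
chromosomes, and undefined (an error) for zero-length intervals.
Breakpoint distance is `max(|Δstart|, |Δend|)`, the criterion
SURVIVOR-style mergers use: two calls are "the same event" when both
breakpoints lie within a tolerance, regardless of how much the spans
overlap.

Insertions are point-anchored (`end == start + 1`) with the inserted
length carried separately. Because a point has no extent, insertions
enter overlap-based comparisons through a symmetric window of their
inserted length centred on the anchor. This is required for
type-agnostic matching: a tandem duplication and the equivalent
insertion call must be able to reach a high reciprocal overlap.
Breakpoint distance, by contrast, uses the raw anchor, so an insertion
at the start of a long duplication does not spuriously match it.

Negative SVLEN values (the deletion convention of some VCF dialects)
are normalized to absolute lengths on read. One htslib behaviour is
worth recording: for symbolic alleles, htslib derives the record end
from SVLEN when present (one base longer than the END field states), so
the readers treat SVLEN as authoritative for the span and fall back to
END only in its absence. The written and read representations round-trip
exactly under this rule.

## Harmonization

**Pass-filtering** keeps records whose FILTER is `PASS` or `.` (some
dialects leave FILTER unset on good records); the accepted label set is
configurable per caller. Removal counts are reported per label.

**Breakend resolution.** Orientation is read from the ALT bracket
notation: `t[p[` / `t]p]` mean the local sequence precedes the junction
(orientation `+`), `]p]t` / `[p[t` that it follows (`-`). For a
same-chromosome mate pair sorted by position, `+-` encodes a deletion,
`-+` a tandem duplication, and `++`/`--` an inversion; the converted
call spans the two breakends. Inter-chromosomal pairs are retained as
translocation breakends (one representative per pair). Unpaired or
mutually inconsistent mates are dropped with counts, and an accounting
identity holds: every input breakend is half of a conversion, half of a
translocation, half of a dropped inconsistent pair, or a dropped
singleton.

**Stitching** collapses near-duplicate calls that joint-calling
workflows produce when the same variant is re-genotyped at two slightly
different site definitions. Within one sample and one type, calls with
reciprocal overlap ≥ 0.8 and breakpoint distance ≤ 100 bp are clustered
by transitive closure and replaced by the highest-quality member (ties:
leftmost start, then shortest). The thresholds are deliberately much
tighter than the cross-tool merge distance: stitching must join records
of the *same* call while keeping genuinely distinct nearby SVs apart.
Both are configurable. Because representatives of distinct connected
components can never satisfy the pairwise criterion, the operation is
idempotent by construction.

## Consensus clustering and the s-of-k rule

Within a sample, calls from the k tools are clustered greedily in
(chrom, start) order: each call joins the nearest open cluster whose
minimum breakpoint distance is within `max_dist` (default 1,000 bp, the
conventional merge distance), with the constraint of at most one call
per tool per cluster. On a same-tool conflict the nearer call keeps the
slot and the displaced call seeds a new cluster (single-step, no
cascade) — this realizes "the nearer candidate joins" deterministically
without global optimization. Matching is type-agnostic by default,
because callers annotate the same event inconsistently (DUP vs INS vs
CNV vs BND); a type-aware mode is available.

A minimum SV length of 50 bp — the conventional lower bound of the SV
size regime — is applied before clustering.

Clusters supported by at least *s* tools (default 3 of 4) emit one
consensus call placed at the cluster **medoid**: the member minimizing
the summed breakpoint distance to the others, ties broken by leftmost
start then shortest length. The type is a majority vote with precedence
DEL > DUP > INS > INV > CNV > BND on ties. When the voted type and the
medoid's shape disagree (an INS vote over a spanning medoid, or vice
versa) the coordinates are coerced through the insertion-window
convention.

The per-sample consensus runs **before** the cross-sample merge. The
consequence is intentional and reproduced, not corrected: a variant
seen by fewer than *s* tools in one individual is lost for that
individual even when the site is confidently called elsewhere in the
cohort, which depresses the frequencies of common variants.

The joint merge applies the same clustering across samples (at most one
call per sample per cluster), producing one merged variant per cluster
with deterministic ids `chrom:start:type:serial`. Samples without a
member receive a **missing** genotype by default. The alternative
`uncalled_as_ref=True` codes them hom-ref, emulating a pipeline that
re-genotypes every sample at every merged site; it is the right choice
whenever cohort allele frequencies are to be compared with planted or
external truth, and it is what the recovery measurements use. Output is
invariant to the order of input callsets: processing order is fixed by
sorting, and ties in medoid selection are broken deterministically.

## Filters

Per-type length caps remove calls whose length **strictly** exceeds
1 kb (INS), 10 kb (DEL) or 20 kb (INV, DUP); boundary values are
retained, consistent with the short class being defined as ≤ 10 kb.
Split-read/paired-end callers produce implausible lengths above these
scales, and long events are handled by the depth-validation path
instead. Types without a cap (CNV, BND) pass through. The standalone
filter stage applies caps to the merged callset; the merge path can
additionally apply them to every per-tool callset before clustering and
re-assert them on the merged output (guarding representative-selection
edge cases) — applying caps twice is safe because the operation is
idempotent. Pre-clustering application is opt-in rather than the
default so that the end-to-end identity-recovery property holds over
the simulator's full planted length range.

Blacklist exclusion removes variants overlapping a catalogued
problematic region by at least 1 bp (the fraction is configurable). It
runs after merging, before analysis, with the option to move it
earlier.

The 10 kb split partitions the callset into the s-of-k class
(≤ 10 kb) and the depth-validated class (> 10 kb).

## Long-call validation

A call longer than 10 kb is accepted when a **single** depth-caller CNV
call of concordant copy state (DEL↔loss, DUP↔gain; CNV matches either)
covers at least 90% of the call. The fraction is anchored on the SV
call (overlap / call length), not reciprocal: depth callers operate at
1 kb window resolution with boundaries snapped outward, so a reciprocal
criterion would systematically over-reject precisely because the
corroborating call is coarse. Outward snapping means quantization can
only extend the depth call, so a fully covered event always reaches
100% call-anchored overlap; even inward-rounded boundaries would cost
at most 2 windows ≤ 20% of the depth call but well under 10% of any
≥ 10 kb SV. A reciprocal mode and a state-agnostic mode exist as
flags. Fragments are not summed — corroboration is meaningless if no
single depth event spans the call.

Validated regions at or above 200 kb are excluded from analysis
(implausibly long calls implicate too many genes) but still written to
the all-calls BED. Gene coverage reports support excluding chromosomes
(the X in particular, where depth methods misbehave without
ploidy-aware handling, which this package does not attempt).

## Novelty

Each merged variant is compared against a chromosome-indexed reference
database; the best match is the record maximizing reciprocal overlap
(ties by accession order), and the variant is novel at threshold *t*
iff that maximum is below *t*. Thresholds 0.70/0.90/0.95 are the
defaults. Type is ignored by default — reference-type vocabularies are
inconsistent, and the read-in mapping (deletion/loss→DEL,
duplication/gain→DUP, unmapped→CNV) is itself an assumption — but a
type-aware mode restricts matches to compatible types with CNV as a
wildcard among {DEL, DUP, CNV}. Translocation breakends have no
meaningful length and are excluded from the comparison, counted
separately. Percentages are rounded half-up to one decimal.

## Annotation

Location classes are made mutually exclusive by the precedence
full_gene > coding > intronic > intergenic (published category tables
that lack such a precedence can sum to more than the variant total;
exclusivity is imposed here so counts are additive). The gene span runs
from transcription start to end; exons are merged across transcripts,
and UTR-containing exons count as exonic sequence, so "coding" means
"touches any exonic base". ACMG classes are accepted as pass-through
annotations but never computed.

Annotated regions merge when they reciprocally overlap by ≥ 70%, cover
exactly the same genes, and have compatible types (identical, or
{DUP, CNV} / {DEL, CNV}, in which case the non-CNV type wins). The
pairwise transitive-closure merge is iterated to a fixpoint because a
merged union span can create new qualifying pairs; this guarantees
idempotence.

## Spectra

Allele frequency is the non-reference **allele** frequency from
genotypes, alt alleles / called alleles (the top frequency bin
reaching 100% only makes sense for allele, not carrier, frequency); a
carrier-frequency alternative is available. Missing genotypes leave the
denominator; variants with no called genotype or frequency 0 are
excluded from the spectrum with a logged count. A singleton has exactly
one observed alt allele. Bins are left-open right-closed, matching the
"(0–1%]" notation: the frequency bins are (0–1], (1–2], (2–5], (5–10]
and deciles to 100%; the length bins are (0–250], (250–500],
(500–1000], (1000–2000], (2000–5000], (5000–10000] bp. Per-sample
summaries use the population (n) standard deviation. The genotype
matrix is samples × variants alt dosage with NaN for missing — suitable
for export to external PCA tooling; the PCA itself is out of scope. The
X chromosome is treated as diploid by default.

## The simulator

`simulate_truth` plants non-overlapping loci on a 5 × 10 Mb synthetic
genome (configurable), separated by at least twice the merge distance
so clustering cannot conflate distinct loci. Defaults describe a
short-read population callset: type mix 75% DEL / 19% DUP / 4% INS /
2% INV, log-uniform lengths 50 bp–10 kb, and a Beta(0.3, 3)
allele-frequency distribution giving the singleton-dominated spectrum
such cohorts show. Genotypes are Binomial(2, AF) per sample
(Hardy–Weinberg). Every operation is a pure function of its inputs and
a seed (caller-specific streams are derived from the truth seed, the
call seed and a CRC of the caller name, so no Python hash randomization
enters).

`emulate_sv_caller` reports each carried locus with the profile's
sensitivity, perturbs breakpoints by rounded Gaussian jitter, relabels
types through a stochastic confusion matrix, flips het↔hom genotypes at
the genotype-error rate, draws qualities from a normal model, and adds
Poisson false positives placed uniformly **away from planted loci** (by
rejection, padded by twice the merge distance) so that truth matching
stays unambiguous. `emulate_depth_caller` emits loss/gain calls for
carried DEL/DUP loci above a minimum length (5 kb default) with
boundaries snapped outward to 1 kb windows; insertions and inversions
are depth-invisible.

What the simulator does **not** emulate: read-level evidence,
alignment artefacts, correlated errors between callers (detections are
independent across tools, which is exactly what makes the binomial
s-of-k closed form the right oracle), locus-dependent sensitivity,
population structure beyond a two-subpopulation AF option, and real
chromosome-X ploidy. Passing recovery tests therefore demonstrate the
correctness of the merging logic under the stated error model, not
caller performance on real data.

`evaluate_recovery` matches carried truth loci to merged variants at
reciprocal overlap ≥ 0.5 (type-agnostic, since confusion may relabel)
and reports recall, precision, per-type recall and allele-frequency
error against the realized (not nominal) truth AF. `carrier_recall`
scores per-(sample, locus) recovery in the per-sample consensus — the
quantity the closed form `P(Bin(k, sens) ≥ s)` predicts.

## Numerical and determinism choices

- Rounding of printed percentages is half-up (`Decimal`), both for
  integer type percentages and one-decimal novelty percentages.
- All tie-breaks (stitch representative, cluster medoid, type vote,
  joint-merge ordering) are total orders, making every pipeline output
  a deterministic function of inputs and seeds.
- Degenerate inputs are errors, not silent passes: zero-length
  intervals in overlap computations, depth calls off the window grid,
  thresholds outside (0, 1], support values outside 1..k.
- Problem sizes used by the verification runs — up to 20 samples ×
  500 loci × 4 tools, oracle comparisons at n ≤ 200, 1,000-draw
  distribution checks — were chosen as the smallest scales at which the
  binomial and half-normal expectations have standard errors well below
  the effect sizes being checked.

## Known limitations

- Strand agreement is not enforced in clustering.
- Inter-chromosomal translocations survive merging as breakend records
  but carry no length; they are excluded from length caps, spectra
  binning by length class, and database comparison.
- The DGV-style type mapping and the any-overlap blacklist rule are
  declared assumptions, both configurable.
- No sequence-resolved breakpoint comparison (no FASTA handling) and no
  micro-homology analysis.
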