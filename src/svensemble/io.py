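"""Readers and writers for the formats the pipeline touches.

Per-caller SV VCFs are read with :mod:`pysam`; the merged population
callset is persisted as a multi-sample VCF 4.2 with ``SUPP``/``SUPP_VEC``
tool-support annotations.  DGV-style databases arrive as tab-separated
text, blacklists and region reports as BED3, gene models as GFF3 (via
gffutils) or BED12.

All reads are strictly validating: rejected records are counted and kept
in a parse report, never silently dropped.  Coordinates are converted to
0-based half-open on the way in and back to 1-based inclusive on the way
out.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam

from .core import (
    SV_TYPES,
    Genotype,
    GenomicInterval,
    SVCall,
    ValidationError,
)

__all__ = [
    "CallSet",
    "DGVRecord",
    "Gene",
    "GeneModel",
    "read_sv_vcf",
    "read_dgv",
    "write_merged_vcf",
    "read_merged_vcf",
    "read_regions",
    "write_regions",
    "read_gene_model",
    "DGV_TYPE_MAP",
]


class FormatError(ValueError):
    """Raised for malformed input files."""


def normalize_chrom(chrom: str, strip_chr: bool = True) -> str:
    """Normalize chromosome naming; by default ``chr1`` and ``1`` unify."""
    if strip_chr and chrom.lower().startswith("chr"):
        return chrom[3:]
    return chrom


# ---------------------------------------------------------------------------
# Call sets
# ---------------------------------------------------------------------------

@dataclass
class ParseReport:
    """Per-file account of rejected or problematic records."""

    n_records: int = 0
    n_calls: int = 0
    n_no_svtype: int = 0
    errors: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "n_calls": self.n_calls,
            "n_no_svtype": self.n_no_svtype,
            "n_errors": len(self.errors),
            "errors": list(self.errors),
        }


@dataclass
class CallSet:
    """A collection of SV calls from one caller, possibly many samples."""

    calls: list[SVCall]
    sample_ids: list[str]
    caller_id: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.sample_ids)
        for c in self.calls:
            if c.sample_id not in known:
                raise ValidationError(
                    f"call sample {c.sample_id!r} not in sample_ids"
                )

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)

    def replace_calls(self, calls: list[SVCall], **provenance) -> "CallSet":
        prov = {**self.provenance, **provenance}
        return CallSet(calls, self.sample_ids, self.caller_id, prov)


# ---------------------------------------------------------------------------
# Per-caller SV VCF reading
# ---------------------------------------------------------------------------

_BND_RE = re.compile(r"([\[\]])(?P<chrom>[^:\[\]]+):(?P<pos>\d+)([\[\]])")


def _bnd_orientation(alt: str) -> str | None:
    """Breakend orientation from the ALT bracket notation.

    '+' when local sequence precedes the bracket (``t[p[`` / ``t]p]``),
    '-' when it follows (``]p]t`` / ``[p[t``).
    """
    if not alt:
        return None
    if alt[0] in "[]":
        return "-"
    if alt[-1] in "[]":
        return "+"
    return None


def _parse_bnd_mate(alt: str) -> tuple[str, int] | None:
    m = _BND_RE.search(alt)
    if m is None:
        return None
    return m.group("chrom"), int(m.group("pos"))


def _genotype_from_gt(gt: tuple) -> Genotype:
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return Genotype(missing=True)
    alt = sum(1 for a in alleles if a > 0)
    ploidy = len(alleles)
    return Genotype(ref_alleles=ploidy - alt, alt_alleles=alt, ploidy=ploidy)


def read_sv_vcf(
    path: str | Path,
    caller_id: str | None = None,
    strip_chr: bool = True,
    sample_id: str | None = None,
) -> CallSet:
    """Read one caller's SV VCF into a :class:`CallSet`.

    Records lacking SVTYPE are rejected and counted; FILTER!=PASS records
    are retained with their filter label (pass-filtering is a separate,
    explicit stage).  Multi-allelic records are split into one call per
    ALT.  Negative SVLEN values (the deletion convention of some dialects)
    are normalized to absolute lengths.

    Calls are emitted per carrier sample (alt dosage >= 1).  A VCF without
    sample columns yields one heterozygous call per record, attributed to
    *sample_id* (default ``"sample0"``).
    """
    path = Path(path)
    caller_id = caller_id or path.stem
    report = ParseReport()
    calls: list[SVCall] = []

    with pysam.VariantFile(str(path)) as vf:
        vcf_samples = list(vf.header.samples)
        for rec in vf:
            report.n_records += 1
            info = dict(rec.info)
            svtype = info.get("SVTYPE")
            if isinstance(svtype, tuple):
                svtype = svtype[0]
            if svtype is None:
                report.n_no_svtype += 1
                continue
            svtype = str(svtype).upper()
            if svtype == "TRA":
                svtype = "BND"
            if svtype not in SV_TYPES:
                report.errors.append(
                    f"{rec.chrom}:{rec.pos}: unknown SVTYPE {svtype!r}"
                )
                continue

            chrom = normalize_chrom(rec.chrom, strip_chr)
            start = rec.start
            svlen_raw = info.get("SVLEN")
            if isinstance(svlen_raw, tuple):
                svlen_raw = svlen_raw[0]
            alts = rec.alts or (".",)

            filt = list(rec.filter.keys())
            filter_status = ";".join(filt) if filt else "."
            qual = float(rec.qual) if rec.qual is not None else 0.0

            for alt in alts:
                try:
                    call = _build_call(
                        rec, info, chrom, start, svtype, svlen_raw, alt,
                        qual, filter_status, strip_chr,
                    )
                except (ValidationError, ValueError) as exc:
                    report.errors.append(f"{rec.chrom}:{rec.pos}: {exc}")
                    continue
                if vcf_samples:
                    for smp in vcf_samples:
                        gt = rec.samples[smp].get("GT", (None,))
                        geno = _genotype_from_gt(gt)
                        if geno.missing or geno.alt_alleles == 0:
                            continue
                        calls.append(
                            call.with_(sample_id=smp, genotype=geno,
                                       caller_id=caller_id)
                        )
                else:
                    calls.append(
                        call.with_(sample_id=sample_id or "sample0",
                                   caller_id=caller_id)
                    )
            report.n_calls = len(calls)

    samples = vcf_samples or [sample_id or "sample0"]
    return CallSet(
        calls,
        sample_ids=samples,
        caller_id=caller_id,
        provenance={"path": str(path), "parse_report": report.as_dict()},
    )


def _build_call(rec, info, chrom, start, svtype, svlen_raw, alt,
                qual, filter_status, strip_chr) -> SVCall:
    """Construct an SVCall from one (record, ALT) pair."""
    if svtype == "BND":
        mate = _parse_bnd_mate(alt) if isinstance(alt, str) else None
        mate_id = info.get("MATEID")
        if isinstance(mate_id, tuple):
            mate_id = mate_id[0]
        return SVCall(
            interval=GenomicInterval(chrom, start, start + 1),
            svtype="BND",
            svlen=1,
            sample_id="", caller_id="",
            quality=qual, filter_status=filter_status,
            record_id=rec.id,
            mate_id=mate_id,
            bnd_orientation=_bnd_orientation(alt if isinstance(alt, str) else ""),
            mate_chrom=normalize_chrom(mate[0], strip_chr) if mate else None,
            mate_pos=mate[1] - 1 if mate else None,
        )

    svlen = abs(int(svlen_raw)) if svlen_raw is not None else None
    if svtype == "INS":
        if svlen is None:
            raise ValueError("INS record lacks SVLEN")
        interval = GenomicInterval(chrom, start, start + 1)
    else:
        # SVLEN is authoritative for the span when present: htslib derives
        # the record end from SVLEN for symbolic alleles (off by one from
        # the END field), so rec.stop is only trusted in its absence.
        if svlen is not None:
            end = start + svlen
        else:
            end = rec.stop
            if end - start <= len(rec.ref or "N"):
                raise ValueError("non-BND record lacks both END and SVLEN")
        interval = GenomicInterval(chrom, start, end)
        svlen = len(interval)
    return SVCall(
        interval=interval, svtype=svtype, svlen=svlen,
        sample_id="", caller_id="",
        quality=qual, filter_status=filter_status, record_id=rec.id,
    )


# ---------------------------------------------------------------------------
# Merged population VCF
# ---------------------------------------------------------------------------

_MERGED_INFOS = [
    ("SVTYPE", "1", "String", "Type of structural variant"),
    ("SVLEN", "1", "Integer", "Length of structural variant"),
    ("SUPP", "1", "Integer", "Number of supporting tools"),
    ("SUPP_VEC", "1", "String", "Tool support bitstring"),
]


def write_merged_vcf(popset, path: str | Path, tool_names=None) -> None:
    """Write a :class:`~svensemble.ensemble.PopulationCallSet` as VCF 4.2.

    INFO carries SVTYPE/SVLEN/END plus SUPP (tool-support count) and
    SUPP_VEC (bitstring over the ordered tool panel); FORMAT is GT only.
    Reading the file back reproduces the variant set.
    """
    header = pysam.VariantHeader()
    contigs: dict[str, int] = {}
    for v in popset.variants:
        contigs[v.interval.chrom] = max(
            contigs.get(v.interval.chrom, 0), v.interval.end + 1
        )
    for chrom, length in sorted(contigs.items()):
        header.contigs.add(chrom, length=length)
    for name, number, vtype, desc in _MERGED_INFOS:
        header.info.add(name, number, vtype, desc)
    header.formats.add("GT", "1", "String", "Genotype")
    if tool_names:
        header.add_meta("tool_panel", ",".join(tool_names))
    for s in popset.sample_ids:
        header.add_sample(s)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in popset.variants:
            stop = v.interval.end if v.svtype != "INS" else v.interval.start + 1
            rec = out.new_record(
                contig=v.interval.chrom,
                start=v.interval.start,
                stop=stop,
                alleles=("N", f"<{v.svtype}>"),
                id=v.id,
            )
            rec.stop = stop  # new_record's stop kwarg writes END one too high
            rec.info["SVTYPE"] = v.svtype
            rec.info["SVLEN"] = v.svlen
            rec.info["SUPP"] = int(sum(v.supp_vec))
            rec.info["SUPP_VEC"] = "".join("1" if b else "0" for b in v.supp_vec)
            for s in popset.sample_ids:
                g = v.genotypes.get(s)
                if g is None or g.missing:
                    rec.samples[s]["GT"] = (None, None)
                else:
                    gt = [1] * g.alt_alleles + [0] * g.ref_alleles
                    rec.samples[s]["GT"] = tuple(sorted(gt))
            out.write(rec)


def read_merged_vcf(path: str | Path, strip_chr: bool = True):
    """Read a merged multi-sample VCF back into a PopulationCallSet."""
    from .ensemble import MergedVariant, PopulationCallSet

    variants = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            info = dict(rec.info)
            svtype = info["SVTYPE"]
            chrom = normalize_chrom(rec.chrom, strip_chr)
            svlen = abs(int(info.get("SVLEN", rec.stop - rec.start)))
            if svtype == "INS":
                interval = GenomicInterval(chrom, rec.start, rec.start + 1)
            elif "SVLEN" in info:
                # htslib derives rec.stop from SVLEN with an extra base
                interval = GenomicInterval(chrom, rec.start, rec.start + svlen)
            else:
                interval = GenomicInterval(chrom, rec.start, rec.stop)
            supp_vec_str = info.get("SUPP_VEC", "1")
            supp_vec = tuple(c == "1" for c in supp_vec_str)
            genos = {}
            for s in samples:
                genos[s] = _genotype_from_gt(rec.samples[s].get("GT", (None,)))
            variants.append(
                MergedVariant(
                    interval=interval, svtype=svtype, svlen=svlen,
                    supp_vec=supp_vec, genotypes=genos,
                    id=rec.id or f"{chrom}:{rec.start}:{svtype}",
                )
            )
    return PopulationCallSet(variants=variants, sample_ids=samples)


# ---------------------------------------------------------------------------
# DGV-style databases
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DGVRecord:
    accession: str
    interval: GenomicInterval
    variant_type: str  # mapped to the internal vocabulary


#: Mapping from DGV type vocabulary to internal SV types.  Unmapped types
#: fall back to CNV, which acts as a wildcard in type-aware matching.
DGV_TYPE_MAP = {
    "deletion": "DEL",
    "loss": "DEL",
    "duplication": "DUP",
    "gain": "DUP",
    "insertion": "INS",
    "novel sequence insertion": "INS",
    "mobile element insertion": "INS",
    "inversion": "INV",
    "cnv": "CNV",
    "gain+loss": "CNV",
    "complex": "CNV",
}

_DGV_COLUMNS = {
    "accession": ("variantaccession", "accession", "id"),
    "chrom": ("chr", "chromosome", "chrom"),
    "start": ("start",),
    "end": ("end",),
    "type": ("variantsubtype", "varianttype", "type"),
}


def read_dgv(
    path: str | Path,
    type_map: dict[str, str] | None = None,
    strip_chr: bool = True,
) -> list[DGVRecord]:
    """Read a DGV-style tab-separated database.

    DGV coordinates are 1-based inclusive and converted to 0-based
    half-open.  Rows with ``end < start`` are rejected and counted;
    duplicate accessions raise.  Unplaced contigs are retained (matching
    is by chromosome string).
    """
    type_map = {**DGV_TYPE_MAP, **(type_map or {})}
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]

    cols = {}
    for key, candidates in _DGV_COLUMNS.items():
        found = next((c for c in candidates if c in df.columns), None)
        if found is None:
            raise FormatError(
                f"DGV file missing required column for {key!r} "
                f"(expected one of {candidates})"
            )
        cols[key] = found

    records: list[DGVRecord] = []
    seen: set[str] = set()
    n_rejected = 0
    for _, row in df.iterrows():
        acc = row[cols["accession"]]
        if acc in seen:
            raise FormatError(f"duplicate DGV accession {acc!r}")
        seen.add(acc)
        start, end = int(row[cols["start"]]) - 1, int(row[cols["end"]])
        if end < start or start < 0:
            n_rejected += 1
            continue
        raw_type = str(row[cols["type"]]).strip().lower()
        records.append(
            DGVRecord(
                accession=acc,
                interval=GenomicInterval(
                    normalize_chrom(str(row[cols["chrom"]]), strip_chr),
                    start, end,
                ),
                variant_type=type_map.get(raw_type, "CNV"),
            )
        )
    if n_rejected:
        import logging
        logging.getLogger(__name__).warning(
            "read_dgv: rejected %d rows with invalid coordinates", n_rejected
        )
    return records


# ---------------------------------------------------------------------------
# BED regions
# ---------------------------------------------------------------------------

def read_regions(path: str | Path, strip_chr: bool = True) -> list[GenomicInterval]:
    """Read BED3+ into 0-based half-open intervals (preserved exactly)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if end < start or start < 0:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval [{start},{end})"
                )
            intervals.append(
                GenomicInterval(normalize_chrom(parts[0], strip_chr), start, end)
            )
    return intervals


def write_regions(intervals, path: str | Path) -> None:
    """Write intervals as BED3 (0-based half-open, unchanged)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gene:
    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    strand: str = "+"


class GeneModel:
    """A set of genes with merged exon intervals, indexed by chromosome."""

    def __init__(self, genes: list[Gene]):
        from intervaltree import IntervalTree

        self.genes = list(genes)
        self._trees: dict[str, "IntervalTree"] = {}
        for g in self.genes:
            tree = self._trees.setdefault(g.interval.chrom, IntervalTree())
            tree.addi(g.interval.start, g.interval.end, g)

    def __len__(self) -> int:
        return len(self.genes)

    def genes_overlapping(self, interval: GenomicInterval) -> list[Gene]:
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        hits = tree.overlap(interval.start, interval.end)
        return sorted((h.data for h in hits), key=lambda g: (g.interval, g.gene_id))

    def genes_contained_in(self, interval: GenomicInterval) -> list[Gene]:
        return [
            g for g in self.genes_overlapping(interval)
            if interval.contains(g.interval)
        ]


def _merge_intervals(ivs: list[GenomicInterval]) -> tuple[GenomicInterval, ...]:
    if not ivs:
        return ()
    ivs = sorted(ivs, key=lambda i: (i.start, i.end))
    merged = [ivs[0]]
    for iv in ivs[1:]:
        if iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return tuple(merged)


def read_gene_model(path: str | Path, strip_chr: bool = True) -> GeneModel:
    """Read a gene model from GFF3 (via gffutils) or BED12.

    The gene span is transcription start to end; exons are merged across
    transcripts so UTR-containing exons count as exonic sequence.
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3", ".gtf"}:
        return _read_gff3(path, strip_chr)
    return _read_bed12(path, strip_chr)


def _read_gff3(path: Path, strip_chr: bool) -> GeneModel:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:",
        merge_strategy="create_unique", keep_order=True,
    )
    genes = []
    for feat in db.features_of_type("gene"):
        chrom = normalize_chrom(feat.seqid, strip_chr)
        gene_iv = GenomicInterval(chrom, feat.start - 1, feat.end)
        exons = [
            GenomicInterval(chrom, e.start - 1, e.end)
            for e in db.children(feat, featuretype="exon")
        ]
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            Gene(gene_id, gene_iv, _merge_intervals(exons), feat.strand or "+")
        )
    return GeneModel(genes)


def _read_bed12(path: Path, strip_chr: bool) -> GeneModel:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 BED columns")
            chrom = normalize_chrom(parts[0], strip_chr)
            start, end = int(parts[1]), int(parts[2])
            name, strand = parts[3], parts[5]
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            exons = [
                GenomicInterval(chrom, start + off, start + off + size)
                for off, size in zip(offsets, sizes)
            ]
            genes.append(
                Gene(name, GenomicInterval(chrom, start, end),
                     _merge_intervals(exons), strand)
            )
    return GeneModel(genes)
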