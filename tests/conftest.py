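"""Shared fixtures: tiny call builders, toy gene models, toy databases."""

from __future__ import annotations

import pytest

from svensemble import Gene, GeneModel, Genotype, GenomicInterval, SVCall
from svensemble.io import DGVRecord


def make_call(
    chrom="1",
    start=1000,
    end=1250,
    svtype="DEL",
    svlen=None,
    sample="S0",
    caller="toolA",
    quality=50.0,
    **kwargs,
):
    """Convenience SVCall builder with sensible defaults."""
    if svtype == "INS":
        interval = GenomicInterval(chrom, start, start + 1)
        svlen = svlen if svlen is not None else 100
    else:
        interval = GenomicInterval(chrom, start, end)
        svlen = end - start
    return SVCall(
        interval=interval,
        svtype=svtype,
        svlen=svlen,
        sample_id=sample,
        caller_id=caller,
        quality=quality,
        genotype=kwargs.pop("genotype", Genotype(1, 1)),
        **kwargs,
    )


@pytest.fixture
def toy_gene_model() -> GeneModel:
    """Three genes on chrom 1: two-exon, single-exon, and one on chrom 2."""
    return GeneModel([
        Gene(
            "geneA",
            GenomicInterval("1", 10_000, 20_000),
            exons=(GenomicInterval("1", 10_000, 10_500),
                   GenomicInterval("1", 19_000, 20_000)),
        ),
        Gene(
            "geneB",
            GenomicInterval("1", 50_000, 52_000),
            exons=(GenomicInterval("1", 50_000, 52_000),),
        ),
        Gene(
            "geneC",
            GenomicInterval("2", 5_000, 9_000),
            exons=(GenomicInterval("2", 5_000, 5_200),
                   GenomicInterval("2", 8_800, 9_000)),
        ),
    ])


@pytest.fixture
def toy_dgv() -> list[DGVRecord]:
    return [
        DGVRecord("dgv1", GenomicInterval("1", 1_000, 2_000), "DEL"),
        DGVRecord("dgv2", GenomicInterval("1", 10_000, 10_300), "DUP"),
        DGVRecord("dgv3", GenomicInterval("2", 500, 1_500), "CNV"),
    ]
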