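import numpy as np
import pytest

from pansv import (
    AnnotationIndex,
    GeneModel,
    GenomicInterval,
    MergedSV,
    PipelineConfig,
    SVCall,
    SVType,
    TEInterval,
)


@pytest.fixture
def cfg():
    return PipelineConfig()


@pytest.fixture
def toy_index():
    """Two genes on a 1 Mb chromosome, far enough apart that +-5 kb flanks
    never compete; gene A on '+' with two exons, gene B on '-' single-exon."""
    gene_a = GeneModel(
        gene_id="geneA",
        span=GenomicInterval("chr1", 100_000, 110_000),
        strand="+",
        exons=(
            GenomicInterval("chr1", 100_000, 103_000),
            GenomicInterval("chr1", 107_000, 110_000),
        ),
    )
    gene_b = GeneModel(
        gene_id="geneB",
        span=GenomicInterval("chr1", 500_000, 504_000),
        strand="-",
        exons=(GenomicInterval("chr1", 500_000, 504_000),),
    )
    tes = [
        TEInterval(GenomicInterval("chr1", 200_000, 260_000), "LTR/Gypsy"),
        TEInterval(GenomicInterval("chr1", 300_000, 301_000), "LTR/Copia"),
    ]
    return AnnotationIndex(
        genes=[gene_a, gene_b], tes=tes, chrom_lengths={"chr1": 1_000_000}
    )


def make_absence(chrom, start, end, accession="GS", caller="syri-like", id=""):
    iv = GenomicInterval(chrom, start, end)
    return SVCall(
        interval=iv,
        sv_type=SVType.ABSENCE,
        sv_length=iv.length,
        accession=accession,
        caller=caller,
        id=id or f"{accession}.{caller}.{chrom}:{start}-{end}",
    )


def make_presence(chrom, anchor, length, accession="GS", caller="syri-like", id=""):
    return SVCall(
        interval=GenomicInterval(chrom, anchor, anchor + 1),
        sv_type=SVType.PRESENCE,
        sv_length=length,
        accession=accession,
        caller=caller,
        id=id or f"{accession}.{caller}.{chrom}:{anchor}+{length}",
    )


def make_merged(chrom, start, end, sv_type=SVType.ABSENCE, accessions=("GS",),
                sv_length=None, members=None, **kw):
    iv = GenomicInterval(chrom, start, end)
    return MergedSV(
        representative=iv,
        sv_type=sv_type,
        sv_length=sv_length if sv_length is not None else iv.length,
        members=tuple(members or (f"m.{chrom}:{start}-{end}",)),
        accessions=frozenset(accessions),
        **kw,
    )
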