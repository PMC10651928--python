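"""Readers and writers for all external formats.

Internal coordinates are 0-based half-open.  The BED dialect is already
0-based; GFF3 and VCF are converted from their 1-based inclusive
conventions on the way in and back on the way out, so a VCF record at
POS=1000 with END=1099 becomes the internal interval [999, 1099).

Presence (insertion) SVs are encoded in BED as a 1 bp anchor
(start, start+1) with the inserted length in the length column, and in
VCF as SVTYPE=INS with SVLEN.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
import pysam
import yaml

from .errors import FormatError, ValidationError
from .model import GenomicInterval, MergedSV, PipelineConfig, SVCall, SVType
from .panclusters import ClusterPresence
from .svannot import AnnotationIndex, GeneModel, TEInterval
from .cnv import AlignmentHit

logger = logging.getLogger(__name__)

_VCF_TYPE = {
    SVType.PRESENCE: "INS",
    SVType.ABSENCE: "DEL",
    SVType.INVERSION: "INV",
    SVType.TRANSLOCATION: "TRA",
}
_VCF_TYPE_REV = {v: k for k, v in _VCF_TYPE.items()}


# ---------------------------------------------------------------------------
# SV callsets


def read_sv_callset(path: str | Path, dialect: str = "bed") -> list[SVCall]:
    """Read an SV callset; returns records sorted by (chrom, start, end)."""
    if dialect == "bed":
        calls = _read_sv_bed(Path(path))
    elif dialect == "vcf":
        calls = _read_sv_vcf(Path(path))
    else:
        raise ValidationError(f"unknown SV dialect {dialect!r}")
    if not calls:
        logger.warning("no SV records in %s", path)
    return sorted(calls, key=lambda c: (c.chrom, c.start, c.interval.end, c.id))


def _read_sv_bed(path: Path) -> list[SVCall]:
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 6 tab-separated columns, got {len(fields)}"
                )
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                sv_type = SVType.coerce(fields[3])
                sv_length = int(fields[4])
                accession = fields[5]
                caller = fields[6] if len(fields) > 6 else ""
                record_id = fields[7] if len(fields) > 7 else f"{path.stem}:{lineno}"
                calls.append(
                    SVCall(
                        interval=GenomicInterval(chrom, start, end),
                        sv_type=sv_type,
                        sv_length=sv_length,
                        accession=accession,
                        caller=caller,
                        id=record_id,
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return calls


def write_sv_callset(
    calls: Iterable[SVCall], path: str | Path, dialect: str = "bed",
    chrom_lengths: Mapping[str, int] | None = None,
) -> None:
    if dialect == "bed":
        _write_sv_bed(calls, Path(path))
    elif dialect == "vcf":
        _write_sv_vcf(calls, Path(path), chrom_lengths or {})
    else:
        raise ValidationError(f"unknown SV dialect {dialect!r}")


def _write_sv_bed(calls: Iterable[SVCall], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tsv_type\tsv_length\taccession\tcaller\tid\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.interval.start}\t{c.interval.end}\t{c.sv_type.value}"
                f"\t{c.sv_length}\t{c.accession}\t{c.caller}\t{c.id}\n"
            )


def _vcf_header(chrom_lengths: Mapping[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in sorted(chrom_lengths):
        header.contigs.add(chrom, length=chrom_lengths[chrom])
    header.info.add("SVTYPE", 1, "String", "Structural variant type")
    header.info.add("END", 1, "Integer", "End position (1-based inclusive)")
    header.info.add("SVLEN", 1, "Integer", "SV length")
    header.info.add("ACC", 1, "String", "Accession identifier")
    header.info.add("CALLER", 1, "String", "Caller identifier")
    for alt in ("INS", "DEL", "INV", "TRA"):
        header.add_line(f'##ALT=<ID={alt},Description="{alt}">')
    return header


def _write_sv_vcf(
    calls: Iterable[SVCall], path: Path, chrom_lengths: Mapping[str, int]
) -> None:
    calls = list(calls)
    lengths = dict(chrom_lengths)
    for c in calls:
        lengths.setdefault(c.chrom, 0)
        lengths[c.chrom] = max(lengths[c.chrom], c.interval.end + 1)
    header = _vcf_header(lengths)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for c in sorted(calls, key=lambda c: (c.chrom, c.start, c.id)):
            rec = vcf.new_record(
                contig=c.chrom,
                start=c.interval.start,  # pysam uses 0-based start
                stop=c.interval.end,
                alleles=("N", f"<{_VCF_TYPE[c.sv_type]}>"),
                id=c.id or None,
            )
            rec.info["SVTYPE"] = _VCF_TYPE[c.sv_type]
            if c.sv_type is SVType.PRESENCE:
                # SVLEN only for insertions: htslib rederives END from SVLEN
                # for other symbolic alleles, and END already carries length
                rec.info["SVLEN"] = c.sv_length
            rec.info["ACC"] = c.accession or "."
            if c.caller:
                rec.info["CALLER"] = c.caller
            vcf.write(rec)


def _read_sv_vcf(path: Path) -> list[SVCall]:
    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            name = rec.id or f"{path.stem}:{rec.chrom}:{rec.pos}"
            if "SVTYPE" not in rec.info:
                raise FormatError(f"{path}: record {name} lacks INFO/SVTYPE")
            svtype_code = str(rec.info["SVTYPE"])
            if svtype_code not in _VCF_TYPE_REV:
                raise FormatError(
                    f"{path}: record {name} has unsupported SVTYPE {svtype_code}"
                )
            sv_type = _VCF_TYPE_REV[svtype_code]
            # pysam: rec.start = POS-1, rec.stop = INFO/END (0-based exclusive)
            start, end = rec.start, rec.stop
            if sv_type is SVType.PRESENCE:
                if "SVLEN" not in rec.info:
                    raise FormatError(f"{path}: INS record {name} lacks INFO/SVLEN")
                sv_length = abs(int(_scalar(rec.info["SVLEN"])))
                interval = GenomicInterval(rec.chrom, start, start + 1)
            else:
                if end <= start:
                    raise FormatError(f"{path}: record {name} has END <= POS")
                interval = GenomicInterval(rec.chrom, start, end)
                sv_length = interval.length
            try:
                calls.append(
                    SVCall(
                        interval=interval,
                        sv_type=sv_type,
                        sv_length=sv_length,
                        accession=str(rec.info["ACC"]) if "ACC" in rec.info else "",
                        caller=str(rec.info["CALLER"]) if "CALLER" in rec.info else "",
                        id=name,
                    )
                )
            except ValidationError as exc:
                raise FormatError(f"{path}: record {name}: {exc}") from exc
    return calls


# ---------------------------------------------------------------------------
# merged SV tables


def write_merged_svs(merged: Iterable[MergedSV], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tstart\tend\tsv_type\tsv_length\tfrequency\taccessions"
            "\tmin_pair_ratio\tte_class\tmembers\n"
        )
        for m in merged:
            ratio = "" if m.min_pair_ratio is None else f"{m.min_pair_ratio:.6f}"
            fh.write(
                f"{m.chrom}\t{m.representative.start}\t{m.representative.end}"
                f"\t{m.sv_type.value}\t{m.sv_length}\t{m.frequency}"
                f"\t{','.join(sorted(m.accessions))}\t{ratio}"
                f"\t{m.inserted_te_class or ''}\t{','.join(m.members)}\n"
            )


def read_merged_svs(path: str | Path) -> list[MergedSV]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise FormatError(f"{path}:{lineno}: expected 10 columns")
            out.append(
                MergedSV(
                    representative=GenomicInterval(f[0], int(f[1]), int(f[2])),
                    sv_type=SVType.coerce(f[3]),
                    sv_length=int(f[4]),
                    members=tuple(f[9].split(",")) if f[9] else ("?",),
                    accessions=frozenset(f[6].split(",")),
                    min_pair_ratio=float(f[7]) if f[7] else None,
                    inserted_te_class=f[8] or None,
                )
            )
    return out


# ---------------------------------------------------------------------------
# annotation


def read_annotation(
    gff_path: str | Path,
    te_path: str | Path | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> AnnotationIndex:
    """Build an :class:`AnnotationIndex` from GFF3 gene models.

    Introns are derived as gaps between consecutive exons of the same
    transcript; the CDS span is taken over all CDS features of the gene.
    TE intervals come from ``te_path`` (BED with a class column, or GFF3).
    """
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        exons = [
            GenomicInterval(ex.seqid, ex.start - 1, ex.end)
            for ex in db.children(gene, featuretype="exon")
        ]
        cds = [
            GenomicInterval(c.seqid, c.start - 1, c.end)
            for c in db.children(gene, featuretype="CDS")
        ]
        span = GenomicInterval(gene.seqid, gene.start - 1, gene.end)
        if not exons:
            exons = [span]
        try:
            genes.append(
                GeneModel(
                    gene_id=gene.id,
                    span=span,
                    strand=gene.strand if gene.strand in "+-" else "+",
                    exons=tuple(sorted(exons, key=lambda e: e.start)),
                    cds_span=(
                        GenomicInterval(
                            span.chrom,
                            min(c.start for c in cds),
                            max(c.end for c in cds),
                        )
                        if cds
                        else None
                    ),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{gff_path}: gene {gene.id}: {exc}") from exc
    tes = read_te_annotation(te_path) if te_path else []
    return AnnotationIndex(genes=genes, tes=tes, chrom_lengths=chrom_lengths)


def read_te_annotation(path: str | Path) -> list[TEInterval]:
    path = Path(path)
    tes: list[TEInterval] = []
    if path.suffix == ".bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) < 4:
                    raise FormatError(f"{path}:{lineno}: expected 4 columns")
                tes.append(
                    TEInterval(GenomicInterval(f[0], int(f[1]), int(f[2])), f[3])
                )
    else:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, merge_strategy="create_unique"
        )
        for feat in db.all_features():
            cls = feat.attributes.get("Class", [feat.featuretype])[0]
            tes.append(
                TEInterval(GenomicInterval(feat.seqid, feat.start - 1, feat.end), cls)
            )
    return tes


def write_annotation_gff3(index: AnnotationIndex, path: str | Path) -> None:
    """Write gene models (gene/mRNA/exon) as GFF3, 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in index.genes:
            s = g.span
            fh.write(
                f"{s.chrom}\tpansv\tgene\t{s.start + 1}\t{s.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            fh.write(
                f"{s.chrom}\tpansv\tmRNA\t{s.start + 1}\t{s.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            for i, ex in enumerate(g.exons, 1):
                fh.write(
                    f"{s.chrom}\tpansv\texon\t{ex.start + 1}\t{ex.end}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.e{i};Parent={g.gene_id}.t1\n"
                )


def write_te_bed(tes: Sequence[TEInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for te in tes:
            iv = te.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{te.te_class}\n")


# ---------------------------------------------------------------------------
# matrices and tables


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Gene x accession TSV with a header row of accession identifiers."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate gene id(s): {sorted(set(dup))}")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ValidationError(f"{path}: missing cells in rows {bad[:5]}")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_cluster_membership(path: str | Path) -> list[ClusterPresence]:
    """TSV (cluster_id, accession, gene_id) -> per-cluster presence counts."""
    df = pd.read_csv(
        path, sep="\t", comment="#", names=["cluster_id", "accession", "gene_id"],
        header=None, skip_blank_lines=True,
    )
    if df.iloc[0].tolist() == ["cluster_id", "accession", "gene_id"]:
        df = df.iloc[1:]
    clusters = []
    for cid, group in df.groupby("cluster_id", sort=True):
        counts = group.groupby("accession")["gene_id"].nunique().to_dict()
        clusters.append(ClusterPresence(cluster_id=str(cid), presence=counts))
    return clusters


def write_cluster_membership(
    clusters: Sequence[ClusterPresence], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\taccession\tgene_id\n")
        for cl in clusters:
            for acc in sorted(cl.presence):
                for k in range(cl.presence[acc]):
                    fh.write(f"{cl.cluster_id}\t{acc}\t{cl.cluster_id}_{acc}_{k}\n")


def read_anchor_pairs(path: str | Path) -> list[tuple[str, str]]:
    """TSV of collinearity anchors (geneA, geneB[, block_id])."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 2:
                raise FormatError(f"{path}:{lineno}: expected >= 2 columns")
            pairs.append((f[0], f[1]))
    return pairs


def read_hits(path: str | Path) -> list[AlignmentHit]:
    """TSV (gene_id, accession, chrom, start, end, identity, coverage)."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            f = line.split("\t")
            if len(f) < 7:
                raise FormatError(f"{path}:{lineno}: expected 7 columns")
            try:
                hits.append(
                    AlignmentHit(
                        gene_id=f[0],
                        accession=f[1],
                        interval=GenomicInterval(f[2], int(f[3]), int(f[4])),
                        identity=float(f[5]),
                        coverage=float(f[6]),
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, length = line.split("\t")[:2]
            sizes[chrom] = int(length)
    return sizes


# ---------------------------------------------------------------------------
# configuration


def read_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "callers" in data:
        data["callers"] = tuple(data["callers"])
    return PipelineConfig(**data)


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(cfg).items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def _scalar(value):
    if isinstance(value, (tuple, list)):
        return value[0]
    return value
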