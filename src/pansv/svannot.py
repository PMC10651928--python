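"""Genomic-context annotation of SVs.

Every SV receives exactly one context label relative to the gene
annotation — exon, intron, promoter (the flank 5' of the coding span on
the gene's strand), downstream flank, or intergenic — with precedence
exon > intron > promoter > downstream_flank.  Exclusive labelling makes
context counts partition the SV set.  The module also profiles breakpoint
distances from gene boundaries, measures the TE composition of PAVs, and
bins PAV density per Mb.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .errors import ValidationError
from .model import (
    GenomicInterval,
    MergedSV,
    PipelineConfig,
    SVType,
    PAV_TYPES,
)

CONTEXT_LABELS = ("promoter", "exon", "intron", "downstream_flank", "intergenic")
#: label precedence when an SV touches several features of one gene
PRECEDENCE = ("exon", "intron", "promoter", "downstream_flank")


@dataclass(frozen=True)
class GeneModel:
    """A gene with its exon chain; introns are the gaps between exons."""

    gene_id: str
    span: GenomicInterval
    strand: str
    exons: tuple[GenomicInterval, ...]
    cds_span: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be '+' or '-'")
        for ex in self.exons:
            if ex.chrom != self.span.chrom or ex.start < self.span.start or ex.end > self.span.end:
                raise ValidationError(
                    f"gene {self.gene_id}: exon [{ex.start}, {ex.end}) outside gene span"
                )

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        exons = sorted(self.exons, key=lambda e: e.start)
        out = []
        for left, right in zip(exons, exons[1:]):
            if right.start > left.end:
                out.append(GenomicInterval(self.span.chrom, left.end, right.start))
        return tuple(out)

    @property
    def coding_span(self) -> GenomicInterval:
        """CDS span if annotated, else the full gene span."""
        return self.cds_span or self.span

    def promoter(self, flank: int) -> GenomicInterval | None:
        cds = self.coding_span
        if self.strand == "+":
            start, end = cds.start - flank, cds.start
        else:
            start, end = cds.end, cds.end + flank
        start = max(0, start)
        return GenomicInterval(cds.chrom, start, end) if start < end else None

    def downstream(self, flank: int) -> GenomicInterval | None:
        cds = self.coding_span
        if self.strand == "+":
            start, end = cds.end, cds.end + flank
        else:
            start, end = cds.start - flank, cds.start
        start = max(0, start)
        return GenomicInterval(cds.chrom, start, end) if start < end else None


@dataclass(frozen=True)
class TEInterval:
    interval: GenomicInterval
    te_class: str


class AnnotationIndex:
    """Gene models plus TE intervals, queryable by interval overlap."""

    def __init__(
        self,
        genes: Sequence[GeneModel],
        tes: Sequence[TEInterval] = (),
        chrom_lengths: Mapping[str, int] | None = None,
    ) -> None:
        self.genes = list(genes)
        self.tes = list(tes)
        self.chrom_lengths = dict(chrom_lengths or {})
        for te in self.tes:
            limit = self.chrom_lengths.get(te.interval.chrom)
            if limit is not None and te.interval.end > limit:
                raise ValidationError(
                    f"TE interval ends at {te.interval.end} beyond chromosome "
                    f"{te.interval.chrom} length {limit}"
                )
        self._gene_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._te_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for g in self.genes:
            self._gene_trees[g.span.chrom].addi(g.span.start, g.span.end, g)
        for te in self.tes:
            self._te_trees[te.interval.chrom].addi(
                te.interval.start, te.interval.end, te
            )

    def genes_overlapping(self, iv: GenomicInterval) -> list[GeneModel]:
        hits = self._gene_trees[iv.chrom].overlap(iv.start, iv.end)
        return sorted((h.data for h in hits), key=lambda g: (g.span.start, g.gene_id))

    def tes_overlapping(self, iv: GenomicInterval) -> list[TEInterval]:
        hits = self._te_trees[iv.chrom].overlap(iv.start, iv.end)
        return sorted(
            (h.data for h in hits), key=lambda t: (t.interval.start, t.te_class)
        )


def _label_for_gene(sv_iv: GenomicInterval, gene: GeneModel, flank: int) -> str | None:
    """Highest-precedence feature of ``gene`` that the SV touches, if any."""
    if any(sv_iv.intersection_length(ex) > 0 for ex in gene.exons):
        return "exon"
    if any(sv_iv.intersection_length(intr) > 0 for intr in gene.introns):
        return "intron"
    prom = gene.promoter(flank)
    if prom is not None and sv_iv.intersection_length(prom) > 0:
        return "promoter"
    down = gene.downstream(flank)
    if down is not None and sv_iv.intersection_length(down) > 0:
        return "downstream_flank"
    # inside the gene span but in neither exon nor intron can only happen for
    # degenerate annotations; treat as intron-like gene body
    if sv_iv.intersection_length(gene.span) > 0:
        return "intron"
    return None


def assign_context(
    sv: MergedSV, index: AnnotationIndex, cfg: PipelineConfig
) -> str:
    """Exclusive context label for one SV.

    The SV is widened by the context flank to collect candidate genes; among
    genes it touches (body or flank) the one with the largest overlap wins,
    ties broken by leftmost gene, and that gene's highest-precedence touched
    feature becomes the label.
    """
    iv = sv.representative
    query = GenomicInterval(
        iv.chrom, max(0, iv.start - cfg.context_flank), iv.end + cfg.context_flank
    )
    best: tuple[int, int, str, str] | None = None  # (-overlap, start, id, label)
    for gene in index.genes_overlapping(query):
        label = _label_for_gene(iv, gene, cfg.context_flank)
        if label is None:
            continue
        overlap = iv.intersection_length(gene.span)
        key = (-overlap, gene.span.start, gene.gene_id)
        if best is None or key < best[:3]:
            best = (*key, label)
    return best[3] if best is not None else "intergenic"


def context_counts(
    svs: Iterable[MergedSV], index: AnnotationIndex, cfg: PipelineConfig
) -> dict[str, int]:
    """Counts per context label; labels partition the SV set."""
    counts = Counter({label: 0 for label in CONTEXT_LABELS})
    for sv in svs:
        counts[assign_context(sv, index, cfg)] += 1
    return dict(counts)


def gene_associated_count(counts: Mapping[str, int]) -> int:
    """SVs overlapping genes or their flanking regulatory sequence."""
    return sum(counts.get(k, 0) for k in PRECEDENCE)


def _breakpoints(sv: MergedSV) -> list[int]:
    iv = sv.representative
    if sv.sv_type is SVType.PRESENCE:
        return [iv.start]  # insertion anchors contribute one breakpoint
    return [iv.start, iv.end]


def breakpoint_distance_profile(
    svs: Iterable[MergedSV], index: AnnotationIndex, cfg: PipelineConfig
) -> dict[str, np.ndarray]:
    """Two-sided histogram of breakpoint distances from gene boundaries.

    For every SV breakpoint outside any gene span but within the context
    flank of its nearest gene, the distance to that gene's nearest boundary
    is binned into ``profile_bin``-sized bins, separately for the gene's
    upstream (5') and downstream (3') side.  Breakpoints inside genes do
    not contribute.
    """
    n_bins = cfg.context_flank // cfg.profile_bin
    profile = {
        "upstream": np.zeros(n_bins, dtype=int),
        "downstream": np.zeros(n_bins, dtype=int),
    }
    for sv in svs:
        for p in _breakpoints(sv):
            chrom = sv.chrom
            query = GenomicInterval(
                chrom, max(0, p - cfg.context_flank), p + cfg.context_flank + 1
            )
            genes = index.genes_overlapping(query)
            if not genes:
                continue
            best: tuple[int, str] | None = None  # (distance, side wrt strand)
            inside = False
            for g in genes:
                if g.span.start <= p < g.span.end:
                    inside = True
                    break
                if p < g.span.start:
                    dist, left_side = g.span.start - p, True
                else:
                    dist, left_side = p - g.span.end + 1, False
                side = (
                    "upstream"
                    if (left_side == (g.strand == "+"))
                    else "downstream"
                )
                if best is None or dist < best[0]:
                    best = (dist, side)
            if inside or best is None or best[0] >= cfg.context_flank:
                continue
            profile[best[1]][best[0] // cfg.profile_bin] += 1
    return profile


def _te_coverage(iv: GenomicInterval, index: AnnotationIndex) -> dict[str, int]:
    """Covered bases per TE class within ``iv`` (classwise union of overlaps)."""
    per_class: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for te in index.tes_overlapping(iv):
        s = max(iv.start, te.interval.start)
        e = min(iv.end, te.interval.end)
        per_class[te.te_class].append((s, e))
    covered: dict[str, int] = {}
    for cls, segs in per_class.items():
        segs.sort()
        total, cur_s, cur_e = 0, None, None
        for s, e in segs:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s
        covered[cls] = total
    return covered


def te_composition(
    pavs: Iterable[MergedSV], index: AnnotationIndex, cfg: PipelineConfig
) -> tuple[float, dict[str, float]]:
    """(fraction of PAVs that are TE-derived, fraction of all PAVs per class).

    An absence PAV is TE-derived when at least ``te_overlap_frac`` of its
    reference interval is covered by TE annotation; its class is the one
    covering the most bases.  A presence PAV is TE-derived when its inserted
    sequence carries a TE annotation (``inserted_te_class``).
    """
    pavs = [p for p in pavs if p.sv_type in PAV_TYPES]
    if not pavs:
        return 0.0, {}
    n_te = 0
    class_counts: Counter[str] = Counter()
    for pav in pavs:
        if pav.sv_type is SVType.PRESENCE:
            if pav.inserted_te_class is not None:
                n_te += 1
                class_counts[pav.inserted_te_class] += 1
            continue
        cov = _te_coverage(pav.representative, index)
        if not cov:
            continue
        # class union may overlap between classes; total TE cover is bounded
        # by the interval length
        total = min(sum(cov.values()), pav.representative.length)
        if total / pav.representative.length >= cfg.te_overlap_frac:
            n_te += 1
            top = max(sorted(cov), key=lambda c: cov[c])
            class_counts[top] += 1
    n = len(pavs)
    return n_te / n, {cls: cnt / n for cls, cnt in sorted(class_counts.items())}


def pav_density(
    pavs: Iterable[MergedSV],
    chrom_lengths: Mapping[str, int],
    bin_size: int = 1_000_000,
) -> dict[str, np.ndarray]:
    """Per-chromosome PAV counts per ``bin_size`` window (start-position binning)."""
    density = {
        chrom: np.zeros(int(np.ceil(length / bin_size)) or 1, dtype=int)
        for chrom, length in chrom_lengths.items()
    }
    for pav in pavs:
        if pav.sv_type not in PAV_TYPES:
            continue
        if pav.chrom not in density:
            raise ValidationError(f"PAV on unknown chromosome {pav.chrom}")
        density[pav.chrom][pav.start // bin_size] += 1
    return density
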