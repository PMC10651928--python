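"""Gene copy-number estimation and CNV-expression correlation.

Copy number of a gene in an accession is the number of distinct loci at
which its protein maps with identity > 90% and coverage > 90% (zero is a
gene deletion).  Near-identical pan-genes (both identity and coverage
> 90% between them) are deduplicated to one representative before CNV
calling.  Per gene and tissue, copy number is correlated with expression
(Pearson); genes pass the filter at p < 0.05 and |r| > 0.5.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .model import GenomicInterval, PipelineConfig


@dataclass(frozen=True)
class AlignmentHit:
    """One protein-to-genome alignment hit of a gene in a target accession."""

    gene_id: str
    accession: str
    interval: GenomicInterval
    identity: float
    coverage: float

    def __post_init__(self) -> None:
        for name in ("identity", "coverage"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(
                    f"hit {self.gene_id}@{self.accession}: {name} {v} outside [0, 1]"
                )


@dataclass(frozen=True)
class CorrelationRecord:
    gene_id: str
    tissue: str
    r: float  # NaN when copy number is constant
    p: float
    flagged: bool
    n: int


def dedup_pan_genes(
    genes: Iterable[str],
    similarity_pairs: Iterable[tuple[str, str, float, float]],
    cfg: PipelineConfig,
) -> set[str]:
    """One representative per group of near-identical pan-genes.

    Genes joined by pairs with identity and coverage both above the CNV
    thresholds form connected components; the lexicographically smallest id
    represents each component.
    """
    g = nx.Graph()
    g.add_nodes_from(genes)
    for a, b, identity, coverage in similarity_pairs:
        g.add_nodes_from((a, b))
        if identity > cfg.cnv_identity_min and coverage > cfg.cnv_coverage_min:
            g.add_edge(a, b)
    return {min(component) for component in nx.connected_components(g)}


def _reciprocal_overlap(a: GenomicInterval, b: GenomicInterval, frac: float) -> bool:
    inter = a.intersection_length(b)
    return inter > frac * a.length and inter > frac * b.length


def copy_number(hits: Sequence[AlignmentHit], cfg: PipelineConfig) -> int:
    """Distinct passing loci for one gene in one accession (0 = deletion).

    Hits passing the identity/coverage filter whose intervals overlap
    reciprocally by more than ``cnv_locus_overlap`` collapse to one locus.
    """
    if len({h.accession for h in hits}) > 1:
        raise ValidationError("copy_number expects hits from a single accession")
    passing = [
        h
        for h in hits
        if h.identity > cfg.cnv_identity_min and h.coverage > cfg.cnv_coverage_min
    ]
    if not passing:
        return 0
    g = nx.Graph()
    g.add_nodes_from(range(len(passing)))
    for i in range(len(passing)):
        for j in range(i + 1, len(passing)):
            if _reciprocal_overlap(
                passing[i].interval, passing[j].interval, cfg.cnv_locus_overlap
            ):
                g.add_edge(i, j)
    return nx.number_connected_components(g)


def build_copy_number_matrix(
    hits: Iterable[AlignmentHit],
    genes: Sequence[str],
    accessions: Sequence[str],
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """Gene x accession integer copy-number matrix from an alignment hit list."""
    grouped: dict[tuple[str, str], list[AlignmentHit]] = {}
    for h in hits:
        grouped.setdefault((h.gene_id, h.accession), []).append(h)
    mat = pd.DataFrame(0, index=list(genes), columns=list(accessions), dtype=int)
    for (gene, acc), group in grouped.items():
        if gene in mat.index and acc in mat.columns:
            mat.loc[gene, acc] = copy_number(group, cfg)
    return mat


def cnv_expression_correlation(
    cn_row: pd.Series,
    expr_row: pd.Series,
    cfg: PipelineConfig,
    gene_id: str = "",
    tissue: str = "",
) -> CorrelationRecord:
    """Pearson correlation of one gene's copy number with its expression.

    Computed over the accessions shared by both rows (at least 3 required).
    A constant copy-number row has no defined correlation and is never
    flagged.  Flagging applies the joint p < ``corr_p_max`` and
    |r| > ``corr_r_min`` filter.
    """
    shared = cn_row.index.intersection(expr_row.index)
    if len(shared) < 3:
        raise ValidationError(
            f"gene {gene_id}: need >= 3 shared accessions, got {len(shared)}"
        )
    x = cn_row[shared].to_numpy(dtype=float)
    y = expr_row[shared].to_numpy(dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationRecord(gene_id, tissue, float("nan"), 1.0, False, len(shared))
    r, p = stats.pearsonr(x, y)
    flagged = (p < cfg.corr_p_max) and (abs(r) > cfg.corr_r_min)
    return CorrelationRecord(gene_id, tissue, float(r), float(p), bool(flagged), len(shared))


def correlate_matrix(
    cn: pd.DataFrame,
    expr: pd.DataFrame,
    tissue: str,
    cfg: PipelineConfig,
) -> list[CorrelationRecord]:
    """Correlation records for every gene present in both matrices."""
    genes = cn.index.intersection(expr.index)
    return [
        cnv_expression_correlation(cn.loc[g], expr.loc[g], cfg, gene_id=g, tissue=tissue)
        for g in genes
    ]


def correlation_summary(
    records: Iterable[CorrelationRecord],
) -> dict[str, dict[str, float]]:
    """Per-tissue tested / flagged counts and flagged proportion."""
    out: dict[str, dict[str, float]] = {}
    for rec in records:
        entry = out.setdefault(rec.tissue, {"tested": 0, "flagged": 0})
        entry["tested"] += 1
        entry["flagged"] += int(rec.flagged)
    for entry in out.values():
        entry["proportion"] = (
            entry["flagged"] / entry["tested"] if entry["tested"] else 0.0
        )
    return out


def deletion_count(cn: pd.DataFrame) -> int:
    """Number of gene x accession cells with copy number zero."""
    return int((cn.to_numpy() == 0).sum())
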