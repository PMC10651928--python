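"""Stepwise collinearity-based pan-gene locus construction.

Starting from the base accession's genes (one locus each), the remaining
accessions are added in order: a gene joins the locus of its collinear
partner when such a partner already sits in the table, and founds a new
locus otherwise.  Conflicts (a gene collinear to two existing loci) resolve
to the earliest-introduced locus; a second gene of the same accession
mapping to an already-filled locus founds a new locus, preserving the
one-gene-per-accession-per-locus shape of a locus.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: anchors between two accessions: iterable of (gene_in_A, gene_in_B) pairs,
#: direction-free; keyed by frozenset({accA, accB})
CollinearityMap = Mapping[frozenset, Sequence[tuple[str, str]]]


@dataclass
class PanLocusTable:
    """locus_id -> {accession -> gene id}; provenance = founding accession."""

    loci: dict[str, dict[str, str]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)
    accessions: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(self.loci, orient="index")
        return df.reindex(columns=self.accessions)

    @property
    def n_loci(self) -> int:
        return len(self.loci)


def _locus_id(i: int) -> str:
    return f"PL{i:06d}"


def build_pangene_loci(
    genes: Mapping[str, Sequence[str]],
    maps: CollinearityMap,
    order: Sequence[str],
) -> PanLocusTable:
    """Build the pan-gene locus table by stepwise accession addition.

    Parameters
    ----------
    genes
        Per-accession gene id lists (order within an accession is the
        annotation order and fixes tie-breaking determinism).
    maps
        Collinearity anchors per accession pair.
    order
        Accession processing order; the first entry is the base whose genes
        seed the initial loci.
    """
    order = list(order)
    missing = [a for a in order if a not in genes]
    if missing:
        raise ValidationError(f"order references unknown accession(s): {missing}")

    table = PanLocusTable(accessions=order)
    gene_locus: dict[tuple[str, str], str] = {}  # (accession, gene) -> locus
    locus_rank: dict[str, int] = {}
    counter = 0

    base = order[0]
    for g in genes[base]:
        lid = _locus_id(counter)
        counter += 1
        table.loci[lid] = {base: g}
        table.provenance[lid] = base
        gene_locus[(base, g)] = lid
        locus_rank[lid] = len(locus_rank)

    # partner lookup: for accession pair {A, new}, gene of new -> genes of A
    for step, acc in enumerate(order[1:], start=1):
        earlier = order[:step]
        partners: dict[str, list[tuple[str, str]]] = {}
        for prev in earlier:
            pair = frozenset((prev, acc))
            for ga, gb in maps.get(pair, ()):  # anchors are direction-free
                for new_gene, old_gene in ((gb, ga), (ga, gb)):
                    partners.setdefault(new_gene, []).append((prev, old_gene))

        for g in genes[acc]:
            hit_loci = {
                gene_locus[(prev, old)]
                for prev, old in partners.get(g, ())
                if (prev, old) in gene_locus
            }
            lid = None
            if hit_loci:
                if len(hit_loci) > 1:
                    logger.info(
                        "gene %s/%s collinear to %d loci; joining the earliest",
                        acc,
                        g,
                        len(hit_loci),
                    )
                lid = min(hit_loci, key=locus_rank.__getitem__)
                if acc in table.loci[lid]:
                    # locus already holds a gene of this accession: the extra
                    # gene founds a new locus
                    lid = None
            if lid is None:
                lid = _locus_id(counter)
                counter += 1
                table.loci[lid] = {}
                table.provenance[lid] = acc
                locus_rank[lid] = len(locus_rank)
            table.loci[lid][acc] = g
            gene_locus[(acc, g)] = lid

    return table


def core_loci(table: PanLocusTable) -> list[str]:
    """Locus ids with a gene in every accession of the table."""
    n = len(table.accessions)
    return [lid for lid, row in table.loci.items() if len(row) == n]
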