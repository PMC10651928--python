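"""Pan-genome gene-cluster classification and saturation curves.

Orthologous gene clusters over ``n`` accessions are categorised by the
number of accessions they occur in: core (all ``n``), soft-core (11 to
``n``-1 at the published 13-accession defaults), dispensable (2 to 10) and
accession-specific (exactly 1).  Percentages are rounded half-up to two
decimals, matching the publication style.  Saturation curves track pan and
core cluster counts over genome-addition orders.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .model import PipelineConfig

CATEGORIES = ("core", "soft-core", "dispensable", "specific")


@dataclass(frozen=True)
class ClusterPresence:
    """An orthologous cluster with per-accession gene counts (0 = absent)."""

    cluster_id: str
    presence: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "presence", dict(self.presence))
        if any(v < 0 for v in self.presence.values()):
            raise ValidationError(f"cluster {self.cluster_id}: negative gene count")
        if self.n_present < 1:
            raise ValidationError(f"cluster {self.cluster_id}: present in no accession")

    @property
    def n_present(self) -> int:
        return sum(1 for v in self.presence.values() if v >= 1)

    @property
    def n_genes(self) -> int:
        return sum(self.presence.values())

    @property
    def accessions(self) -> frozenset[str]:
        return frozenset(a for a, v in self.presence.items() if v >= 1)


def classify_cluster(n_present: int, cfg: PipelineConfig) -> str:
    """Category for a cluster present in ``n_present`` accessions."""
    if not (1 <= n_present <= cfg.n_accessions):
        raise ValidationError(
            f"n_present {n_present} outside [1, {cfg.n_accessions}]"
        )
    if n_present == cfg.n_accessions:
        return "core"
    if n_present >= cfg.softcore_min:
        return "soft-core"
    if n_present >= cfg.dispensable_min:
        return "dispensable"
    return "specific"


def _pct(count: int, total: int) -> float:
    """Half-up percentage at 2 decimals, e.g. 700/46409 -> 1.51."""
    if total == 0:
        return 0.0
    q = (Decimal(count) * 100 / Decimal(total)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return float(q)


@dataclass(frozen=True)
class CategoryTally:
    """Cluster / gene counts and percentages per category."""

    cluster_counts: Mapping[str, int]
    gene_counts: Mapping[str, int]

    @property
    def total_clusters(self) -> int:
        return sum(self.cluster_counts.values())

    @property
    def total_genes(self) -> int:
        return sum(self.gene_counts.values())

    @property
    def cluster_pct(self) -> dict[str, float]:
        return {
            c: _pct(self.cluster_counts.get(c, 0), self.total_clusters)
            for c in CATEGORIES
        }

    @property
    def gene_pct(self) -> dict[str, float]:
        return {
            c: _pct(self.gene_counts.get(c, 0), self.total_genes) for c in CATEGORIES
        }

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, tuple[int, int]]
    ) -> "CategoryTally":
        """Build from per-category (cluster count, gene count) pairs."""
        unknown = set(counts) - set(CATEGORIES)
        if unknown:
            raise ValidationError(f"unknown categories: {sorted(unknown)}")
        return cls(
            cluster_counts={c: counts.get(c, (0, 0))[0] for c in CATEGORIES},
            gene_counts={c: counts.get(c, (0, 0))[1] for c in CATEGORIES},
        )


def tally(clusters: Sequence[ClusterPresence], cfg: PipelineConfig) -> CategoryTally:
    """Categorise clusters and accumulate cluster and gene counts."""
    if not clusters:
        raise ValidationError("tally requires a non-empty cluster list")
    cluster_counts = {c: 0 for c in CATEGORIES}
    gene_counts = {c: 0 for c in CATEGORIES}
    for cl in clusters:
        cat = classify_cluster(cl.n_present, cfg)
        cluster_counts[cat] += 1
        gene_counts[cat] += cl.n_genes
    return CategoryTally(cluster_counts=cluster_counts, gene_counts=gene_counts)


def _presence_matrix(
    clusters: Sequence[ClusterPresence], accessions: Sequence[str]
) -> np.ndarray:
    mat = np.zeros((len(clusters), len(accessions)), dtype=bool)
    col = {a: j for j, a in enumerate(accessions)}
    for i, cl in enumerate(clusters):
        for a in cl.accessions:
            if a not in col:
                raise ValidationError(f"cluster {cl.cluster_id}: unknown accession {a}")
            mat[i, col[a]] = True
    return mat


def pan_core_curve(
    clusters: Sequence[ClusterPresence],
    accessions: Sequence[str],
    orders: Sequence[Sequence[str]] | None = None,
    n_perm: int = 100,
    seed: int = 0,
):
    """Pan / core cluster counts over genome-addition orders.

    For each order's length-k prefix, ``pan`` counts clusters present in at
    least one prefix accession and ``core`` clusters present in all of them;
    curves are averaged over orders (100 seeded random permutations by
    default, or explicit orders).  Per order, core is non-increasing and pan
    non-decreasing in k.

    Returns a dict with keys ``k``, ``pan_mean``, ``pan_sd``, ``core_mean``,
    ``core_sd`` and per-order matrices ``pan``, ``core``.
    """
    accessions = list(accessions)
    mat = _presence_matrix(clusters, accessions)
    idx = {a: j for j, a in enumerate(accessions)}
    if orders is None:
        rng = np.random.default_rng(seed)
        order_idx = [rng.permutation(len(accessions)) for _ in range(n_perm)]
    else:
        order_idx = []
        for order in orders:
            unknown = set(order) - set(accessions)
            if unknown:
                raise ValidationError(f"order contains unknown accession(s) {unknown}")
            if len(set(order)) != len(accessions):
                raise ValidationError("order must be a permutation of all accessions")
            order_idx.append(np.array([idx[a] for a in order]))

    n_k = len(accessions)
    pan = np.zeros((len(order_idx), n_k), dtype=int)
    core = np.zeros_like(pan)
    for o, perm in enumerate(order_idx):
        sub = mat[:, perm]
        any_so_far = np.logical_or.accumulate(sub, axis=1)
        all_so_far = np.logical_and.accumulate(sub, axis=1)
        pan[o] = any_so_far.sum(axis=0)
        core[o] = all_so_far.sum(axis=0)
    return {
        "k": np.arange(1, n_k + 1),
        "pan_mean": pan.mean(axis=0),
        "pan_sd": pan.std(axis=0),
        "core_mean": core.mean(axis=0),
        "core_sd": core.std(axis=0),
        "pan": pan,
        "core": core,
    }
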