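"""Synthetic pan-genome inputs with planted ground truth.

The generator emulates the study design every analysis module expects:
13 *Malus*-like accessions, ground-truth SVs of four types observed by
three imperfect callers (dropouts, false positives, breakpoint jitter),
orthologous-cluster presence counts at the published category proportions,
and copy-number / expression matrices with planted linear CN-expression
effects.  Everything is deterministic given the seed, and every emitted
record traces back to a truth identifier.
"""
from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import (
    DEFAULT_CALLERS,
    GenomicInterval,
    MergedSV,
    PipelineConfig,
    SVCall,
    SVType,
)
from .panclusters import CATEGORIES, ClusterPresence
from .svannot import AnnotationIndex, GeneModel, TEInterval

#: the 13 accession codes used throughout (Granny Smith is the reference)
DEFAULT_ACCESSIONS = (
    "GS", "FJ", "GA", "OR", "SD",
    "MSM", "MSR", "MO", "MA", "COP", "HC", "JG", "RA",
)
#: accessions with fruit RNA-seq (peel and flesh tissues)
FRUIT_ACCESSIONS = ("GS", "OR", "SD", "FJ", "GA")

_PUBLISHED_CATEGORY_PROPS = {
    "core": 0.3210,
    "soft-core": 0.1678,
    "dispensable": 0.4962,
    "specific": 0.0151,
}
# mean genes per present accession, from published genes/cluster ratios
_PUBLISHED_GENES_PER_PRESENCE = {
    "core": 1.49,
    "soft-core": 1.38,
    "dispensable": 1.15,
    "specific": 28.3,
}


@dataclass(frozen=True)
class CallerModel:
    """Imperfect-caller behaviour: dropouts, false positives and jitter."""

    sensitivity: float = 0.95
    fp_per_mb: float = 0.2
    jitter_frac: float = 0.02  # breakpoint jitter relative to event length
    anchor_jitter_bp: int = 2  # insertion-anchor jitter, bp
    length_jitter_frac: float = 0.02  # inserted-length jitter (presence)

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0):
            raise ValidationError("sensitivity must be in [0, 1]")
        if self.jitter_frac < 0 or self.anchor_jitter_bp < 0:
            raise ValidationError("jitter must be non-negative")


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    The genome is desk-scale (three chromosomes, 30 Mb) while rates and
    proportions mirror the published study: PAVs dominate the SV spectrum,
    sharing follows a power law so most SVs are private or nearly so,
    cluster categories follow the published proportions, and ~71% of PAVs
    are TE-derived with LTR/Gypsy the dominant class.
    """

    n_accessions: int = 13
    accessions: tuple[str, ...] = DEFAULT_ACCESSIONS
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {
            "chr01": 12_000_000,
            "chr02": 10_000_000,
            "chr03": 8_000_000,
        }
    )
    # events per Mb per type; PAV >> translocation >> inversion as published
    sv_rate: Mapping[str, float] = field(
        default_factory=lambda: {
            "presence": 4.0,
            "absence": 4.0,
            "translocation": 1.0,
            "inversion": 0.1,
        }
    )
    sharing_alpha: float = 1.5  # P(frequency f) proportional to f^-alpha
    callers: Mapping[str, CallerModel] = field(
        default_factory=lambda: {name: CallerModel() for name in DEFAULT_CALLERS}
    )
    # planted high-rate segments for hotspot recovery experiments
    hotspot_segments: tuple[tuple[str, int, int], ...] = ()
    hotspot_multiplier: float = 10.0
    # TE composition planted into PAVs (published fractions)
    te_pav_frac: float = 0.7131
    gypsy_frac: float = 0.4327
    # annotation model
    n_genes_per_mb: float = 20.0
    gene_length_range: tuple[int, int] = (1_000, 6_000)
    intergenic_gap_range: tuple[int, int] = (12_000, 40_000)
    te_genome_frac: float = 0.40
    # cluster model
    n_clusters: int = 5_000
    category_props: Mapping[str, float] = field(
        default_factory=lambda: dict(_PUBLISHED_CATEGORY_PROPS)
    )
    genes_per_presence: Mapping[str, float] = field(
        default_factory=lambda: dict(_PUBLISHED_GENES_PER_PRESENCE)
    )
    # CNV / expression model
    n_cnv_genes: int = 200
    planted_frac: float = 0.5
    target_r: float = 0.8
    cn_probs: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.02, 1: 0.70, 2: 0.18, 3: 0.10}
    )
    expr_baseline: float = 10.0
    expr_noise_sd: float = 1.0
    # pan-gene model
    n_pangene_loci: int = 300
    locus_presence_prob: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_accessions > len(self.accessions):
            self.accessions = tuple(
                f"A{i:02d}" for i in range(1, self.n_accessions + 1)
            )
        else:
            self.accessions = tuple(self.accessions[: self.n_accessions])
        props = np.array([self.category_props[c] for c in CATEGORIES], dtype=float)
        if np.any(props < 0) or props.sum() <= 0:
            raise ValidationError("category proportions must be non-negative")
        self.category_props = dict(zip(CATEGORIES, props / props.sum()))
        if not (0.0 <= self.te_pav_frac <= 1.0) or self.gypsy_frac > self.te_pav_frac:
            raise ValidationError(
                "require 0 <= gypsy_frac <= te_pav_frac <= 1"
            )
        p = np.array(list(self.cn_probs.values()), dtype=float)
        if not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
            raise ValidationError("cn_probs must sum to 1")


@dataclass
class SVTruth:
    """Planted SV events plus the noisy callsets observing them."""

    events: list[MergedSV]
    callsets: dict[str, dict[str, list[SVCall]]]  # accession -> caller -> calls
    call_truth: dict[str, str]  # call id -> truth event id or "fp"
    te_truth: dict[str, str | None]  # PAV truth id -> planted TE class or None


# ---------------------------------------------------------------------------
# position sampling


class _Placer:
    """Rejection sampler keeping same-type events non-overlapping (padded)."""

    def __init__(self, pad: int) -> None:
        self.pad = pad
        self.starts: dict[str, list[int]] = {}
        self.ends: dict[str, list[int]] = {}

    def try_place(self, chrom: str, start: int, end: int) -> bool:
        starts = self.starts.setdefault(chrom, [])
        ends = self.ends.setdefault(chrom, [])
        i = bisect_left(starts, start)
        if i > 0 and ends[i - 1] + self.pad > start:
            return False
        if i < len(starts) and starts[i] - self.pad < end:
            return False
        starts.insert(i, start)
        ends.insert(i, end)
        return True


def _segment_table(cfg: SimConfig) -> tuple[list[tuple[str, int, int]], np.ndarray]:
    """(chrom, start, end) segments with sampling weights, honouring planted
    high-rate segments."""
    hot = {(c, s, e) for c, s, e in cfg.hotspot_segments}
    segments: list[tuple[str, int, int]] = []
    weights: list[float] = []
    for chrom in sorted(cfg.chrom_lengths):
        length = cfg.chrom_lengths[chrom]
        cuts = sorted(
            {0, length}
            | {s for c, s, e in hot if c == chrom}
            | {e for c, s, e in hot if c == chrom}
        )
        for s, e in zip(cuts, cuts[1:]):
            mult = cfg.hotspot_multiplier if any(
                c == chrom and hs <= s and e <= he for c, hs, he in hot
            ) else 1.0
            segments.append((chrom, s, e))
            weights.append((e - s) * mult)
    w = np.asarray(weights, dtype=float)
    return segments, w / w.sum()


def _sample_position(
    rng: np.random.Generator,
    segments: list[tuple[str, int, int]],
    probs: np.ndarray,
    length: int,
    chrom_lengths: Mapping[str, int],
) -> tuple[str, int]:
    for _ in range(200):
        chrom, s, e = segments[rng.choice(len(segments), p=probs)]
        start = int(rng.integers(s, e))
        if start + length <= chrom_lengths[chrom]:
            return chrom, start
    raise ValidationError("could not place event; genome too small for event length")


def _event_length(rng: np.random.Generator, sv_type: SVType) -> int:
    if sv_type in (SVType.PRESENCE, SVType.ABSENCE):
        return int(np.clip(rng.lognormal(math.log(600), 0.9), 50, 20_000))
    if sv_type is SVType.INVERSION:
        return int(rng.integers(20_000, 200_000))
    return int(rng.integers(2_000, 50_000))


def _sample_frequency(rng: np.random.Generator, n: int, alpha: float) -> int:
    f = np.arange(1, n + 1, dtype=float)
    p = f**-alpha
    return int(rng.choice(np.arange(1, n + 1), p=p / p.sum()))


# ---------------------------------------------------------------------------
# SV truth and callsets


def simulate_sv_truth(cfg: SimConfig) -> SVTruth:
    """Plant ground-truth SVs and derive three noisy per-accession callsets.

    Same-type truth events never overlap (padded placement), so under small
    jitter distinct events can never satisfy the merge predicates and the
    truth frequency spectrum is exactly recoverable.
    """
    rng = np.random.default_rng(cfg.seed)
    genome_mb = sum(cfg.chrom_lengths.values()) / 1e6
    segments, probs = _segment_table(cfg)

    events: list[MergedSV] = []
    te_truth: dict[str, str | None] = {}
    counter = 0
    for type_name in ("absence", "presence", "inversion", "translocation"):
        sv_type = SVType(type_name)
        n_events = int(round(cfg.sv_rate.get(type_name, 0.0) * genome_mb))
        if cfg.hotspot_segments:
            hot_mb = sum(e - s for _, s, e in cfg.hotspot_segments) / 1e6
            n_events += int(
                round(cfg.sv_rate.get(type_name, 0.0) * hot_mb * (cfg.hotspot_multiplier - 1))
            )
        placer = _Placer(pad=60)
        placed = 0
        while placed < n_events:
            length = _event_length(rng, sv_type)
            anchor_len = 1 if sv_type is SVType.PRESENCE else length
            chrom, start = _sample_position(
                rng, segments, probs, anchor_len, cfg.chrom_lengths
            )
            if not placer.try_place(chrom, start, start + anchor_len):
                continue
            placed += 1
            tid = f"T{counter:06d}"
            counter += 1
            freq = _sample_frequency(rng, cfg.n_accessions, cfg.sharing_alpha)
            accs = frozenset(
                rng.choice(cfg.accessions, size=freq, replace=False).tolist()
            )
            te_class = None
            if sv_type in (SVType.PRESENCE, SVType.ABSENCE):
                te_class = _planted_te_class(rng, cfg)
                te_truth[tid] = te_class
            events.append(
                MergedSV(
                    representative=GenomicInterval(chrom, start, start + anchor_len),
                    sv_type=sv_type,
                    sv_length=length,
                    members=(tid,),
                    accessions=accs,
                    id=tid,
                    inserted_te_class=(
                        te_class if sv_type is SVType.PRESENCE else None
                    ),
                )
            )

    events.sort(key=lambda e: (e.chrom, e.start, e.id))
    callsets: dict[str, dict[str, list[SVCall]]] = {
        acc: {name: [] for name in cfg.callers} for acc in cfg.accessions
    }
    call_truth: dict[str, str] = {}
    serial = 0
    for event in events:
        for acc in sorted(event.accessions):
            for name in cfg.callers:
                model = cfg.callers[name]
                if rng.random() >= model.sensitivity:
                    continue
                call = _observe(rng, event, acc, name, model, cfg)
                cid = f"{acc}.{name}.{serial:06d}"
                serial += 1
                call = replace(call, id=cid)
                callsets[acc][name].append(call)
                call_truth[cid] = event.id

    # false positives, uniform over the genome, never mapped to truth
    for acc in cfg.accessions:
        for name, model in cfg.callers.items():
            n_fp = int(rng.poisson(model.fp_per_mb * genome_mb))
            for _ in range(n_fp):
                sv_type = SVType(
                    str(
                        rng.choice(
                            list(cfg.sv_rate),
                            p=np.array(list(cfg.sv_rate.values()))
                            / sum(cfg.sv_rate.values()),
                        )
                    )
                )
                length = _event_length(rng, sv_type)
                anchor_len = 1 if sv_type is SVType.PRESENCE else length
                chrom, start = _sample_position(
                    rng, segments, probs, anchor_len, cfg.chrom_lengths
                )
                cid = f"{acc}.{name}.fp{serial:06d}"
                serial += 1
                iv = GenomicInterval(chrom, start, start + anchor_len)
                callsets[acc][name].append(
                    SVCall(
                        interval=iv,
                        sv_type=sv_type,
                        sv_length=length if sv_type is SVType.PRESENCE else iv.length,
                        accession=acc,
                        caller=name,
                        id=cid,
                    )
                )
                call_truth[cid] = "fp"

    for acc in callsets:
        for name in callsets[acc]:
            callsets[acc][name].sort(key=lambda c: (c.chrom, c.start, c.id))
    return SVTruth(events=events, callsets=callsets, call_truth=call_truth, te_truth=te_truth)


def _planted_te_class(rng: np.random.Generator, cfg: SimConfig) -> str | None:
    if rng.random() >= cfg.te_pav_frac:
        return None
    if rng.random() < cfg.gypsy_frac / cfg.te_pav_frac:
        return "LTR/Gypsy"
    other = ("LTR/Copia", "DNA/hAT", "LINE/L1")
    return str(rng.choice(other, p=(0.6, 0.25, 0.15)))


def _observe(
    rng: np.random.Generator,
    event: MergedSV,
    accession: str,
    caller: str,
    model: CallerModel,
    cfg: SimConfig,
) -> SVCall:
    iv = event.representative
    limit = cfg.chrom_lengths[iv.chrom]
    if event.sv_type is SVType.PRESENCE:
        j = model.anchor_jitter_bp
        start = int(np.clip(iv.start + rng.integers(-j, j + 1), 0, limit - 1))
        lj = model.length_jitter_frac
        sv_length = max(1, int(round(event.sv_length * rng.uniform(1 - lj, 1 + lj))))
        return SVCall(
            interval=GenomicInterval(iv.chrom, start, start + 1),
            sv_type=event.sv_type,
            sv_length=sv_length,
            accession=accession,
            caller=caller,
        )
    j = int(round(model.jitter_frac * iv.length))
    start = int(np.clip(iv.start + rng.integers(-j, j + 1), 0, limit - 1))
    end = int(np.clip(iv.end + rng.integers(-j, j + 1), start + 1, limit))
    new_iv = GenomicInterval(iv.chrom, start, end)
    return SVCall(
        interval=new_iv,
        sv_type=event.sv_type,
        sv_length=new_iv.length,
        accession=accession,
        caller=caller,
    )


# ---------------------------------------------------------------------------
# clusters


def simulate_clusters(
    cfg: SimConfig, pipeline_cfg: PipelineConfig | None = None
) -> tuple[list[ClusterPresence], dict[str, str]]:
    """Clusters with planted category labels matching published proportions."""
    pcfg = pipeline_cfg or PipelineConfig(n_accessions=cfg.n_accessions)
    rng = np.random.default_rng(cfg.seed + 1)
    cats = list(CATEGORIES)
    probs = np.array([cfg.category_props[c] for c in cats])
    clusters: list[ClusterPresence] = []
    labels: dict[str, str] = {}
    for i in range(cfg.n_clusters):
        cat = str(rng.choice(cats, p=probs))
        if cat == "core":
            n_present = pcfg.n_accessions
        elif cat == "soft-core":
            n_present = int(rng.integers(pcfg.softcore_min, pcfg.n_accessions))
        elif cat == "dispensable":
            n_present = int(rng.integers(pcfg.dispensable_min, pcfg.softcore_min))
        else:
            n_present = 1
        accs = rng.choice(cfg.accessions, size=n_present, replace=False)
        mean_extra = max(0.0, cfg.genes_per_presence[cat] - 1.0)
        counts = 1 + rng.poisson(mean_extra, size=n_present)
        cid = f"C{i:06d}"
        clusters.append(
            ClusterPresence(
                cluster_id=cid,
                presence={a: int(k) for a, k in zip(accs.tolist(), counts)},
            )
        )
        labels[cid] = cat
    return clusters, labels


# ---------------------------------------------------------------------------
# CNV / expression


def slope_for_target_r(r: float, sd_cn: float, noise_sd: float) -> float:
    """Slope b with population correlation r for expr = a + b*CN + noise."""
    if sd_cn <= 0:
        raise ValidationError("copy-number standard deviation must be positive")
    return noise_sd * r / (sd_cn * math.sqrt(1.0 - r * r))


def simulate_cnv_expression(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], set[str]]:
    """Copy-number matrix, per-tissue expression matrices, planted gene set.

    Planted genes follow expr = a + b*CN + N(0, sigma^2) with b set so the
    population correlation is ``target_r``; other genes have expression
    independent of copy number.  Leaf expression covers all accessions;
    peel and flesh cover the five fruit-sampled accessions.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    genes = [f"G{i:06d}" for i in range(cfg.n_cnv_genes)]
    accs = list(cfg.accessions)
    cn_values = np.array(list(cfg.cn_probs), dtype=int)
    cn_p = np.array(list(cfg.cn_probs.values()), dtype=float)

    n_planted = int(round(cfg.planted_frac * cfg.n_cnv_genes))
    planted = set(rng.choice(genes, size=n_planted, replace=False).tolist())

    cn = rng.choice(cn_values, p=cn_p, size=(cfg.n_cnv_genes, len(accs)))
    for i, g in enumerate(genes):
        if g in planted:
            while cn[i].min() == cn[i].max():
                cn[i] = rng.choice(cn_values, p=cn_p, size=len(accs))
    cn_df = pd.DataFrame(cn, index=genes, columns=accs, dtype=int)

    tissues = {
        "leaf": accs,
        "peel": [a for a in FRUIT_ACCESSIONS if a in accs],
        "flesh": [a for a in FRUIT_ACCESSIONS if a in accs],
    }
    pop_sd = math.sqrt(
        float(np.sum(cn_p * cn_values**2) - np.sum(cn_p * cn_values) ** 2)
    )
    b = slope_for_target_r(cfg.target_r, pop_sd, cfg.expr_noise_sd)
    expr: dict[str, pd.DataFrame] = {}
    for tissue, tissue_accs in tissues.items():
        if len(tissue_accs) < 3:
            continue
        noise = rng.normal(0.0, cfg.expr_noise_sd, size=(cfg.n_cnv_genes, len(tissue_accs)))
        base = rng.normal(cfg.expr_baseline, cfg.expr_noise_sd, size=(cfg.n_cnv_genes, len(tissue_accs)))
        x = cn_df[tissue_accs].to_numpy(dtype=float)
        mask = np.array([g in planted for g in genes])[:, None]
        values = np.where(mask, cfg.expr_baseline + b * x + noise, base)
        expr[tissue] = pd.DataFrame(
            np.clip(values, 0.0, None), index=genes, columns=tissue_accs
        )
    return cn_df, expr, planted


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(
    cfg: SimConfig, truth: SVTruth | None = None
) -> AnnotationIndex:
    """Gene models with introns plus classed TE intervals.

    Gene bodies never overlap and are separated by at least twice the
    5 kb context flank, so flank labels are unambiguous by construction.
    When an :class:`SVTruth` is supplied, TE intervals are planted to cover
    exactly the absence PAVs whose planted TE status says so, making the
    measured TE composition reflect the planted fractions.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    genes: list[GeneModel] = []
    g_serial = 0
    for chrom in sorted(cfg.chrom_lengths):
        length = cfg.chrom_lengths[chrom]
        pos = int(rng.integers(*cfg.intergenic_gap_range))
        while True:
            glen = int(rng.integers(*cfg.gene_length_range))
            if pos + glen + cfg.intergenic_gap_range[0] > length:
                break
            span = GenomicInterval(chrom, pos, pos + glen)
            genes.append(
                GeneModel(
                    gene_id=f"GS{g_serial:05d}",
                    span=span,
                    strand="+" if rng.random() < 0.5 else "-",
                    exons=_random_exons(rng, span),
                )
            )
            g_serial += 1
            pos += glen + int(rng.integers(*cfg.intergenic_gap_range))

    tes: list[TEInterval] = []
    forbidden: list[GenomicInterval] = []
    if truth is not None:
        for event in truth.events:
            if event.sv_type is not SVType.ABSENCE:
                continue
            cls = truth.te_truth.get(event.id)
            iv = event.representative
            if cls is None:
                forbidden.append(iv)
            else:
                pad = int(rng.integers(0, 50))
                start = max(0, iv.start - pad)
                end = min(cfg.chrom_lengths[iv.chrom], iv.end + pad)
                tes.append(TEInterval(GenomicInterval(iv.chrom, start, end), cls))

    total = sum(cfg.chrom_lengths.values())
    covered = sum(te.interval.length for te in tes)
    chroms = sorted(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    classes = ("LTR/Gypsy", "LTR/Copia", "DNA/hAT", "LINE/L1")
    class_p = (0.50, 0.25, 0.15, 0.10)
    attempts = 0
    while covered < cfg.te_genome_frac * total and attempts < 500_000:
        attempts += 1
        chrom = chroms[int(rng.choice(len(chroms), p=lengths / lengths.sum()))]
        te_len = int(np.clip(rng.lognormal(math.log(2_000), 0.8), 200, 15_000))
        start = int(rng.integers(0, max(1, cfg.chrom_lengths[chrom] - te_len)))
        iv = GenomicInterval(chrom, start, start + te_len)
        if any(iv.intersection_length(f) > 0 for f in forbidden):
            continue
        tes.append(TEInterval(iv, str(rng.choice(classes, p=class_p))))
        covered += te_len

    return AnnotationIndex(genes=genes, tes=tes, chrom_lengths=dict(cfg.chrom_lengths))


def _random_exons(
    rng: np.random.Generator, span: GenomicInterval
) -> tuple[GenomicInterval, ...]:
    n_exons = int(rng.integers(1, 6))
    if n_exons == 1:
        return (span,)
    n_parts = 2 * n_exons - 1
    weights = rng.uniform(0.5, 1.5, size=n_parts)
    sizes = np.maximum(1, (weights / weights.sum() * span.length).astype(int))
    sizes[-1] = span.length - sizes[:-1].sum()
    if sizes[-1] < 1:  # pathological rounding; fall back to equal split
        sizes = np.full(n_parts, span.length // n_parts)
        sizes[-1] = span.length - sizes[:-1].sum()
    exons = []
    pos = span.start
    for i, size in enumerate(sizes):
        if i % 2 == 0:
            exons.append(GenomicInterval(span.chrom, pos, pos + int(size)))
        pos += int(size)
    return tuple(exons)


# ---------------------------------------------------------------------------
# pan-gene loci


def simulate_pangene(
    cfg: SimConfig,
) -> tuple[dict[str, list[str]], dict[frozenset, list[tuple[str, str]]], list[str], int]:
    """1:1 collinearity maps over planted loci.

    Each planted locus is present in each accession independently with
    ``locus_presence_prob`` (re-drawn to appear somewhere); pairs of
    accessions share anchors at loci both carry.  Returns (per-accession
    genes, anchor maps, processing order, ground-truth core-locus count).
    """
    rng = np.random.default_rng(cfg.seed + 4)
    accs = list(cfg.accessions)
    presence = rng.random((cfg.n_pangene_loci, len(accs))) < cfg.locus_presence_prob
    for i in range(cfg.n_pangene_loci):
        if not presence[i].any():
            presence[i, int(rng.integers(len(accs)))] = True

    genes: dict[str, list[str]] = {a: [] for a in accs}
    for i in range(cfg.n_pangene_loci):
        for j, acc in enumerate(accs):
            if presence[i, j]:
                genes[acc].append(f"{acc}_g{i:05d}")

    maps: dict[frozenset, list[tuple[str, str]]] = {}
    for j1 in range(len(accs)):
        for j2 in range(j1 + 1, len(accs)):
            pair = frozenset((accs[j1], accs[j2]))
            anchors = [
                (f"{accs[j1]}_g{i:05d}", f"{accs[j2]}_g{i:05d}")
                for i in range(cfg.n_pangene_loci)
                if presence[i, j1] and presence[i, j2]
            ]
            maps[pair] = anchors
    core_truth = int(presence.all(axis=1).sum())
    return genes, maps, accs, core_truth
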