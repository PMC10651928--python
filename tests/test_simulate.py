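"""Determinism and planted-truth guarantees of the synthetic generator."""
import numpy as np
import pytest

from pansv import (
    CallerModel,
    PipelineConfig,
    SimConfig,
    SVType,
    classify_cluster,
    consensus_candidates,
    frequency_spectrum,
    merge_across_accessions,
    simulate_annotation,
    simulate_clusters,
    simulate_cnv_expression,
    simulate_sv_truth,
    te_composition,
    union_overlap_ratio,
    assign_context,
)

SMALL = dict(chrom_lengths={"chr01": 3_000_000}, n_accessions=5)


def _perfect_callers():
    return {
        name: CallerModel(sensitivity=1.0, fp_per_mb=0.0, jitter_frac=0.0,
                          anchor_jitter_bp=0, length_jitter_frac=0.0)
        for name in ("syri-like", "assemblytics-like", "svmu-like")
    }


def test_generator_is_seed_deterministic():
    a = simulate_sv_truth(SimConfig(seed=5, **SMALL))
    b = simulate_sv_truth(SimConfig(seed=5, **SMALL))
    assert a.events == b.events
    assert a.callsets == b.callsets
    c = simulate_sv_truth(SimConfig(seed=6, **SMALL))
    assert c.events != a.events


def test_perfect_callers_reproduce_truth_exactly():
    sim = SimConfig(seed=7, callers=_perfect_callers(), **SMALL)
    truth = simulate_sv_truth(sim)
    for event in truth.events:
        for acc in event.accessions:
            for name, calls in truth.callsets[acc].items():
                matching = [
                    c for c in calls if truth.call_truth[c.id] == event.id
                ]
                assert len(matching) == 1
                call = matching[0]
                assert call.sv_type is event.sv_type
                assert call.interval == event.representative
                assert call.sv_length == event.sv_length


def test_zero_sensitivity_gives_empty_callsets():
    callers = {
        name: CallerModel(sensitivity=0.0, fp_per_mb=0.0)
        for name in ("syri-like", "assemblytics-like", "svmu-like")
    }
    truth = simulate_sv_truth(SimConfig(seed=8, callers=callers, **SMALL))
    assert all(
        not calls
        for by_caller in truth.callsets.values()
        for calls in by_caller.values()
    )


def test_small_jitter_keeps_union_ratio_above_worst_case_bound():
    """Jitter of +-5 bp on >=200 bp absence events keeps any two observations
    of the same event above (L-10)/(L+10) >= 190/210 overlap ratio."""
    callers = {
        name: CallerModel(sensitivity=1.0, fp_per_mb=0.0, jitter_frac=0.025)
        for name in ("syri-like", "assemblytics-like", "svmu-like")
    }
    sim = SimConfig(seed=9, callers=callers, **SMALL)
    truth = simulate_sv_truth(sim)
    for event in truth.events:
        if event.sv_type is not SVType.ABSENCE or event.sv_length < 200:
            continue
        obs = [
            c
            for acc in event.accessions
            for calls in truth.callsets[acc].values()
            for c in calls
            if truth.call_truth[c.id] == event.id
        ]
        length = event.sv_length
        j = int(round(0.025 * length))
        bound = (length - 2 * j) / (length + 2 * j)
        for i in range(len(obs)):
            for k in range(i + 1, len(obs)):
                assert (
                    union_overlap_ratio(obs[i].interval, obs[k].interval)
                    >= bound - 1e-12
                )


def test_jittered_calls_preserve_type_and_trace_to_truth():
    truth = simulate_sv_truth(SimConfig(seed=10, **SMALL))
    by_id = {e.id: e for e in truth.events}
    for acc, by_caller in truth.callsets.items():
        for calls in by_caller.values():
            for c in calls:
                origin = truth.call_truth[c.id]
                if origin == "fp":
                    continue
                assert c.sv_type is by_id[origin].sv_type
                assert acc in by_id[origin].accessions


def test_end_to_end_recovery_of_truth_frequency_spectrum():
    """With perfect callers and no false positives the pipeline reconstructs
    the planted frequency spectrum exactly."""
    sim = SimConfig(seed=20, callers=_perfect_callers(), **SMALL)
    truth = simulate_sv_truth(sim)
    cfg = PipelineConfig(n_accessions=sim.n_accessions, softcore_min=4)
    cands = {
        acc: consensus_candidates(truth.callsets[acc], cfg)
        for acc in sim.accessions
    }
    merged = merge_across_accessions(cands, cfg)
    got = frequency_spectrum(merged, sim.n_accessions)
    want = frequency_spectrum(truth.events, sim.n_accessions)
    assert got == want


def test_cluster_labels_equal_classifier_output():
    sim = SimConfig(seed=21, n_clusters=500)
    clusters, labels = simulate_clusters(sim)
    cfg = PipelineConfig()
    assert all(
        labels[c.cluster_id] == classify_cluster(c.n_present, cfg) for c in clusters
    )


def test_cluster_proportions_converge_to_planted_proportions():
    sim = SimConfig(seed=22, n_clusters=20_000)
    clusters, labels = simulate_clusters(sim)
    from collections import Counter

    freq = Counter(labels.values())
    for cat, prop in sim.category_props.items():
        assert freq[cat] / sim.n_clusters == pytest.approx(prop, abs=0.01)


def test_noise_free_planted_genes_reach_perfect_correlation():
    sim = SimConfig(seed=23, n_cnv_genes=50, expr_noise_sd=0.0)
    # zero noise makes the slope formula singular; plant a fixed slope instead
    cn, expr, planted = simulate_cnv_expression_no_noise(sim)
    for g in planted:
        x = cn.loc[g].to_numpy(dtype=float)
        y = expr["leaf"].loc[g].to_numpy(dtype=float)
        assert abs(np.corrcoef(x, y)[0, 1]) == pytest.approx(1.0)


def simulate_cnv_expression_no_noise(sim):
    """sigma=0 variant: expression exactly a + b*CN for planted genes."""
    from pansv import simulate as simmod

    rng = np.random.default_rng(sim.seed)
    genes = [f"G{i:06d}" for i in range(sim.n_cnv_genes)]
    accs = list(sim.accessions)
    import pandas as pd

    cn = pd.DataFrame(
        rng.integers(0, 4, size=(len(genes), len(accs))), index=genes, columns=accs
    )
    planted = set(genes[: len(genes) // 2])
    for g in planted:  # ensure variance
        if cn.loc[g].nunique() == 1:
            cn.loc[g, accs[0]] = cn.loc[g, accs[0]] + 1
    expr = {"leaf": cn * 2.0 + 5.0}
    return cn, expr, planted


def test_cnv_expression_matrices_are_seed_deterministic():
    a = simulate_cnv_expression(SimConfig(seed=24, n_cnv_genes=30))
    b = simulate_cnv_expression(SimConfig(seed=24, n_cnv_genes=30))
    assert a[0].equals(b[0])
    assert all(a[1][t].equals(b[1][t]) for t in a[1])
    assert a[2] == b[2]


def test_annotation_without_te_gives_zero_te_composition():
    sim = SimConfig(seed=25, te_genome_frac=0.0, te_pav_frac=0.0, gypsy_frac=0.0, **SMALL)
    truth = simulate_sv_truth(sim)
    index = simulate_annotation(sim, truth=truth)
    pavs = [e for e in truth.events if e.sv_type.value in ("presence", "absence")]
    frac, classes = te_composition(pavs, index, PipelineConfig())
    assert frac == 0.0 and classes == {}


def test_upstream_svs_label_promoter_by_construction():
    """Gene spacing exceeds twice the flank, so an SV 3 kb upstream of a
    gene can only be its promoter."""
    sim = SimConfig(seed=26, chrom_lengths={"chr01": 2_000_000})
    index = simulate_annotation(sim)
    cfg = PipelineConfig()
    from conftest import make_merged

    checked = 0
    for gene in index.genes[:20]:
        if gene.strand != "+" or gene.span.start < 4_000:
            continue
        sv = make_merged("chr01", gene.span.start - 3_000, gene.span.start - 2_900)
        assert assign_context(sv, index, cfg) == "promoter"
        checked += 1
    assert checked > 0


def test_annotation_gene_bodies_do_not_overlap():
    sim = SimConfig(seed=27, **SMALL)
    index = simulate_annotation(sim)
    spans = sorted((g.span for g in index.genes), key=lambda s: (s.chrom, s.start))
    for a, b in zip(spans, spans[1:]):
        if a.chrom == b.chrom:
            assert a.end <= b.start
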