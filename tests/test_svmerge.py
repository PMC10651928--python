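"""Overlap-ratio rules, three-caller consensus, cross-accession merging."""
import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pansv import (
    ConfigurationError,
    GenomicInterval,
    PipelineConfig,
    SVType,
    ValidationError,
    consensus_candidates,
    frequency_spectrum,
    is_same_presence,
    length_ratio,
    merge_across_accessions,
    union_overlap_ratio,
)
from pansv.svmerge import _pair_same

from conftest import make_absence, make_merged, make_presence


# ---------------------------------------------------------------------------
# pairwise rules


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ((100, 200), (100, 200), 1.0),
        ((0, 100), (200, 300), 0.0),
        ((0, 100), (10, 110), 90 / 110),
        ((0, 100), (50, 150), 50 / 150),
    ],
)
def test_union_overlap_ratio_values(a, b, expected):
    ia = GenomicInterval("chr1", *a)
    ib = GenomicInterval("chr1", *b)
    assert union_overlap_ratio(ia, ib) == pytest.approx(expected)
    assert union_overlap_ratio(ib, ia) == pytest.approx(expected)  # symmetric


def test_union_overlap_ratio_different_chromosomes_is_zero():
    a = GenomicInterval("chr1", 0, 100)
    b = GenomicInterval("chr2", 0, 100)
    assert union_overlap_ratio(a, b) == 0.0


@pytest.mark.parametrize(
    "la, lb, expected", [(100, 100, 1.0), (90, 100, 0.9), (10, 100, 0.1)]
)
def test_length_ratio_values(la, lb, expected):
    a = make_presence("chr1", 1000, la)
    b = make_presence("chr1", 1000, lb)
    assert length_ratio(a, b) == pytest.approx(expected)
    assert length_ratio(b, a) == pytest.approx(expected)


@pytest.mark.parametrize(
    "lb, anchor_b, expected",
    [
        (95, 1003, True),   # ratio 0.95, distance 3 -> both rules pass
        (95, 1010, False),  # distance 10 >= 5 bp tolerance
        (89, 1003, False),  # ratio 0.89 fails the >0.90 rule
    ],
)
def test_is_same_presence_rules(cfg, lb, anchor_b, expected):
    a = make_presence("chr1", 1000, 100)
    b = make_presence("chr1", anchor_b, lb)
    assert is_same_presence(a, b, cfg) is expected


@given(
    start=st.integers(0, 10_000),
    length=st.integers(1, 5_000),
    shift=st.integers(-5_000, 5_000),
)
@settings(max_examples=200, derandomize=True)
def test_overlap_ratio_symmetric_and_one_iff_identical(start, length, shift):
    a = GenomicInterval("chr1", start, start + length)
    b_start = max(0, start + shift)
    b = GenomicInterval("chr1", b_start, b_start + length + abs(shift) % 7 + (shift == 0))
    r1, r2 = union_overlap_ratio(a, b), union_overlap_ratio(b, a)
    assert r1 == r2
    assert (r1 == 1.0) == (a == b)


# ---------------------------------------------------------------------------
# three-caller consensus

CALLERS = ("syri-like", "assemblytics-like", "svmu-like")


def test_identical_absence_from_three_callers_is_one_candidate(cfg):
    sets = {
        c: [make_absence("chr1", 1000, 2000, caller=c, id=f"{c}.1")] for c in CALLERS
    }
    (cand,) = consensus_candidates(sets, cfg)
    assert cand.representative == GenomicInterval("chr1", 1000, 2000)
    assert len(cand.members) == 3


def test_two_caller_support_yields_no_candidate(cfg):
    sets = {
        CALLERS[0]: [make_absence("chr1", 1000, 2000, caller=CALLERS[0])],
        CALLERS[1]: [make_absence("chr1", 1000, 2000, caller=CALLERS[1])],
        CALLERS[2]: [],
    }
    assert consensus_candidates(sets, cfg) == []


def test_unknown_caller_identifier_is_configuration_error(cfg):
    with pytest.raises(ConfigurationError, match="unknown caller"):
        consensus_candidates({"delly": []}, cfg)


def test_inversion_translocation_candidates_come_from_primary_caller_only(cfg):
    sets = {c: [_typed("chr1", 10_000, 60_000, SVType.INVERSION, c)] for c in CALLERS}
    cands = consensus_candidates(sets, cfg)
    assert len(cands) == 1
    assert cands[0].members == (f"{cfg.primary_caller}.inv",)


def _typed(chrom, start, end, sv_type, caller):
    from pansv import SVCall

    iv = GenomicInterval(chrom, start, end)
    return SVCall(
        interval=iv,
        sv_type=sv_type,
        sv_length=iv.length,
        accession="GS",
        caller=caller,
        id=f"{caller}.inv",
    )


def _brute_force_consensus(sets, cfg):
    """Oracle: enumerate all cross-caller triples, keep those with all three
    pairwise similarities passing, assign greedily by best minimum ratio."""
    from pansv.svmerge import _pair_ratio

    c1, c2, c3 = cfg.callers
    triples = []
    for a in sets[c1]:
        for b in sets[c2]:
            for c in sets[c3]:
                if a.sv_type is not b.sv_type or b.sv_type is not c.sv_type:
                    continue
                if a.sv_type in (SVType.INVERSION, SVType.TRANSLOCATION):
                    continue
                if (
                    _pair_same(a, b, cfg)
                    and _pair_same(a, c, cfg)
                    and _pair_same(b, c, cfg)
                ):
                    score = min(
                        _pair_ratio(a, b), _pair_ratio(a, c), _pair_ratio(b, c)
                    )
                    triples.append((score, a, b, c))
    triples.sort(key=lambda t: (-t[0], t[1].start, t[1].id, t[2].id, t[3].id))
    used, chosen = set(), []
    for score, a, b, c in triples:
        ids = {a.id, b.id, c.id}
        if ids & used:
            continue
        used |= ids
        chosen.append(frozenset(ids))
    return set(chosen)


def test_consensus_matches_brute_force_triple_oracle(cfg):
    """Jittered calls over planted events: candidate triples equal the
    exhaustive enumeration over all cross-caller triples."""
    rng = np.random.default_rng(42)
    for _ in range(50):
        n_events = rng.integers(2, 6)
        sets = {c: [] for c in CALLERS}
        for e in range(n_events):
            start = int(rng.integers(0, 100_000))
            length = int(rng.integers(200, 2_000))
            for c in CALLERS:
                if rng.random() < 0.85:  # dropouts
                    j = int(0.02 * length)
                    s = max(0, start + int(rng.integers(-j, j + 1)))
                    t = s + length + int(rng.integers(-j, j + 1))
                    sets[c].append(
                        make_absence("chr1", s, t, caller=c, id=f"{c}.e{e}")
                    )
        got = consensus_candidates(sets, cfg)
        got_sets = {frozenset(m.members) for m in got}
        assert got_sets == _brute_force_consensus(sets, cfg)


# ---------------------------------------------------------------------------
# cross-accession merging


def test_same_absence_in_13_accessions_merges_to_frequency_13(cfg):
    cands = [
        make_merged("chr1", 5000, 9000, accessions=(f"A{i:02d}",),
                    members=(f"m{i}",))
        for i in range(13)
    ]
    (merged,) = merge_across_accessions(cands, cfg)
    assert merged.frequency == 13
    assert frequency_spectrum([merged], 13)[13] == 1


def test_union_ratio_085_stays_split(cfg):
    # [0,100) vs [0,85)/[0,100) union ratio = 85/100 = 0.85 < 0.90
    a = make_merged("chr1", 0, 100, accessions=("GS",), members=("a",))
    b = make_merged("chr1", 0, 85, accessions=("GA",), members=("b",))
    assert len(merge_across_accessions([a, b], cfg)) == 2


def test_single_linkage_chains_transitively(cfg):
    # A~B and B~C pass, A~C fails -> one cluster {A,B,C} under single linkage
    a = make_merged("chr1", 0, 1000, accessions=("GS",), members=("a",))
    b = make_merged("chr1", 40, 1040, accessions=("GA",), members=("b",))
    c = make_merged("chr1", 85, 1085, accessions=("OR",), members=("c",))
    assert union_overlap_ratio(a.representative, b.representative) > 0.9
    assert union_overlap_ratio(b.representative, c.representative) > 0.9
    assert union_overlap_ratio(a.representative, c.representative) < 0.9
    (merged,) = merge_across_accessions([a, b, c], cfg)
    assert merged.accessions == {"GS", "GA", "OR"}
    assert merged.min_pair_ratio == pytest.approx(
        union_overlap_ratio(a.representative, c.representative)
    )


def test_merge_is_idempotent(cfg):
    rng = np.random.default_rng(7)
    cands = _random_candidates(rng, 40)
    once = merge_across_accessions(cands, cfg)
    twice = merge_across_accessions(once, cfg)
    assert once == twice


def test_merge_is_input_order_invariant(cfg):
    rng = np.random.default_rng(11)
    cands = _random_candidates(rng, 30)
    ref = merge_across_accessions(cands, cfg)
    for seed in range(5):
        shuffled = list(cands)
        np.random.default_rng(seed).shuffle(shuffled)
        assert merge_across_accessions(shuffled, cfg) == ref


def test_raising_threshold_never_decreases_merged_count():
    rng = np.random.default_rng(13)
    cands = _random_candidates(rng, 50)
    counts = []
    for thr in (0.5, 0.7, 0.9, 0.95):
        cfg = PipelineConfig(merge_ratio_threshold=thr)
        counts.append(len(merge_across_accessions(cands, cfg)))
    assert counts == sorted(counts)


def test_mixed_types_in_internal_clustering_rejected(cfg):
    from pansv.svmerge import _merge_one_type

    a = make_merged("chr1", 0, 100, sv_type=SVType.ABSENCE, members=("a",))
    b = make_merged("chr1", 0, 1, sv_type=SVType.PRESENCE, sv_length=50, members=("b",))
    with pytest.raises(ValidationError, match="mixed"):
        _merge_one_type([a, b], cfg)


def _random_candidates(rng, n, chrom="chr1"):
    cands = []
    for i in range(n):
        start = int(rng.integers(0, 20_000))
        length = int(rng.integers(50, 3_000))
        acc = f"A{int(rng.integers(0, 13)):02d}"
        cands.append(
            make_merged(chrom, start, start + length, accessions=(acc,),
                        members=(f"m{i}",))
        )
    return cands


def _oracle_single_linkage(cands, cfg):
    """Exhaustive pairwise graph + connected components (networkx)."""
    g = nx.Graph()
    g.add_nodes_from(range(len(cands)))
    for i, j in itertools.combinations(range(len(cands)), 2):
        a, b = cands[i], cands[j]
        if a.sv_type is not b.sv_type:
            continue
        if a.sv_type is SVType.PRESENCE:
            same = (
                a.chrom == b.chrom
                and abs(a.start - b.start) < cfg.presence_anchor_tol
                and min(a.sv_length, b.sv_length) / max(a.sv_length, b.sv_length)
                > cfg.merge_ratio_threshold
            )
        else:
            same = (
                union_overlap_ratio(a.representative, b.representative)
                > cfg.merge_ratio_threshold
            )
        if same:
            g.add_edge(i, j)
    return {
        frozenset(m for k in comp for m in cands[k].members)
        for comp in nx.connected_components(g)
    }


def test_merge_equals_connected_components_oracle(cfg):
    rng = np.random.default_rng(17)
    for _ in range(100):
        cands = _random_candidates(rng, int(rng.integers(2, 50)))
        merged = merge_across_accessions(cands, cfg)
        assert {frozenset(m.members) for m in merged} == _oracle_single_linkage(
            cands, cfg
        )


# ---------------------------------------------------------------------------
# frequency spectrum


def test_frequency_spectrum_counts_and_bounds(cfg):
    svs = [
        make_merged("chr1", i * 10_000, i * 10_000 + 500, accessions=(f"A{i}",))
        for i in range(3)
    ]
    assert frequency_spectrum(svs, 13) == {f: (3 if f == 1 else 0) for f in range(1, 14)}
    with pytest.raises(ValidationError):
        frequency_spectrum(svs, 0)
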