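"""Overlap-ratio SV consensus and cross-accession merging.

Two similarity rules drive everything here:

* absence / inversion / translocation SVs compare by the **union overlap
  ratio** — overlapping length divided by the non-redundant length covered
  by the two intervals (interval Jaccard);
* presence (insertion) SVs compare by the **length ratio** (shorter /
  longer inserted length) combined with a reference-anchor distance below
  5 bp, because inserted sequence has no reference extent to overlap.

Within one accession, a candidate SV requires concordant calls from all
three callers (pairwise similarity above the threshold inside a
cross-caller triple); inversions and translocations are taken from the
designated primary caller only.  Across accessions candidates are merged
by single-linkage clustering under the same type-appropriate predicate.
"""
from __future__ import annotations

import itertools
from bisect import bisect_left, bisect_right
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError, ValidationError
from .model import (
    GenomicInterval,
    MergedSV,
    PipelineConfig,
    SVCall,
    SVType,
    sort_calls,
)


class _UnionFind:
    """Array-based disjoint sets for single-linkage clustering."""

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def union_overlap_ratio(a: GenomicInterval, b: GenomicInterval) -> float:
    """|a ∩ b| / |a ∪ b| with the union taken as non-redundant covered length.

    Intervals on different chromosomes do not overlap and return 0.0.
    Symmetric; equals 1.0 iff the intervals are identical.
    """
    inter = a.intersection_length(b)
    if inter == 0:
        return 0.0
    union = a.length + b.length - inter
    return inter / union


def length_ratio(a: SVCall, b: SVCall) -> float:
    """Shorter / longer inserted length for two presence SVs."""
    for call in (a, b):
        if call.sv_length <= 0:
            raise ValidationError(f"presence SV with non-positive length: {call.id}")
    lo, hi = sorted((a.sv_length, b.sv_length))
    return lo / hi


def is_same_presence(a: SVCall, b: SVCall, cfg: PipelineConfig) -> bool:
    """Presence merge rule: length ratio above threshold AND reference anchors
    (start positions) closer than the anchor tolerance."""
    if a.chrom != b.chrom:
        return False
    if abs(a.start - b.start) >= cfg.presence_anchor_tol:
        return False
    return cfg.meets(length_ratio(a, b))


def _pair_ratio(a: SVCall, b: SVCall) -> float:
    if a.sv_type is SVType.PRESENCE:
        return length_ratio(a, b)
    return union_overlap_ratio(a.interval, b.interval)


def _pair_same(a: SVCall, b: SVCall, cfg: PipelineConfig) -> bool:
    if a.sv_type is SVType.PRESENCE:
        return is_same_presence(a, b, cfg)
    return cfg.meets(union_overlap_ratio(a.interval, b.interval))


def _representative(calls: Sequence[SVCall]) -> SVCall:
    """Longest interval wins; ties by smallest start, then canonical order."""
    return min(
        calls,
        key=lambda c: (
            -c.interval.length,
            c.interval.start,
            c.interval.chrom,
            c.accession,
            c.caller,
            c.id,
        ),
    )


def _min_pair_ratio(calls: Sequence[SVCall]) -> float:
    if len(calls) == 1:
        return 1.0
    return min(_pair_ratio(a, b) for a, b in itertools.combinations(calls, 2))


def _as_merged(calls: Sequence[SVCall], min_ratio: float | None = None) -> MergedSV:
    rep = _representative(calls)
    return MergedSV(
        representative=rep.interval,
        sv_type=rep.sv_type,
        sv_length=rep.sv_length,
        members=tuple(c.id for c in sort_calls(calls)),
        accessions=frozenset(c.accession for c in calls),
        min_pair_ratio=_min_pair_ratio(calls) if min_ratio is None else min_ratio,
    )


def _compatible_range(
    calls: Sequence[SVCall], starts: Sequence[int], query: SVCall, cfg: PipelineConfig
) -> list[SVCall]:
    """Calls from a start-sorted list that may satisfy the pairwise predicate."""
    if query.sv_type is SVType.PRESENCE:
        lo = bisect_left(starts, query.start - cfg.presence_anchor_tol)
        hi = bisect_right(starts, query.start + cfg.presence_anchor_tol)
    else:
        # overlap ratio > 0 requires the partner to start before query.end and
        # end after query.start; partner length is unbounded, so scan from the
        # left edge of anything still overlapping.
        lo = 0
        hi = bisect_right(starts, query.interval.end)
    return [c for c in calls[lo:hi] if _pair_same(c, query, cfg)]


def consensus_candidates(
    callsets: Mapping[str, Sequence[SVCall]],
    cfg: PipelineConfig,
) -> list[MergedSV]:
    """Three-caller consensus for one accession.

    Absence and presence candidates require one call from each of the three
    configured callers with all three pairwise similarities above the merge
    threshold; each input call supports at most one candidate (triples are
    assigned greedily, best minimum-pairwise-ratio first).  Inversion and
    translocation candidates are exactly the calls of the primary caller.
    """
    unknown = set(callsets) - set(cfg.callers)
    if unknown:
        raise ConfigurationError(
            f"unknown caller identifier(s): {sorted(unknown)}; configured callers "
            f"are {list(cfg.callers)}"
        )

    by_caller: dict[str, list[SVCall]] = {
        name: sort_calls(callsets.get(name, [])) for name in cfg.callers
    }

    out: list[MergedSV] = []

    # inversions / translocations: primary caller only, one candidate per call
    for call in by_caller[cfg.primary_caller]:
        if call.sv_type in (SVType.INVERSION, SVType.TRANSLOCATION):
            out.append(_as_merged([call]))

    # PAV consensus per (chrom, type)
    for sv_type in (SVType.ABSENCE, SVType.PRESENCE):
        grouped: dict[str, dict[str, list[SVCall]]] = defaultdict(dict)
        for name in cfg.callers:
            for chrom, calls in _group_by_chrom(by_caller[name], sv_type).items():
                grouped[chrom][name] = calls
        for chrom in sorted(grouped):
            out.extend(_consensus_one_group(grouped[chrom], cfg))

    return sorted(out, key=lambda m: (m.chrom, m.start, m.representative.end))


def _group_by_chrom(calls: Sequence[SVCall], sv_type: SVType) -> dict[str, list[SVCall]]:
    groups: dict[str, list[SVCall]] = defaultdict(list)
    for c in calls:
        if c.sv_type is sv_type:
            groups[c.chrom].append(c)
    return groups


def _consensus_one_group(
    by_caller: Mapping[str, Sequence[SVCall]], cfg: PipelineConfig
) -> list[MergedSV]:
    c1, c2, c3 = cfg.callers
    calls2 = list(by_caller.get(c2, []))
    calls3 = list(by_caller.get(c3, []))
    starts2 = [c.start for c in calls2]
    starts3 = [c.start for c in calls3]

    triples: list[tuple[float, SVCall, SVCall, SVCall]] = []
    for a in by_caller.get(c1, []):
        partners2 = _compatible_range(calls2, starts2, a, cfg)
        if not partners2:
            continue
        partners3 = _compatible_range(calls3, starts3, a, cfg)
        for b in partners2:
            for c in partners3:
                if _pair_same(b, c, cfg):
                    score = min(_pair_ratio(a, b), _pair_ratio(a, c), _pair_ratio(b, c))
                    triples.append((score, a, b, c))

    # greedy best-score-first; each call supports at most one candidate
    triples.sort(key=lambda t: (-t[0], t[1].start, t[1].id, t[2].id, t[3].id))
    used: set[str] = set()
    out: list[MergedSV] = []
    for score, a, b, c in triples:
        ids = {a.id, b.id, c.id}
        if ids & used:
            continue
        used |= ids
        out.append(_as_merged([a, b, c], min_ratio=score))
    return out


def merge_across_accessions(
    candidates: Iterable[MergedSV] | Mapping[str, Sequence[MergedSV]],
    cfg: PipelineConfig,
) -> list[MergedSV]:
    """Merge per-accession candidate SVs into a non-redundant pan-SV set.

    Single-linkage clustering under the type-appropriate predicate
    (union overlap ratio above the threshold for absence / inversion /
    translocation; the length-ratio + anchor rule for presence).  The
    result is deterministic and independent of input order: members are
    canonically sorted before clustering.
    """
    if isinstance(candidates, Mapping):
        flat = [m for acc in sorted(candidates) for m in candidates[acc]]
    else:
        flat = list(candidates)

    out: list[MergedSV] = []
    by_type: dict[SVType, list[MergedSV]] = defaultdict(list)
    for m in flat:
        by_type[m.sv_type].append(m)
    for sv_type in sorted(by_type, key=lambda t: t.value):
        out.extend(_merge_one_type(by_type[sv_type], cfg))
    return sorted(out, key=lambda m: (m.chrom, m.start, m.representative.end))


def _proxy_call(m: MergedSV, idx: int) -> SVCall:
    """View a candidate through its representative for pairwise comparison."""
    return SVCall(
        interval=m.representative,
        sv_type=m.sv_type,
        sv_length=m.sv_length,
        accession=sorted(m.accessions)[0],
        id=m.id or f"cand{idx}",
    )


def _merge_one_type(cands: list[MergedSV], cfg: PipelineConfig) -> list[MergedSV]:
    if not cands:
        return []
    sv_type = cands[0].sv_type
    if any(m.sv_type is not sv_type for m in cands):
        raise ValidationError("mixed SV types inside one clustering call")

    cands = sorted(
        cands,
        key=lambda m: (
            m.chrom,
            m.start,
            m.representative.end,
            m.sv_length,
            m.members,
        ),
    )
    proxies = [_proxy_call(m, i) for i, m in enumerate(cands)]

    uf = _UnionFind(len(cands))
    # sweep: candidates are start-sorted per chromosome; only nearby pairs can
    # satisfy either predicate.
    active: list[int] = []
    for i, p in enumerate(proxies):
        still = []
        for j in active:
            q = proxies[j]
            if q.chrom != p.chrom:
                continue
            if sv_type is SVType.PRESENCE:
                if q.start >= p.start - cfg.presence_anchor_tol:
                    still.append(j)
            elif q.interval.end > p.start:
                still.append(j)
        active = still
        for j in active:
            if _pair_same(proxies[j], p, cfg):
                uf.union(i, j)
        active.append(i)

    clusters: dict[int, list[int]] = defaultdict(list)
    for i in range(len(cands)):
        clusters[uf.find(i)].append(i)

    out = []
    for root in sorted(clusters):
        idxs = clusters[root]
        group = [cands[i] for i in idxs]
        rep = min(
            group,
            key=lambda m: (
                -m.representative.length,
                m.representative.start,
                m.representative.chrom,
                m.members,
            ),
        )
        ratios = [1.0]
        if len(idxs) > 1:
            ratios = [
                _pair_ratio(proxies[i], proxies[j])
                for i, j in itertools.combinations(idxs, 2)
            ]
        members = tuple(sorted(set(itertools.chain(*(m.members for m in group)))))
        accs = frozenset(itertools.chain(*(m.accessions for m in group)))
        te_classes = {m.inserted_te_class for m in group} - {None}
        out.append(
            MergedSV(
                representative=rep.representative,
                sv_type=sv_type,
                sv_length=rep.sv_length,
                members=members,
                accessions=accs,
                min_pair_ratio=min(ratios),
                inserted_te_class=sorted(te_classes)[0] if te_classes else None,
            )
        )
    return out


def frequency_spectrum(
    merged: Iterable[MergedSV], n_accessions: int
) -> dict[int, int]:
    """Histogram of per-SV accession frequencies over 1..n_accessions."""
    spectrum = {f: 0 for f in range(1, n_accessions + 1)}
    for m in merged:
        if not (1 <= m.frequency <= n_accessions):
            raise ValidationError(
                f"SV frequency {m.frequency} outside [1, {n_accessions}]"
            )
        spectrum[m.frequency] += 1
    return spectrum
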