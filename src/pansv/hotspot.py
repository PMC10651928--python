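"""SV hotspot detection by sliding-window breakpoint counting.

Breakpoints (SV start and end; one anchor point for insertions) are counted
in 400 kb windows sliding by 200 kb along each chromosome; the top decile of
windows by breakpoint count are hotspots, and contiguous (overlapping or
abutting) hotspot windows are merged into hotspot regions.
"""
from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .model import GenomicInterval, MergedSV, PipelineConfig, SVType


@dataclass(frozen=True)
class WindowCount:
    window: GenomicInterval
    breakpoints: int


@dataclass(frozen=True)
class HotspotRegion:
    region: GenomicInterval
    windows: tuple[WindowCount, ...]

    @property
    def peak(self) -> int:
        return max(w.breakpoints for w in self.windows)


def _sv_breakpoints(sv: MergedSV) -> list[int]:
    iv = sv.representative
    if sv.sv_type is SVType.PRESENCE:
        return [iv.start]
    return [iv.start, iv.end]


def window_breakpoint_counts(
    svs: Iterable[MergedSV],
    chrom_lengths: Mapping[str, int],
    cfg: PipelineConfig,
) -> list[WindowCount]:
    """Breakpoint counts for every sliding window on every chromosome.

    A breakpoint at position p is counted in every window containing p;
    with window = 2 x step that is two windows away from chromosome edges.
    Terminal windows are truncated at the chromosome end and keep raw counts.
    """
    window, step = cfg.hotspot_window, cfg.hotspot_step
    points: dict[str, list[int]] = defaultdict(list)
    for sv in svs:
        length = chrom_lengths.get(sv.chrom)
        if length is None:
            raise ValidationError(f"SV on chromosome {sv.chrom} missing from lengths")
        if sv.representative.end > length:
            raise ValidationError(
                f"SV [{sv.start}, {sv.representative.end}) beyond chromosome "
                f"{sv.chrom} length {length}"
            )
        points[sv.chrom].extend(_sv_breakpoints(sv))

    out: list[WindowCount] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        n_windows = max(1, math.ceil(max(length - window, 0) / step) + 1)
        counts = np.zeros(n_windows, dtype=int)
        for p in points.get(chrom, []):
            # windows with i*step <= p < i*step + window
            i_max = min(n_windows - 1, p // step)
            i_min = max(0, (p - window) // step + 1)
            counts[i_min : i_max + 1] += 1
        for i in range(n_windows):
            start = i * step
            end = min(start + window, length)
            out.append(WindowCount(GenomicInterval(chrom, start, end), int(counts[i])))
    return out


def select_hotspots(
    windows: Sequence[WindowCount], cfg: PipelineConfig
) -> list[HotspotRegion]:
    """Top-decile windows merged into hotspot regions.

    Exactly ``ceil(hotspot_top_frac * len(windows))`` windows are selected by
    descending breakpoint count, ties broken by (chrom, start) for
    reproducibility; overlapping or abutting selected windows merge.
    """
    if not windows:
        raise ValidationError("select_hotspots requires at least one window")
    k = math.ceil(cfg.hotspot_top_frac * len(windows))
    ranked = sorted(
        windows, key=lambda w: (-w.breakpoints, w.window.chrom, w.window.start)
    )
    selected = sorted(ranked[:k], key=lambda w: (w.window.chrom, w.window.start))

    regions: list[HotspotRegion] = []
    group: list[WindowCount] = []
    for w in selected:
        if group and (
            w.window.chrom != group[-1].window.chrom
            or w.window.start > group[-1].window.end
        ):
            regions.append(_close_region(group))
            group = []
        group.append(w)
    if group:
        regions.append(_close_region(group))
    return regions


def _close_region(group: list[WindowCount]) -> HotspotRegion:
    region = GenomicInterval(
        group[0].window.chrom,
        group[0].window.start,
        max(w.window.end for w in group),
    )
    return HotspotRegion(region=region, windows=tuple(group))
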