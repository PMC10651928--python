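"""Core value types shared across the pipeline.

Coordinates are 0-based half-open throughout the package; GFF3/VCF I/O in
:mod:`pansv.io` converts from/to the 1-based inclusive conventions of those
formats.  Length arithmetic is therefore always ``end - start``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

from .errors import ValidationError


class SVType(str, Enum):
    """The four structural-variant classes handled by the pipeline.

    ``presence`` is an insertion relative to the reference; ``absence`` a
    deletion.  Together they form presence/absence variation (PAV), the
    dominant SV class in plant pan-genomes.
    """

    PRESENCE = "presence"
    ABSENCE = "absence"
    INVERSION = "inversion"
    TRANSLOCATION = "translocation"

    @classmethod
    def coerce(cls, value: "SVType | str") -> "SVType":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValidationError(f"unknown SV type: {value!r}") from None


#: PAV = presence/absence variation subset of SV types.
PAV_TYPES = frozenset({SVType.PRESENCE, SVType.ABSENCE})


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chromosome identifier must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class SVCall:
    """One caller's observation of one SV in one accession.

    For ``absence``/``inversion``/``translocation`` the interval is the
    affected reference segment and ``sv_length == interval.length`` for
    absence.  For ``presence`` (insertion) the interval is a 1-2 bp
    breakpoint anchor on the reference and ``sv_length`` is the inserted
    length, which is absent from the reference itself.
    """

    interval: GenomicInterval
    sv_type: SVType
    sv_length: int
    accession: str
    caller: str = ""
    id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sv_type", SVType.coerce(self.sv_type))
        if self.sv_length <= 0:
            raise ValidationError(
                f"sv_length must be positive, got {self.sv_length} ({self.id or 'unnamed'})"
            )
        if self.sv_type is SVType.ABSENCE and self.sv_length != self.interval.length:
            raise ValidationError(
                "absence SV requires sv_length == interval length "
                f"({self.sv_length} != {self.interval.length})"
            )
        if self.sv_type is SVType.PRESENCE and self.interval.length > 2:
            raise ValidationError(
                "presence SV must be anchored by a point interval (length <= 2), "
                f"got length {self.interval.length}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start


@dataclass(frozen=True)
class MergedSV:
    """A consensus SV supported by one or more calls/accessions.

    ``representative`` is the interval of the longest member (ties broken by
    smallest start); ``min_pair_ratio`` records the smallest pairwise
    similarity inside the cluster, surfacing single-linkage non-transitivity.
    ``inserted_te_class`` optionally carries the TE annotation of an inserted
    sequence (presence SVs), used by TE-composition analysis.
    """

    representative: GenomicInterval
    sv_type: SVType
    sv_length: int
    members: tuple[str, ...]
    accessions: frozenset[str]
    id: str = ""
    min_pair_ratio: float | None = None
    inserted_te_class: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sv_type", SVType.coerce(self.sv_type))
        object.__setattr__(self, "members", tuple(self.members))
        object.__setattr__(self, "accessions", frozenset(self.accessions))
        if not self.members:
            raise ValidationError("MergedSV requires at least one member call")
        if not self.accessions:
            raise ValidationError("MergedSV requires at least one accession")

    @property
    def frequency(self) -> int:
        """Number of accessions carrying the SV."""
        return len(self.accessions)

    @property
    def chrom(self) -> str:
        return self.representative.chrom

    @property
    def start(self) -> int:
        return self.representative.start


DEFAULT_CALLERS = ("syri-like", "assemblytics-like", "svmu-like")


@dataclass
class PipelineConfig:
    """Numeric constants and switches of the whole pipeline.

    Defaults implement the published analysis settings: 90% overlap/length
    ratio for merging, 5 bp presence-anchor tolerance, +-5 kb gene context
    flank, 400 kb / 200 kb hotspot windows with a top-10% cut,
    identity/coverage > 90% for gene copy-number counting, and the
    p < 0.05 & |r| > 0.5 CNV-expression filter over 13 accessions.
    """

    merge_ratio_threshold: float = 0.90
    presence_anchor_tol: int = 5
    context_flank: int = 5_000
    hotspot_window: int = 400_000
    hotspot_step: int = 200_000
    hotspot_top_frac: float = 0.10
    cnv_identity_min: float = 0.90
    cnv_coverage_min: float = 0.90
    corr_p_max: float = 0.05
    corr_r_min: float = 0.5
    n_accessions: int = 13
    softcore_min: int = 11
    dispensable_min: int = 2
    profile_bin: int = 10
    te_overlap_frac: float = 0.5
    rng_seed: int = 0
    # operational switches (interpretations exposed as configuration)
    callers: tuple[str, str, str] = DEFAULT_CALLERS
    primary_caller: str = DEFAULT_CALLERS[0]
    strict_threshold: bool = True  # '>' if True else '>='
    cnv_locus_overlap: float = 0.5  # reciprocal overlap collapsing hits into loci

    def __post_init__(self) -> None:
        for name in (
            "merge_ratio_threshold",
            "hotspot_top_frac",
            "cnv_identity_min",
            "cnv_coverage_min",
            "te_overlap_frac",
        ):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValidationError(f"{name} must be in (0, 1], got {v}")
        if not (self.hotspot_window >= self.hotspot_step > 0):
            raise ValidationError("require hotspot_window >= hotspot_step > 0")
        if not (self.softcore_min < self.n_accessions):
            raise ValidationError("softcore_min must be below n_accessions")
        if self.dispensable_min < 2:
            raise ValidationError("dispensable_min must be >= 2")
        if self.dispensable_min >= self.softcore_min:
            raise ValidationError("dispensable_min must be below softcore_min")
        if len(set(self.callers)) != 3:
            raise ValidationError("exactly three distinct caller identifiers required")
        if self.primary_caller not in self.callers:
            raise ValidationError(
                f"primary caller {self.primary_caller!r} not among callers {self.callers}"
            )
        if self.context_flank % self.profile_bin != 0:
            raise ValidationError("profile_bin must divide context_flank")

    def meets(self, ratio: float) -> bool:
        """Apply the merge-ratio threshold with the configured operator."""
        if self.strict_threshold:
            return ratio > self.merge_ratio_threshold
        return ratio >= self.merge_ratio_threshold


def sort_calls(calls: Iterable[SVCall]) -> list[SVCall]:
    """Canonical (chrom, start, end, accession, caller, id) ordering."""
    return sorted(
        calls,
        key=lambda c: (
            c.interval.chrom,
            c.interval.start,
            c.interval.end,
            c.accession,
            c.caller,
            c.id,
        ),
    )
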