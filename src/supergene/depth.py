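"""MAPQ-filtered, library-normalized read depth and copy-state (dosage) calls.

The central inference of the package: a genomic region carried on *m* of *p*
haplotypes receives, after normalization, a median read depth of roughly
(m/p) x the depth of its flanking regions.  The dosage ratio
r = median(region) / median(flank) is therefore an estimator of m/p, and
rounding r*p with a guard band yields a copy-number call: null (m=0),
hemizygous (p=2, m=1), homozygous (m=p), or partial (0 < m < p for higher
ploidies).

Depth is accumulated only at reference positions consumed by CIGAR ops
M/=/X; deletions (D) and skips (N) contribute nothing.  Records that are
unmapped, secondary, supplementary, or below the MAPQ threshold (default 30)
are excluded.  Positions that are ambiguous (N) in the reference are masked
out of every summary statistic.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .core import Alignment, AnnotationSet, ContigSet, GenomicInterval
from .errors import (
    AlignmentOutOfBoundsError,
    ConfigError,
    EmptyUnitSetError,
    NoCdsError,
    ZeroFlankDepthError,
)

DEPTH_CONSUMING = frozenset("M=X")
REF_ADVANCING = frozenset("M=XDN")


@dataclass
class DepthProfile:
    """Per-base depth over one contig, with ambiguous-base mask."""

    contig: str
    depth: np.ndarray  # float64, length == contig length
    mask: np.ndarray  # bool, True at ambiguous (N) positions
    norm_factor: float = 1.0
    min_mapq: int | None = None

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.depth.shape != self.mask.shape:
            raise ValueError("depth and mask lengths differ")
        if (self.depth < 0).any():
            raise ValueError("negative depth")

    @property
    def length(self) -> int:
        return self.depth.size


@dataclass
class UnitSummary:
    """Depth summary over one window or CDS interval."""

    interval: GenomicInterval
    value: float  # mean (windows) or median (CDS); NaN when undefined
    n_unmasked: int
    in_region: bool | None = None

    @property
    def defined(self) -> bool:
        return self.n_unmasked > 0 and not math.isnan(self.value)


@dataclass
class DosageCall:
    """Region/flank medians, their ratio and the inferred copy state."""

    median_region: float
    median_flank: float
    ratio: float
    ploidy: int
    copy_number: int | None
    label: str  # null | hemizygous | homozygous | partial | ambiguous
    ci: tuple[float, float] | None = None
    n_region: int = 0
    n_flank: int = 0

    def to_dict(self) -> dict:
        return {
            "median_region": self.median_region,
            "median_flank": self.median_flank,
            "ratio": self.ratio,
            "ploidy": self.ploidy,
            "copy_number": self.copy_number,
            "label": self.label,
            "ci_95": list(self.ci) if self.ci is not None else None,
            "n_region": self.n_region,
            "n_flank": self.n_flank,
        }


# ---------------------------------------------------------------------------
# depth accumulation
# ---------------------------------------------------------------------------


def depth_from_alignments(
    alignments: Iterable[Alignment],
    contigs: ContigSet,
    contig: str,
    min_mapq: int = 30,
) -> DepthProfile:
    """Per-base depth on one contig from an alignment stream.

    Walks each CIGAR: M/=/X increment depth, D/N advance without depth,
    I/S/H consume no reference.  An alignment running past the contig end
    raises :class:`AlignmentOutOfBoundsError`.
    """
    length = contigs.length(contig)
    diff = np.zeros(length + 1, dtype=np.float64)
    for aln in alignments:
        if (
            aln.is_unmapped
            or aln.is_secondary
            or aln.is_supplementary
            or aln.contig != contig
            or aln.mapq < min_mapq
        ):
            continue
        pos = aln.pos0
        for op, n in aln.cigar:
            if op in DEPTH_CONSUMING:
                if pos + n > length:
                    raise AlignmentOutOfBoundsError(
                        f"alignment {aln.query_id} extends past end of {contig}"
                    )
                diff[pos] += 1
                diff[pos + n] -= 1
                pos += n
            elif op in "DN":
                pos += n
        if pos > length:
            raise AlignmentOutOfBoundsError(
                f"alignment {aln.query_id} extends past end of {contig}"
            )
    return DepthProfile(
        contig=contig,
        depth=np.cumsum(diff[:length]),
        mask=contigs.n_mask(contig),
        min_mapq=min_mapq,
    )


def depth_from_segments(
    contig: str,
    length: int,
    starts: np.ndarray,
    ends: np.ndarray,
    mapq: np.ndarray,
    min_mapq: int = 30,
    mask: np.ndarray | None = None,
) -> DepthProfile:
    """Vectorized depth from pre-resolved match segments.

    Fast path for simulator truth alignments, where every record is a plain
    match segment (or two segments around a deletion junction).  Equivalent
    to :func:`depth_from_alignments` on the corresponding SAM.
    """
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    keep = np.asarray(mapq) >= min_mapq
    if starts.size and int(ends.max(initial=0)) > length:
        raise AlignmentOutOfBoundsError("segment extends past end of contig")
    diff = np.zeros(length + 1, dtype=np.float64)
    np.add.at(diff, starts[keep], 1.0)
    np.add.at(diff, ends[keep], -1.0)
    if mask is None:
        mask = np.zeros(length, dtype=bool)
    return DepthProfile(
        contig=contig, depth=np.cumsum(diff[:length]), mask=mask, min_mapq=min_mapq
    )


def normalize(profile: DepthProfile, library_total_bases: float) -> DepthProfile:
    """Scale depth to 'per gigabase sequenced' so libraries are comparable.

    Each depth value is multiplied by 1e9 / library_total_bases; the factor
    is recorded on the returned profile.
    """
    if library_total_bases <= 0:
        raise ConfigError("library_total_bases must be positive")
    factor = 1e9 / float(library_total_bases)
    return replace(
        profile,
        depth=profile.depth * factor,
        norm_factor=profile.norm_factor * factor,
    )


# ---------------------------------------------------------------------------
# summary units
# ---------------------------------------------------------------------------


def window_means(profile: DepthProfile, window: int = 5000) -> list[UnitSummary]:
    """Mean depth in non-overlapping windows tiled from position 0.

    Means are taken over unmasked positions only; a trailing partial window
    is emitted with its true width; an entirely-masked window carries a NaN
    mean (flagged undefined via ``n_unmasked == 0``).
    """
    if window < 1:
        raise ConfigError("window must be >= 1")
    length = profile.length
    if length == 0:
        return []
    edges = np.arange(0, length, window)
    unmasked = (~profile.mask).astype(np.float64)
    sums = np.add.reduceat(profile.depth * unmasked, edges)
    counts = np.add.reduceat(unmasked, edges)
    out = []
    for i, s in enumerate(edges):
        e = min(s + window, length)
        n = int(counts[i])
        mean = float(sums[i] / n) if n > 0 else float("nan")
        out.append(
            UnitSummary(
                interval=GenomicInterval(profile.contig, int(s), int(e)),
                value=mean,
                n_unmasked=n,
            )
        )
    return out


def cds_depth(
    profile: DepthProfile,
    annotation: AnnotationSet,
    region: GenomicInterval | None = None,
) -> list[UnitSummary]:
    """Median depth per unique CDS interval, position-ordered.

    Restricting depth to coding sequence keeps cross-species read mapping
    honest (CDSs are the most conserved targets).  Each CDS is labeled as
    inside or outside the focal region by its midpoint.  A CDS wholly inside
    an N-gap carries a NaN median.
    """
    cds_ivs = annotation.cds_intervals(profile.contig)
    if not cds_ivs:
        raise NoCdsError(f"no CDS on contig {profile.contig}")
    out = []
    for iv in cds_ivs:
        sl = slice(iv.start, iv.end)
        vals = profile.depth[sl][~profile.mask[sl]]
        med = float(np.median(vals)) if vals.size else float("nan")
        out.append(
            UnitSummary(
                interval=iv,
                value=med,
                n_unmasked=int(vals.size),
                in_region=region.contains(iv.midpoint) if region else None,
            )
        )
    return out


def _partition_units(
    summaries: Sequence[UnitSummary],
    region: GenomicInterval,
    flanks: Sequence[GenomicInterval],
) -> tuple[list[float], list[float]]:
    region_vals, flank_vals = [], []
    for u in summaries:
        if not u.defined:
            continue
        mid = u.interval.midpoint
        if u.interval.contig == region.contig and region.contains(mid):
            region_vals.append(u.value)
        elif any(
            f.contig == u.interval.contig and f.contains(mid) for f in flanks
        ):
            flank_vals.append(u.value)
    return region_vals, flank_vals


def region_flank_medians(
    summaries: Sequence[UnitSummary],
    region: GenomicInterval,
    flanks: Sequence[GenomicInterval],
) -> tuple[float, float]:
    """Median of per-unit summaries inside the region and inside the flanks.

    Medians are taken over unit-level values (not per-base) for robustness;
    even counts use the midpoint of the central pair.  Undefined units are
    skipped.  Raises :class:`EmptyUnitSetError` when either side is empty.
    """
    region_vals, flank_vals = _partition_units(summaries, region, flanks)
    if not region_vals or not flank_vals:
        raise EmptyUnitSetError(
            f"no usable units (region n={len(region_vals)}, flank n={len(flank_vals)})"
        )
    return float(np.median(region_vals)), float(np.median(flank_vals))


# ---------------------------------------------------------------------------
# dosage call
# ---------------------------------------------------------------------------


def dosage_call(
    median_region: float,
    median_flank: float,
    ploidy: int,
    guard: float = 0.15,
) -> DosageCall:
    """Copy-state call from the region/flank depth ratio.

    r = median_region / median_flank estimates m/p.  m-hat = round(r*p) is
    accepted only when |r*p - m-hat| <= guard*p; outside the guard band the
    call is 'ambiguous' rather than forced.
    """
    if median_flank <= 0:
        raise ZeroFlankDepthError("flank median depth is zero; no call possible")
    if ploidy < 1:
        raise ConfigError("ploidy must be >= 1")
    r = median_region / median_flank
    m_est = int(round(r * ploidy))
    m_est = min(max(m_est, 0), ploidy)
    if abs(r * ploidy - m_est) > guard * ploidy:
        label, m_out = "ambiguous", None
    elif m_est == 0:
        label, m_out = "null", 0
    elif m_est == ploidy:
        label, m_out = "homozygous", m_est
    elif ploidy == 2 and m_est == 1:
        label, m_out = "hemizygous", 1
    else:
        label, m_out = "partial", m_est
    return DosageCall(
        median_region=median_region,
        median_flank=median_flank,
        ratio=r,
        ploidy=ploidy,
        copy_number=m_out,
        label=label,
    )


def bootstrap_ratio_ci(
    region_units: Sequence[float],
    flank_units: Sequence[float],
    B: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile 95% CI of the dosage ratio by resampling summary units.

    Units are resampled with replacement independently on each side;
    deterministic for a fixed seed.  All-equal units give a zero-width CI.
    """
    region_units = np.asarray(region_units, dtype=np.float64)
    flank_units = np.asarray(flank_units, dtype=np.float64)
    if region_units.size < 2 or flank_units.size < 2:
        raise EmptyUnitSetError("need >= 2 units on each side for a bootstrap CI")
    rng = np.random.default_rng(seed)
    r_idx = rng.integers(0, region_units.size, size=(B, region_units.size))
    f_idx = rng.integers(0, flank_units.size, size=(B, flank_units.size))
    r_med = np.median(region_units[r_idx], axis=1)
    f_med = np.median(flank_units[f_idx], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = r_med / f_med
    ratios = ratios[np.isfinite(ratios)]
    if ratios.size == 0:
        raise ZeroFlankDepthError("all bootstrap flank medians were zero")
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    return float(lo), float(hi)


def call_region_dosage(
    summaries: Sequence[UnitSummary],
    region: GenomicInterval,
    flanks: Sequence[GenomicInterval],
    ploidy: int,
    guard: float = 0.15,
    bootstrap_B: int = 1000,
    seed: int = 0,
) -> DosageCall:
    """Medians + call + bootstrap CI in one step (the per-sample pipeline)."""
    region_vals, flank_vals = _partition_units(summaries, region, flanks)
    if not region_vals or not flank_vals:
        raise EmptyUnitSetError(
            f"no usable units (region n={len(region_vals)}, flank n={len(flank_vals)})"
        )
    med_r = float(np.median(region_vals))
    med_f = float(np.median(flank_vals))
    call = dosage_call(med_r, med_f, ploidy, guard)
    call.n_region = len(region_vals)
    call.n_flank = len(flank_vals)
    if len(region_vals) >= 2 and len(flank_vals) >= 2:
        call.ci = bootstrap_ratio_ci(region_vals, flank_vals, B=bootstrap_B, seed=seed)
    return call
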