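"""Regional enrichment statistics: repeat-fraction percentiles, intron and
intergenic length distributions, and Nx/NGx assembly contiguity metrics.

The question these statistics answer: is a focal region (a non-recombining
supergene) compositionally unusual relative to the rest of the genome —
more repetitive than comparably sized contigs, with longer introns and
larger intergenic gaps than the genome-wide background?
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import AnnotationSet, ContigSet, GenomicInterval
from .errors import ConfigError, DataError


# ---------------------------------------------------------------------------
# interval coverage
# ---------------------------------------------------------------------------


def merge_intervals(pairs: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open (start, end) pairs as a sorted disjoint list."""
    if not pairs:
        return []
    pairs = sorted(pairs)
    merged = [list(pairs[0])]
    for s, e in pairs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def merged_coverage_fraction(
    intervals: Sequence[GenomicInterval],
    target: GenomicInterval,
    mask: np.ndarray | None = None,
) -> float:
    """Fraction of a target interval covered by the union of intervals.

    Intervals are clipped to the target and merged, so overlapping or
    duplicated annotations are not double-counted.  By default ambiguous (N)
    positions count in the denominator; pass the contig's N mask to use an
    unmasked denominator instead.
    """
    if target.length == 0:
        raise DataError("zero-length target interval")
    clipped = [
        (max(iv.start, target.start), min(iv.end, target.end))
        for iv in intervals
        if iv.contig == target.contig and iv.start < target.end and iv.end > target.start
    ]
    merged = merge_intervals(clipped)
    if mask is None:
        covered = sum(e - s for s, e in merged)
        return covered / target.length
    sub = mask[target.start : target.end]
    denom = int((~sub).sum())
    if denom == 0:
        raise DataError("target interval is entirely masked")
    covered = 0
    for s, e in merged:
        covered += int((~mask[s:e]).sum())
    return covered / denom


def empirical_percentile(value: float, sample: Sequence[float]) -> float:
    """Percentile of a value in a sample, strictly-less convention.

    100 * #{s < value} / n, so 'top 5%' means percentile >= 95 and a value
    equal to every sample point sits at percentile 0.
    """
    sample = np.asarray(sample, dtype=np.float64)
    if sample.size == 0:
        raise DataError("empty sample")
    return 100.0 * float((sample < value).sum()) / sample.size


def contig_value_distribution(
    contigs: ContigSet,
    repeat_intervals: Sequence[GenomicInterval],
    min_len: int | None = None,
    size_window: tuple[int, float] | None = None,
) -> dict[str, float]:
    """Per-contig repeat fractions over a selected contig set.

    Selector: ``min_len`` keeps contigs strictly longer than the threshold;
    ``size_window=(target_len, tol)`` keeps contigs within
    [ (1-tol) * target_len, (1+tol) * target_len ].  Exactly one selector
    must be given.  Raises :class:`DataError` when no contig passes.
    """
    if (min_len is None) == (size_window is None):
        raise ConfigError("give exactly one of min_len or size_window")
    by_contig: dict[str, list[GenomicInterval]] = {}
    for iv in repeat_intervals:
        by_contig.setdefault(iv.contig, []).append(iv)
    out: dict[str, float] = {}
    for name in contigs:
        length = contigs.length(name)
        if min_len is not None and not length > min_len:
            continue
        if size_window is not None:
            target, tol = size_window
            if not ((1 - tol) * target <= length <= (1 + tol) * target):
                continue
        whole = GenomicInterval(name, 0, length)
        out[name] = merged_coverage_fraction(by_contig.get(name, []), whole)
    if not out:
        raise DataError("no contig passes the selector")
    return out


# ---------------------------------------------------------------------------
# intron / intergenic statistics
# ---------------------------------------------------------------------------


@dataclass
class IntronStats:
    lengths: np.ndarray
    median: float
    top_threshold: float  # (1 - q) upper quantile, default q = 0.05
    q: float
    n: int

    def to_dict(self) -> dict:
        return {
            "median_bp": self.median,
            "top_threshold_bp": self.top_threshold,
            "q": self.q,
            "n": self.n,
        }


def intron_lengths(
    annotation: AnnotationSet,
    subset: GenomicInterval | Sequence[str] | None = None,
    q: float = 0.05,
    dedupe_per_gene: bool = False,
) -> IntronStats:
    """Intron length distribution: median and the top-q threshold.

    An intron is the gap between consecutive exons of one transcript;
    single-exon transcripts contribute nothing.  ``subset`` restricts to
    transcripts whose span midpoint lies in an interval, or to an explicit
    transcript-id collection.  With ``dedupe_per_gene`` identical intron
    intervals shared by alternative spliceoforms of one gene are counted
    once.
    """
    tx_ids = None
    region = None
    if subset is not None:
        if isinstance(subset, GenomicInterval):
            region = subset
        else:
            tx_ids = set(subset)
    lengths = []
    seen: set[tuple[str, int, int]] = set()
    for tx in annotation:
        if tx_ids is not None and tx.transcript_id not in tx_ids:
            continue
        if region is not None and not (
            tx.contig == region.contig and region.contains(tx.span.midpoint)
        ):
            continue
        for iv in tx.introns():
            if dedupe_per_gene:
                key = (tx.gene_id, iv.start, iv.end)
                if key in seen:
                    continue
                seen.add(key)
            lengths.append(iv.length)
    if not lengths:
        raise DataError("no multi-exon transcript in the selection")
    arr = np.asarray(lengths, dtype=np.float64)
    return IntronStats(
        lengths=arr,
        median=float(np.median(arr)),
        top_threshold=float(np.quantile(arr, 1 - q)),
        q=q,
        n=arr.size,
    )


@dataclass
class IntergenicStats:
    distances: list[int]
    median: float
    n: int
    n_overlapping: int  # gene pairs that overlap (distance reported as 0)

    def to_dict(self) -> dict:
        return {
            "distances_bp": self.distances,
            "median_bp": self.median,
            "n": self.n,
            "n_overlapping_pairs": self.n_overlapping,
        }


def intergenic_distances(
    annotation: AnnotationSet, region: GenomicInterval
) -> IntergenicStats:
    """Distances between consecutive gene bodies inside a region.

    Gene bodies are outermost exon spans (union over transcripts); genes are
    selected by span midpoint, sorted by start.  With half-open intervals
    adjacent genes give distance 0; overlapping genes give 0 and are
    flagged.  Even counts use the midpoint median rule.
    """
    spans = [
        s
        for s in annotation.gene_spans(region.contig).values()
        if region.contains(s.midpoint)
    ]
    if len(spans) < 2:
        raise DataError(
            f"need >= 2 genes in region, found {len(spans)}"
        )
    spans.sort(key=lambda iv: iv.start)
    distances, n_overlap = [], 0
    for prev, nxt in zip(spans, spans[1:]):
        d = nxt.start - prev.end
        if d < 0:
            n_overlap += 1
            d = 0
        distances.append(int(d))
    return IntergenicStats(
        distances=distances,
        median=float(np.median(distances)),
        n=len(distances),
        n_overlapping=n_overlap,
    )


# ---------------------------------------------------------------------------
# assembly metrics
# ---------------------------------------------------------------------------


@dataclass
class AssemblyStats:
    n_contigs: int
    total_bases: int
    n50: int
    ng50: int | None  # None when the assembly never reaches G/2
    max_length: int
    n_count: int | None = None
    n_fraction: float | None = None

    def to_dict(self) -> dict:
        return {
            "n_contigs": self.n_contigs,
            "total_bases": self.total_bases,
            "n50": self.n50,
            "ng50": self.ng50,
            "max_length": self.max_length,
            "n_count": self.n_count,
            "n_fraction": self.n_fraction,
        }


def _nx(lengths_desc: np.ndarray, half: float) -> int | None:
    cum = np.cumsum(lengths_desc)
    idx = np.searchsorted(cum, half)
    if idx >= lengths_desc.size:
        return None
    return int(lengths_desc[idx])


def nx_statistics(
    contig_lengths: Sequence[int], genome_size_estimate: float | None = None
) -> AssemblyStats:
    """N50 and (optionally) NG50 of a set of contig lengths.

    N50 is the length of the contig at which the descending cumulative sum
    first reaches half the assembly total; NG50 replaces the assembly total
    with an independent genome-size estimate, making it robust to
    incompleteness of the assembly itself.  NG50 is None (flagged undefined)
    when the assembly never reaches G/2.
    """
    lengths = np.asarray(sorted(contig_lengths, reverse=True), dtype=np.int64)
    if lengths.size == 0:
        raise DataError("empty contig length list")
    if (lengths <= 0).any():
        raise DataError("contig lengths must be positive")
    total = int(lengths.sum())
    n50 = _nx(lengths, total / 2)
    ng50 = None
    if genome_size_estimate is not None:
        if genome_size_estimate <= 0:
            raise ConfigError("genome size estimate must be positive")
        ng50 = _nx(lengths, genome_size_estimate / 2)
    return AssemblyStats(
        n_contigs=int(lengths.size),
        total_bases=total,
        n50=int(n50),
        ng50=ng50,
        max_length=int(lengths[0]),
    )


def assembly_stats(
    contigs: ContigSet, genome_size_estimate: float | None = None
) -> AssemblyStats:
    """Full assembly metrics (incl. ambiguous-base content) for a ContigSet."""
    stats = nx_statistics(
        list(contigs.lengths().values()), genome_size_estimate
    )
    n_count = sum(contigs.n_count(name) for name in contigs)
    stats.n_count = n_count
    stats.n_fraction = n_count / stats.total_bases if stats.total_bases else 0.0
    return stats


def mean_genome_size(estimates: Sequence[float]) -> float:
    """Arithmetic mean of independent genome-size estimates."""
    if len(estimates) == 0:
        raise DataError("no genome size estimates")
    if any(e <= 0 for e in estimates):
        raise DataError("genome size estimates must be positive")
    return float(np.mean(estimates))


def assembly_fraction(assembly_total: float, genome_size: float) -> float:
    """Assembly span as a percentage of the estimated genome size.

    May exceed 100 (flagged by the caller); report with
    round(x, 1) or round(x) as needed.
    """
    if genome_size <= 0 or assembly_total <= 0:
        raise DataError("assembly total and genome size must be positive")
    return 100.0 * assembly_total / genome_size


# ---------------------------------------------------------------------------
# combined region report
# ---------------------------------------------------------------------------


def build_region_report(
    contigs: ContigSet,
    annotation: AnnotationSet | None,
    repeat_intervals: Sequence[GenomicInterval],
    region: GenomicInterval,
    flanks: Sequence[GenomicInterval] = (),
    min_len: int = 10_000,
    size_tol: float = 0.20,
    intron_q: float = 0.05,
    genome_size_estimate: float | None = None,
) -> dict:
    """Assemble the full enrichment report for one focal region.

    Covers: region vs genome-wide repeat fraction, the region's percentile
    against long contigs and size-matched contigs, intron length
    distributions (focal vs genome-wide), intergenic distances inside the
    region vs the flanks, and assembly Nx metrics.  Every statistic carries
    its sample size; sections that cannot be computed are reported as None
    with a reason.
    """
    report: dict = {"region": {
        "contig": region.contig, "start": region.start, "end": region.end,
        "length": region.length,
    }}

    region_frac = merged_coverage_fraction(
        [iv for iv in repeat_intervals if iv.contig == region.contig], region
    )
    genome_len = contigs.total_bases()
    merged_total = sum(
        e - s
        for name in contigs
        for s, e in merge_intervals(
            [
                (iv.start, iv.end)
                for iv in repeat_intervals
                if iv.contig == name
            ]
        )
    )
    genome_frac = merged_total / genome_len if genome_len else 0.0
    report["repeats"] = {
        "region_fraction": region_frac,
        "genome_fraction": genome_frac,
        "n_repeat_intervals": len(repeat_intervals),
    }
    for key, kwargs in (
        ("percentile_vs_min_len", {"min_len": min_len}),
        ("percentile_vs_size_matched", {"size_window": (region.length, size_tol)}),
    ):
        try:
            dist = contig_value_distribution(contigs, repeat_intervals, **kwargs)
            sample = [v for c, v in dist.items() if c != region.contig]
            if not sample:
                raise DataError("only the focal contig passes the selector")
            report["repeats"][key] = {
                "percentile": empirical_percentile(region_frac, sample),
                "n_contigs": len(sample),
            }
        except DataError as exc:
            report["repeats"][key] = {"percentile": None, "reason": str(exc)}

    if annotation is not None and len(annotation):
        try:
            genome_introns = intron_lengths(annotation, q=intron_q)
            report["introns_genome"] = genome_introns.to_dict()
        except DataError as exc:
            genome_introns = None
            report["introns_genome"] = {"median_bp": None, "reason": str(exc)}
        try:
            focal = intron_lengths(annotation, subset=region, q=intron_q)
            d = focal.to_dict()
            d["lengths_bp"] = [int(x) for x in focal.lengths]
            if genome_introns is not None:
                d["above_genome_top_threshold"] = int(
                    (focal.lengths > genome_introns.top_threshold).sum()
                )
            report["introns_region"] = d
        except DataError as exc:
            report["introns_region"] = {"median_bp": None, "reason": str(exc)}
        try:
            report["intergenic_region"] = intergenic_distances(
                annotation, region
            ).to_dict()
        except DataError as exc:
            report["intergenic_region"] = {"median_bp": None, "reason": str(exc)}
        flank_meds = []
        for f in flanks:
            try:
                flank_meds += intergenic_distances(annotation, f).distances
            except DataError:
                continue
        report["intergenic_flanks"] = (
            {"median_bp": float(np.median(flank_meds)), "n": len(flank_meds)}
            if flank_meds
            else {"median_bp": None, "reason": "fewer than 2 genes per flank"}
        )
    else:
        report["introns_genome"] = {"median_bp": None, "reason": "no annotation"}

    report["assembly"] = assembly_stats(contigs, genome_size_estimate).to_dict()
    return report
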