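"""Synthetic diploid/polyploid genomes, annotations and shotgun reads with
known ground truth.

The generator emulates the data structure that the dosage, k-mer and
region-enrichment analyses assume:

* a reference contig that carries a contiguous focal region (the supergene),
  with the region present on 0..m of the p sample haplotypes — hemizygosity
  is the m=1, p=2 case; non-carrier haplotypes have the region cleanly
  deleted;
* background SNP heterozygosity at rate theta between haplotypes;
* a repeat family planted to a target merged coverage inside the region
  (repeat-rich) versus the background (repeat-poorer);
* gene models whose intron lengths follow log-normal laws with a long right
  tail inside the region;
* uniform-coverage single-end shotgun reads with i.i.d. base errors, plus a
  truth SAM placing every read at its origin.

All randomness flows from a single integer seed through named
``numpy.random.Generator`` instances; identical seeds give byte-identical
output files.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .core import (
    AnnotationSet,
    ContigSet,
    GenomicInterval,
    TranscriptModel,
    decode_seq,
)
from .errors import (
    CompartmentTooSmallError,
    SimulationParameterError,
    UnreachableFractionError,
)

REF_CONTIG = "contig_sl"  # reference contig name used by the simulator


@dataclass
class SimulationSpec:
    """Generative parameters for one single-contig simulation.

    Defaults describe a diploid with a 30 kb focal region carried on one of
    two haplotypes (a hemizygote), 1% SNP heterozygosity, and 15x
    per-haplotype coverage of 100 bp reads at 1% base error.
    """

    genome_length: int = 500_000
    ploidy: int = 2
    region_length: int = 30_000
    region_start: int | None = None  # None = centered
    copy_number: int = 1  # haplotypes carrying the region (m)
    snp_rate: float = 0.01  # theta, substitutions/base between haplotypes
    repeat_fraction_in: float = 0.64
    repeat_fraction_out: float = 0.37
    repeat_unit_length: int = 500
    repeat_divergence: float = 0.05
    depth_per_haplotype: float = 15.0
    read_length: int = 100
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ploidy < 1:
            raise SimulationParameterError("ploidy must be >= 1")
        if not (0 <= self.copy_number <= self.ploidy):
            raise SimulationParameterError(
                f"copy number m={self.copy_number} outside 0..p={self.ploidy}"
            )
        if self.region_length >= self.genome_length:
            raise SimulationParameterError("region length must be < genome length")
        for name in ("snp_rate", "error_rate", "repeat_divergence"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) or not np.isfinite(v):
                raise SimulationParameterError(f"{name} must be in [0, 1]")
        if not (
            0.0 <= self.repeat_fraction_out <= self.repeat_fraction_in <= 1.0
        ):
            raise SimulationParameterError("need 0 <= f_out <= f_in <= 1")
        if self.read_length <= 0:
            raise SimulationParameterError("read length must be positive")
        if not np.isfinite(self.depth_per_haplotype) or self.depth_per_haplotype <= 0:
            raise SimulationParameterError("depth must be positive and finite")

    @property
    def region(self) -> GenomicInterval:
        start = (
            (self.genome_length - self.region_length) // 2
            if self.region_start is None
            else self.region_start
        )
        return GenomicInterval(REF_CONTIG, start, start + self.region_length)


@dataclass
class Haplotype:
    codes: np.ndarray  # uint8 base codes
    carrier: bool
    sub_positions: np.ndarray  # reference coordinates of substitutions
    sub_alts: np.ndarray  # substituted base codes


@dataclass
class HaplotypeTruth:
    """Ground truth of one simulation: haplotypes, region, repeats, SNPs."""

    spec: SimulationSpec
    ref_codes: np.ndarray
    region: GenomicInterval
    haplotypes: list[Haplotype]
    repeat_intervals: list[GenomicInterval] = field(default_factory=list)

    @property
    def contig(self) -> str:
        return REF_CONTIG

    def reference_contigset(self) -> ContigSet:
        return ContigSet.from_records([(REF_CONTIG, decode_seq(self.ref_codes))])

    def haplotype_contigset(self) -> ContigSet:
        return ContigSet.from_records(
            (f"hap{i}", decode_seq(h.codes)) for i, h in enumerate(self.haplotypes)
        )

    def het_positions(self) -> np.ndarray:
        """Reference positions polymorphic among the sample haplotypes."""
        pools = [
            h.sub_positions
            for h in self.haplotypes
            if h.sub_positions.size
        ]
        if not pools:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(pools))

    def flanks(self) -> list[GenomicInterval]:
        """Everything on the reference outside the region, split left/right."""
        out = []
        if self.region.start > 0:
            out.append(GenomicInterval(REF_CONTIG, 0, self.region.start))
        if self.region.end < self.ref_codes.size:
            out.append(
                GenomicInterval(REF_CONTIG, self.region.end, self.ref_codes.size)
            )
        return out

    def hap_repeat_intervals(self, i: int) -> list[tuple[int, int]]:
        """Planted repeat intervals in haplotype-local coordinates."""
        hap = self.haplotypes[i]
        out = []
        r = self.region
        for iv in self.repeat_intervals:
            if hap.carrier:
                out.append((iv.start, iv.end))
            elif iv.end <= r.start:
                out.append((iv.start, iv.end))
            elif iv.start >= r.end:
                out.append((iv.start - r.length, iv.end - r.length))
            # repeats inside the region do not exist on non-carriers
        return sorted(out)

    def summary(self) -> dict:
        return {
            "contig": self.contig,
            "genome_length": int(self.ref_codes.size),
            "ploidy": self.spec.ploidy,
            "copy_number": self.spec.copy_number,
            "region": [self.region.start, self.region.end],
            "snp_rate": self.spec.snp_rate,
            "n_het_positions": int(self.het_positions().size),
            "n_repeat_copies": len(self.repeat_intervals),
            "seed": self.spec.seed,
        }


def _mutate(
    codes: np.ndarray, rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bernoulli(rate) substitutions; returns (mutated, positions, alts)."""
    out = codes.copy()
    if rate <= 0:
        return out, np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint8)
    hits = np.nonzero(rng.random(codes.size) < rate)[0]
    shifts = rng.integers(1, 4, size=hits.size, dtype=np.uint8)
    alts = ((codes[hits] + shifts) % 4).astype(np.uint8)
    out[hits] = alts
    return out, hits.astype(np.int64), alts


def simulate_haplotypes(spec: SimulationSpec) -> tuple[ContigSet, HaplotypeTruth]:
    """Generate a reference plus p sample haplotypes.

    The reference is a haplotype that carries the focal region (so region
    coordinates exist on the reference even when no sample haplotype does).
    When m >= 1 the first haplotype is the reference itself; every other
    haplotype is a copy with Bernoulli(theta) substitutions, and non-carrier
    haplotypes have the region deleted.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    ref = rng.integers(0, 4, size=spec.genome_length, dtype=np.uint8)
    region = spec.region
    haps: list[Haplotype] = []
    for i in range(spec.ploidy):
        carrier = i < spec.copy_number
        if i == 0 and carrier:
            codes, pos, alts = (
                ref.copy(),
                np.empty(0, dtype=np.int64),
                np.empty(0, dtype=np.uint8),
            )
        else:
            codes, pos, alts = _mutate(ref, spec.snp_rate, rng)
        if not carrier:
            codes = np.concatenate([codes[: region.start], codes[region.end :]])
            keep = (pos < region.start) | (pos >= region.end)
            pos, alts = pos[keep], alts[keep]
        haps.append(
            Haplotype(codes=codes, carrier=carrier, sub_positions=pos, sub_alts=alts)
        )
    truth = HaplotypeTruth(
        spec=spec, ref_codes=ref, region=region, haplotypes=haps
    )
    return truth.reference_contigset(), truth


# ---------------------------------------------------------------------------
# repeats
# ---------------------------------------------------------------------------


def _plant_in_compartment(
    ref: np.ndarray,
    start: int,
    end: int,
    fraction: float,
    unit: np.ndarray,
    divergence: float,
    rng: np.random.Generator,
    tol: float = 0.02,
) -> list[tuple[int, int]]:
    """Tile non-overlapping mutated unit copies to a target merged coverage."""
    comp_len = end - start
    unit_len = unit.size
    n_slots = comp_len // unit_len
    n_copies = int(round(fraction * comp_len / unit_len))
    if n_copies > n_slots:
        raise UnreachableFractionError(
            f"fraction {fraction} unreachable in compartment of {comp_len} bp "
            f"with unit length {unit_len}"
        )
    achieved = n_copies * unit_len / comp_len
    if abs(achieved - fraction) > tol:
        raise UnreachableFractionError(
            f"unit length {unit_len} too coarse: achievable {achieved:.3f} "
            f"vs target {fraction:.3f}"
        )
    slots = np.sort(rng.choice(n_slots, size=n_copies, replace=False))
    out = []
    for s in slots:
        lo = start + int(s) * unit_len
        copy, _, _ = _mutate(unit, divergence, rng)
        ref[lo : lo + unit_len] = copy
        out.append((lo, lo + unit_len))
    return out


def _rebuild_haplotypes(truth: HaplotypeTruth) -> None:
    """Re-derive haplotypes from the (modified) reference and recorded SNPs."""
    region = truth.region
    for hap in truth.haplotypes:
        codes = truth.ref_codes.copy()
        codes[hap.sub_positions] = hap.sub_alts
        if not hap.carrier:
            codes = np.concatenate([codes[: region.start], codes[region.end :]])
        hap.codes = codes


def plant_repeat_family(
    truth: HaplotypeTruth,
    region: GenomicInterval | None = None,
    f_in: float | None = None,
    f_out: float | None = None,
    unit_len: int | None = None,
    divergence: float | None = None,
    seed: int | None = None,
) -> list[GenomicInterval]:
    """Plant a repeat family at target coverage f_in inside the region and
    f_out outside, mutating each copy at the divergence rate.

    Copies are placed on non-overlapping unit-length slots, so the merged
    coverage matches the target to within one slot (+-0.02 enforced).
    Haplotypes are rebuilt so carriers share the region's repeat copies and
    non-carriers only the background ones.  Returns the planted intervals in
    reference coordinates (also recorded on the truth object).
    """
    spec = truth.spec
    region = region or truth.region
    f_in = spec.repeat_fraction_in if f_in is None else f_in
    f_out = spec.repeat_fraction_out if f_out is None else f_out
    unit_len = spec.repeat_unit_length if unit_len is None else unit_len
    divergence = spec.repeat_divergence if divergence is None else divergence
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))

    unit = rng.integers(0, 4, size=unit_len, dtype=np.uint8)
    planted: list[tuple[int, int]] = []
    if f_in > 0:
        planted += _plant_in_compartment(
            truth.ref_codes, region.start, region.end, f_in, unit, divergence, rng
        )
    if f_out > 0:
        for lo, hi in ((0, region.start), (region.end, truth.ref_codes.size)):
            if hi > lo:
                planted += _plant_in_compartment(
                    truth.ref_codes, lo, hi, f_out, unit, divergence, rng
                )
    truth.repeat_intervals = [
        GenomicInterval(truth.contig, s, e) for s, e in sorted(planted)
    ]
    _rebuild_haplotypes(truth)
    return truth.repeat_intervals


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


@dataclass
class LogNormalLaw:
    """Log-normal length law parameterized by its median.

    Draws median * exp(sigma * Z) rounded to integers, floored at
    ``min_len`` and capped at ``cap`` (a truncation far in the upper tail
    that bounds worst-case gene footprints without moving the median).
    """

    median: float
    sigma: float = 0.8
    min_len: int = 60
    cap: int | None = None

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        vals = self.median * np.exp(self.sigma * rng.standard_normal(n))
        vals = np.maximum(np.round(vals).astype(np.int64), self.min_len)
        if self.cap is not None:
            vals = np.minimum(vals, self.cap)
        return vals


def lay_gene_compartment(
    contig: str,
    start: int,
    end: int,
    n_genes: int,
    intron_law: LogNormalLaw,
    gap_law: LogNormalLaw,
    rng: np.random.Generator,
    n_exons_range: tuple[int, int] = (4, 6),
    exon_len_range: tuple[int, int] = (150, 400),
    id_prefix: str = "g",
) -> list[TranscriptModel]:
    """Lay non-overlapping gene models left-to-right inside [start, end).

    Exon count and lengths are uniform draws; intron lengths follow the
    given law; genes are separated by gap-law intergenic distances.  Raises
    :class:`CompartmentTooSmallError` if the requested genes do not fit.
    """
    transcripts = []
    pos = start
    for g in range(n_genes):
        gap = int(gap_law.draw(rng, 1)[0])
        pos += gap
        n_exons = int(rng.integers(n_exons_range[0], n_exons_range[1] + 1))
        exon_lens = rng.integers(
            exon_len_range[0], exon_len_range[1] + 1, size=n_exons
        )
        intron_lens = intron_law.draw(rng, n_exons - 1) if n_exons > 1 else []
        exons = []
        cursor = pos
        for i, el in enumerate(exon_lens):
            exons.append(GenomicInterval(contig, cursor, cursor + int(el)))
            cursor += int(el)
            if i < n_exons - 1:
                cursor += int(intron_lens[i])
        if cursor > end:
            raise CompartmentTooSmallError(
                f"gene {g + 1}/{n_genes} ends at {cursor} past compartment end {end}"
            )
        gid = f"{id_prefix}{g + 1:04d}"
        transcripts.append(
            TranscriptModel(
                gene_id=gid,
                transcript_id=f"{gid}.1",
                contig=contig,
                strand="+",
                exons=exons,
                cds=list(exons),  # UTR-less models: CDS == exons
            )
        )
        pos = cursor
    return transcripts


# worst-case footprint of one background gene under the default laws:
# 5 introns at cap 3000 + 6 exons at 400 + leading gap at cap 4000
_BG_GENE_FOOTPRINT = 5 * 3000 + 6 * 400 + 4000


def _region_laws(budget: int) -> tuple[LogNormalLaw, LogNormalLaw]:
    """Intron and gap laws whose caps make one focal gene (3 introns,
    4 exons of <= 400 bp, one leading gap) provably fit a per-gene budget."""
    cap = max((budget - 4 * 400) // 4, 80)
    return (
        LogNormalLaw(median=max(cap / 2.5, 70), sigma=0.6, cap=cap),
        LogNormalLaw(median=max(cap / 2.0, 70), sigma=0.4, cap=cap),
    )


def make_gene_models(
    truth: HaplotypeTruth,
    region: GenomicInterval | None = None,
    n_genes_in: int | None = None,
    n_genes_out: int | None = None,
    intron_law_in: LogNormalLaw | None = None,
    intron_law_out: LogNormalLaw | None = None,
    seed: int | None = None,
    gap_law_in: LogNormalLaw | None = None,
    gap_law_out: LogNormalLaw | None = None,
) -> AnnotationSet:
    """Gene models for a simulated genome: longer-intron genes inside the
    focal region, short-intron genes on the flanks.

    Defaults: genome-wide introns log-normal with median 440 bp; focal
    intron/gap laws derived from the region size (a per-gene budget caps
    the worst-case footprint, so the default layout fits any region and
    seed).  ``n_genes_in``/``n_genes_out`` default to as many genes as the
    compartments provably hold, up to 3 focal and 20 background genes.
    """
    region = region or truth.region
    seed = truth.spec.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    if n_genes_in is None:
        n_genes_in = min(3, max(1, region.length // 8000))
    intron_law_out = intron_law_out or LogNormalLaw(median=440, sigma=0.8, cap=3000)
    gap_law_out = gap_law_out or LogNormalLaw(median=1800, sigma=0.5, cap=4000)
    if intron_law_in is None or gap_law_in is None:
        in_law, in_gap = _region_laws(region.length // max(n_genes_in, 1))
        intron_law_in = intron_law_in or in_law
        gap_law_in = gap_law_in or in_gap

    ann = AnnotationSet()
    if n_genes_in:
        ann.transcripts += lay_gene_compartment(
            truth.contig,
            region.start,
            region.end,
            n_genes_in,
            intron_law_in,
            gap_law_in,
            rng,
            n_exons_range=(3, 4),
            id_prefix="gin",
        )
    flanks = truth.flanks()
    if flanks:
        capacity = [f.length // _BG_GENE_FOOTPRINT for f in flanks]
        if n_genes_out is None:
            counts = capacity
            if sum(counts) > 20:
                scale = 20 / sum(counts)
                counts = [int(c * scale) for c in counts]
        else:
            shares = [f.length for f in flanks]
            total = sum(shares)
            counts = [round(n_genes_out * s / total) for s in shares]
            counts[-1] = n_genes_out - sum(counts[:-1])
        for f, n in zip(flanks, counts):
            if n > 0:
                ann.transcripts += lay_gene_compartment(
                    truth.contig,
                    f.start,
                    f.end,
                    n,
                    intron_law_out,
                    gap_law_out,
                    rng,
                    id_prefix=f"gout{f.start}_",
                )
    return ann


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


@dataclass
class ReadSet:
    """Simulated single-end reads with their truth placements.

    Truth alignments are stored as one or two match segments in reference
    coordinates: reads from a non-carrier haplotype that span the deletion
    junction get a split (aM rN bM) truth record, where r is the region
    length — D/N-style gaps contribute no depth downstream.
    """

    contig: str
    contig_length: int
    read_length: int
    hap_index: np.ndarray  # int32 haplotype of origin
    hap_start: np.ndarray  # int64 start in haplotype coordinates
    seqs: np.ndarray  # (n_reads, read_length) uint8 base codes
    ref_pos: np.ndarray  # int64 truth leftmost reference position
    m1: np.ndarray  # int64 first match length
    skip: np.ndarray  # int64 reference skip (0 = contiguous read)
    mapq: np.ndarray  # int32

    @property
    def n_reads(self) -> int:
        return self.hap_index.size

    @property
    def total_bases(self) -> int:
        return self.n_reads * self.read_length

    def read_ids(self) -> list[str]:
        return [
            f"r{h}_{i}" for i, h in enumerate(self.hap_index)
        ]

    def sequences(self) -> list[str]:
        return [decode_seq(row) for row in self.seqs]

    def depth_segments(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, ends, mapq) arrays over all match segments."""
        m2 = self.read_length - self.m1
        starts = [self.ref_pos]
        ends = [self.ref_pos + self.m1]
        mapqs = [self.mapq]
        split = self.skip > 0
        if split.any():
            s2 = self.ref_pos[split] + self.m1[split] + self.skip[split]
            starts.append(s2)
            ends.append(s2 + m2[split])
            mapqs.append(self.mapq[split])
        return (
            np.concatenate(starts),
            np.concatenate(ends),
            np.concatenate(mapqs),
        )

    def write_fastq(self, path: str | Path) -> None:
        qual = "I" * self.read_length
        with open(path, "w") as fh:
            for i, h in enumerate(self.hap_index):
                fh.write(
                    f"@r{h}_{i}\n{decode_seq(self.seqs[i])}\n+\n{qual}\n"
                )

    def write_sam(self, path: str | Path) -> None:
        header = {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": self.contig, "LN": int(self.contig_length)}],
        }
        qual = "I" * self.read_length
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for i, h in enumerate(self.hap_index):
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = f"r{h}_{i}"
                rec.flag = 0
                rec.reference_name = self.contig
                rec.reference_start = int(self.ref_pos[i])
                rec.mapping_quality = int(self.mapq[i])
                a, gap = int(self.m1[i]), int(self.skip[i])
                if gap:
                    b = self.read_length - a
                    rec.cigartuples = [(0, a), (3, gap), (0, b)]
                else:
                    rec.cigartuples = [(0, self.read_length)]
                rec.query_sequence = decode_seq(self.seqs[i])
                rec.query_qualities = pysam.qualitystring_to_array(qual)
                out.write(rec)


def simulate_reads(truth: HaplotypeTruth, spec: SimulationSpec | None = None) -> ReadSet:
    """Uniform-coverage single-end reads from every haplotype.

    Read starts are uniform per haplotype, base errors i.i.d.
    Bernoulli(error_rate).  Truth placement is MAPQ 60, except reads lying
    wholly inside a planted repeat copy when the family has >= 2 copies at
    divergence < 2 x error_rate, which get MAPQ 0 (a deliberate, simple
    stand-in for aligner ambiguity in near-identical repeats).
    """
    spec = spec or truth.spec
    ell = spec.read_length
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 4]))
    region = truth.region
    ambiguous_repeats = (
        len(truth.repeat_intervals) >= 2
        and truth.spec.repeat_divergence < 2 * spec.error_rate
    )

    all_hap, all_start, all_seq = [], [], []
    all_pos, all_m1, all_skip, all_mapq = [], [], [], []
    for i, hap in enumerate(truth.haplotypes):
        hap_len = hap.codes.size
        if ell >= hap_len:
            raise SimulationParameterError("read length must be < haplotype length")
        n = int(round(spec.depth_per_haplotype * hap_len / ell))
        starts = np.sort(rng.integers(0, hap_len - ell + 1, size=n))
        # sequences with errors, chunked to bound the error-mask allocation
        seqs = hap.codes[starts[:, None] + np.arange(ell)]
        for lo in range(0, n, 65536):
            block = seqs[lo : lo + 65536]
            if spec.error_rate > 0:
                mask = rng.random(block.shape) < spec.error_rate
                shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
                block[mask] = (block[mask] + shift) % 4
        # truth placement in reference coordinates
        if hap.carrier:
            pos, m1, skip = starts, np.full(n, ell), np.zeros(n, dtype=np.int64)
        else:
            pos = starts.copy()
            m1 = np.full(n, ell)
            skip = np.zeros(n, dtype=np.int64)
            after = starts >= region.start
            pos[after] = starts[after] + region.length
            spans = (starts < region.start) & (starts + ell > region.start)
            m1[spans] = region.start - starts[spans]
            skip[spans] = region.length
            pos[spans] = starts[spans]
        mapq = np.full(n, 60, dtype=np.int32)
        if ambiguous_repeats:
            reps = truth.hap_repeat_intervals(i)
            if reps:
                rs = np.array([r[0] for r in reps])
                re_ = np.array([r[1] for r in reps])
                idx = np.searchsorted(rs, starts, side="right") - 1
                inside = (idx >= 0) & (starts + ell <= re_[np.clip(idx, 0, None)])
                mapq[inside] = 0
        all_hap.append(np.full(n, i, dtype=np.int32))
        all_start.append(starts)
        all_seq.append(seqs)
        all_pos.append(pos.astype(np.int64))
        all_m1.append(m1.astype(np.int64))
        all_skip.append(skip)
        all_mapq.append(mapq)

    return ReadSet(
        contig=truth.contig,
        contig_length=truth.ref_codes.size,
        read_length=ell,
        hap_index=np.concatenate(all_hap),
        hap_start=np.concatenate(all_start),
        seqs=np.concatenate(all_seq),
        ref_pos=np.concatenate(all_pos),
        m1=np.concatenate(all_m1),
        skip=np.concatenate(all_skip),
        mapq=np.concatenate(all_mapq),
    )


# ---------------------------------------------------------------------------
# multi-contig scene for region-enrichment analyses
# ---------------------------------------------------------------------------


@dataclass
class SceneSpec:
    """A multi-contig genome with one repeat- and long-intron-enriched
    focal region, for the region-report analyses.

    Background contigs are sized within the +-20% window around the focal
    region length so both contig selectors (minimum length, size-matched)
    have a comparison sample.
    """

    seed: int = 0
    focal_contig_length: int = 400_000
    region_length: int = 150_000
    n_background_contigs: int = 30
    background_length_jitter: float = 0.10
    f_in: float = 0.64
    f_out: float = 0.37
    repeat_unit_length: int = 500
    repeat_divergence: float = 0.05
    n_genes_in: int = 3
    n_genes_per_background: int = 3
    intron_law_in: LogNormalLaw = field(
        default_factory=lambda: LogNormalLaw(median=5000, sigma=0.6, cap=9000)
    )
    intron_law_out: LogNormalLaw = field(
        default_factory=lambda: LogNormalLaw(median=440, sigma=0.8, cap=3000)
    )


@dataclass
class Scene:
    contigs: ContigSet
    focal_contig: str
    region: GenomicInterval
    flanks: list[GenomicInterval]
    repeat_intervals: list[GenomicInterval]
    annotation: AnnotationSet


def build_scene(spec: SceneSpec) -> Scene:
    """Generate the full multi-contig scene (sequences, repeats, genes)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 5]))
    focal = "contig_focal"
    region_start = (spec.focal_contig_length - spec.region_length) // 2
    region = GenomicInterval(focal, region_start, region_start + spec.region_length)

    seqs: dict[str, np.ndarray] = {
        focal: rng.integers(0, 4, size=spec.focal_contig_length, dtype=np.uint8)
    }
    for b in range(spec.n_background_contigs):
        jit = 1.0 + rng.uniform(
            -spec.background_length_jitter, spec.background_length_jitter
        )
        seqs[f"contig_b{b + 1:02d}"] = rng.integers(
            0, 4, size=int(spec.region_length * jit), dtype=np.uint8
        )

    unit = rng.integers(0, 4, size=spec.repeat_unit_length, dtype=np.uint8)
    repeats: list[GenomicInterval] = []
    for name, codes in seqs.items():
        if name == focal:
            planted = _plant_in_compartment(
                codes, region.start, region.end, spec.f_in, unit,
                spec.repeat_divergence, rng,
            )
            for lo, hi in ((0, region.start), (region.end, codes.size)):
                planted += _plant_in_compartment(
                    codes, lo, hi, spec.f_out, unit, spec.repeat_divergence, rng
                )
        else:
            planted = _plant_in_compartment(
                codes, 0, codes.size, spec.f_out, unit, spec.repeat_divergence, rng
            )
        repeats += [GenomicInterval(name, s, e) for s, e in sorted(planted)]

    ann = AnnotationSet()
    gap_in = LogNormalLaw(median=10000, sigma=0.3, cap=12000)
    gap_out = LogNormalLaw(median=1800, sigma=0.5, cap=6000)
    ann.transcripts += lay_gene_compartment(
        focal, region.start, region.end, spec.n_genes_in,
        spec.intron_law_in, gap_in, rng, n_exons_range=(3, 4), id_prefix="gin",
    )
    for name, codes in seqs.items():
        if name == focal:
            continue
        ann.transcripts += lay_gene_compartment(
            name, 0, codes.size, spec.n_genes_per_background,
            spec.intron_law_out, gap_out, rng, id_prefix=f"{name}_g",
        )

    contigs = ContigSet.from_records(
        (name, decode_seq(codes)) for name, codes in seqs.items()
    )
    flanks = [
        GenomicInterval(focal, 0, region.start),
        GenomicInterval(focal, region.end, spec.focal_contig_length),
    ]
    return Scene(
        contigs=contigs,
        focal_contig=focal,
        region=region,
        flanks=flanks,
        repeat_intervals=repeats,
        annotation=ann,
    )


def write_truth_json(truth: HaplotypeTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.summary(), fh, indent=2, sort_keys=True)
        fh.write("\n")
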