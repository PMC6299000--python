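"""Desk-scale parameter-recovery benchmarks.

Each benchmark simulates data with known ground truth under the package's
study conditions and measures how often the corresponding analysis recovers
the truth:

* dosage: diploid genomes with the focal region on m of 2 haplotypes —
  does the windowed region/flank depth ratio recover m and lie near m/2?
* zygosity: homozygous vs heterozygous libraries — does the k-mer spectrum
  classification recover the generating SNP rate, with the heterozygous
  minor peak at the expected half multiplicity?
* repeat enrichment: a planted repeat-rich focal region — are the planted
  coverage fractions and the region's top-5% percentile recovered?

All sub-seeds are derived from one base seed via ``numpy`` seed sequences,
so a single integer reproduces every replicate.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import depth as depth_mod
from .kmers import count_kmers, zygosity_from_spectrum
from .regions import build_region_report
from .simulate import (
    SceneSpec,
    SimulationSpec,
    build_scene,
    simulate_haplotypes,
    simulate_reads,
)

_EXPECTED_LABEL = {0: "null", 1: "hemizygous", 2: "homozygous"}


def _sub_seeds(base_seed: int, n: int, stream: int) -> np.ndarray:
    ss = np.random.SeedSequence([int(base_seed), stream])
    return (ss.generate_state(n, dtype=np.uint32) % np.uint32(2**31 - 1)).astype(int)


@dataclass
class DosageRecovery:
    n_replicates: int  # per copy-number value
    labels_correct: int
    ratios_within: int  # |ratio - m/2| <= 0.1
    total: int

    @property
    def label_accuracy(self) -> float:
        return self.labels_correct / self.total

    @property
    def ratio_accuracy(self) -> float:
        return self.ratios_within / self.total


def dosage_recovery(
    base_seed: int = 0,
    n_replicates: int = 50,
    copy_numbers: tuple[int, ...] = (0, 1, 2),
    genome_length: int = 500_000,
    region_length: int = 30_000,
    depth_per_haplotype: float = 15.0,
    error_rate: float = 0.01,
    window: int = 5_000,
    ratio_tol: float = 0.1,
) -> DosageRecovery:
    """Windowed dosage recovery over seeded replicates of m in {0, 1, 2}."""
    correct = within = total = 0
    for m in copy_numbers:
        seeds = _sub_seeds(base_seed, n_replicates, stream=100 + m)
        for s in seeds:
            spec = SimulationSpec(
                genome_length=genome_length,
                region_length=region_length,
                ploidy=2,
                copy_number=m,
                depth_per_haplotype=depth_per_haplotype,
                error_rate=error_rate,
                seed=int(s),
            )
            _, truth = simulate_haplotypes(spec)
            reads = simulate_reads(truth)
            starts, ends, mapq = reads.depth_segments()
            prof = depth_mod.depth_from_segments(
                truth.contig, spec.genome_length, starts, ends, mapq
            )
            prof = depth_mod.normalize(prof, reads.total_bases)
            units = depth_mod.window_means(prof, window=window)
            med_r, med_f = depth_mod.region_flank_medians(
                units, truth.region, truth.flanks()
            )
            call = depth_mod.dosage_call(med_r, med_f, ploidy=2)
            total += 1
            if call.label == _EXPECTED_LABEL[m]:
                correct += 1
            if abs(call.ratio - m / 2) <= ratio_tol:
                within += 1
    return DosageRecovery(
        n_replicates=n_replicates,
        labels_correct=correct,
        ratios_within=within,
        total=total,
    )


@dataclass
class ZygosityRecovery:
    n_replicates: int  # per SNP-rate value
    labels_correct: int
    total: int
    minor_major_ratios: list[float]  # het replicates: minor/major multiplicity

    @property
    def label_accuracy(self) -> float:
        return self.labels_correct / self.total


def zygosity_recovery(
    base_seed: int = 0,
    n_replicates: int = 20,
    snp_rates: tuple[float, ...] = (0.0, 0.01),
    genome_length: int = 200_000,
    depth_per_haplotype: float = 30.0,
    k: int = 15,
) -> ZygosityRecovery:
    """K-mer zygosity recovery for homozygous vs heterozygous libraries."""
    correct = total = 0
    ratios: list[float] = []
    for theta in snp_rates:
        expected = "homozygous" if theta == 0 else "heterozygous"
        seeds = _sub_seeds(base_seed, n_replicates, stream=200 + int(theta * 1000))
        for s in seeds:
            spec = SimulationSpec(
                genome_length=genome_length,
                region_length=genome_length // 5,
                ploidy=2,
                copy_number=2,
                snp_rate=theta,
                depth_per_haplotype=depth_per_haplotype,
                seed=int(s),
            )
            _, truth = simulate_haplotypes(spec)
            reads = simulate_reads(truth)
            call = zygosity_from_spectrum(count_kmers(reads.seqs, k))
            total += 1
            if call.label == expected:
                correct += 1
            if call.label == "heterozygous" and len(call.peaks) >= 2:
                by_height = sorted(call.peaks, key=lambda p: p[1])
                ratios.append(by_height[-2][0] / by_height[-1][0])
    return ZygosityRecovery(
        n_replicates=n_replicates,
        labels_correct=correct,
        total=total,
        minor_major_ratios=ratios,
    )


def repeat_enrichment_recovery(base_seed: int = 0) -> dict:
    """Region report of a planted f_in=0.64 / f_out=0.37 scene."""
    scene = build_scene(SceneSpec(seed=int(base_seed)))
    report = build_region_report(
        scene.contigs,
        scene.annotation,
        scene.repeat_intervals,
        scene.region,
        flanks=scene.flanks,
    )
    return report
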