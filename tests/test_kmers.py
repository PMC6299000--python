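"""K-mer spectrum construction, shape analysis and completeness checks."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from supergene import (
    KmerSpectrum,
    SimulationSpec,
    assembly_copy_spectrum,
    classify_zygosity,
    count_kmer_table,
    count_kmers,
    estimate_genome_size,
    find_peaks,
    first_local_minimum,
    simulate_haplotypes,
    simulate_reads,
    zygosity_from_spectrum,
)
from supergene.core import ContigSet
from supergene.errors import KmerParameterError

RC = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s[::-1].translate(RC)


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "seq,k,expected",
    [
        ("ACGT", 3, {2: 1}),  # CGT canonicalizes onto ACG
        ("AAAAA", 3, {3: 1}),
        ("ANA", 3, {}),  # N-containing windows skipped
    ],
)
def test_count_kmers_small_examples(seq, k, expected):
    assert count_kmers([seq], k).hist == expected


@pytest.mark.parametrize("k", [0, -3, 4])
def test_invalid_k_rejected(k):
    with pytest.raises(KmerParameterError):
        count_kmers(["ACGTACGT"], k)


@given(st.lists(st.text(alphabet="ACGT", min_size=7, max_size=40), min_size=1, max_size=8))
def test_reverse_complement_invariance(reads):
    """Canonicalization makes the spectrum strand-symmetric."""
    fwd = count_kmers(reads, 7)
    rev = count_kmers([revcomp(r) for r in reads], 7)
    assert fwd.hist == rev.hist


@given(st.lists(st.text(alphabet="ACGT", min_size=1, max_size=60), min_size=1, max_size=8))
def test_instance_conservation(reads):
    """Sum of multiplicity x count equals the number of countable windows."""
    k = 5
    sp = count_kmers(reads, k)
    expected = sum(max(0, len(r) - k + 1) for r in reads)
    assert sp.total_kmer_instances == expected


def test_matrix_and_string_paths_agree(rng):
    from supergene.core import encode_seq

    reads = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(40)]
    mat = np.vstack([encode_seq(r) for r in reads])
    assert count_kmers(mat, 9).hist == count_kmers(reads, 9).hist


# ---------------------------------------------------------------------------
# spectrum shape
# ---------------------------------------------------------------------------


def _spectrum(hist: dict[int, int]) -> KmerSpectrum:
    return KmerSpectrum(k=15, hist=hist)


def test_first_local_minimum_exhaustive_scan():
    sp = _spectrum({1: 100, 2: 40, 3: 8, 4: 12, 5: 30, 6: 20})
    # exhaustive scan: 3 is the first x with h[x] <= both neighbours
    assert first_local_minimum(sp) == 3


def test_first_local_minimum_tie_resolves_left():
    sp = _spectrum({1: 50, 2: 5, 3: 5, 4: 40})
    assert first_local_minimum(sp) == 2


def test_first_local_minimum_monotone_decreasing_is_none():
    sp = _spectrum({1: 100, 2: 50, 3: 20, 4: 10})
    assert first_local_minimum(sp) is None


def test_find_peaks_flat_beyond_cutoff_is_empty():
    sp = _spectrum({1: 100, 2: 10})
    assert find_peaks(sp, cutoff=2) == []


@pytest.mark.parametrize(
    "peaks,label",
    [
        ([(30, 1000.0)], "homozygous"),
        ([(15, 400.0), (30, 1000.0)], "heterozygous"),
        ([(10, 50.0), (30, 1000.0)], "homozygous"),  # 5% secondary = noise
    ],
)
def test_classify_zygosity_threshold_rules(peaks, label):
    call = classify_zygosity(peaks)
    assert call.label == label
    if label == "heterozygous":
        assert call.het_to_hom_height_ratio == pytest.approx(0.4)


def test_classify_zygosity_empty_is_undetermined():
    assert classify_zygosity([]).label == "undetermined"


def _library_spectrum(theta: float, seed: int, genome_length=50_000):
    spec = SimulationSpec(
        genome_length=genome_length,
        region_length=genome_length // 5,
        ploidy=2,
        copy_number=2,
        snp_rate=theta,
        depth_per_haplotype=30.0,
        seed=seed,
    )
    _, truth = simulate_haplotypes(spec)
    reads = simulate_reads(truth)
    return count_kmers(reads.seqs, 15)


def test_homozygous_library_has_single_coverage_peak():
    sp = _library_spectrum(theta=0.0, seed=1)
    cutoff = first_local_minimum(sp)
    peaks = find_peaks(sp, cutoff)
    assert len(peaks) == 1
    # error-thinned k-mer coverage: 2c * (1-eps)^k * (l-k+1)/l
    expect = 2 * 30 * (1 - 0.01) ** 15 * (100 - 15 + 1) / 100
    assert abs(peaks[0][0] - expect) <= 3


def test_heterozygous_library_has_half_coverage_secondary_peak():
    sp = _library_spectrum(theta=0.01, seed=1)
    call = zygosity_from_spectrum(sp)
    assert call.label == "heterozygous"
    peaks = sorted(call.peaks, key=lambda p: p[1])
    minor, major = peaks[-2][0], peaks[-1][0]
    assert 0.4 * major <= minor <= 0.6 * major


# ---------------------------------------------------------------------------
# genome size
# ---------------------------------------------------------------------------


def test_genome_size_recovered_from_error_free_reads():
    spec = SimulationSpec(
        genome_length=10_000,
        region_length=2_000,
        ploidy=1,
        copy_number=1,
        snp_rate=0.0,
        depth_per_haplotype=20.0,
        error_rate=0.0,
        seed=9,
    )
    _, truth = simulate_haplotypes(spec)
    reads = simulate_reads(truth)
    sp = count_kmers(reads.seqs, 15)
    peak = max(find_peaks(sp, cutoff=0), key=lambda p: p[1])
    est = estimate_genome_size(sp, cutoff=0, hom_peak_multiplicity=peak[0])
    assert est == pytest.approx(10_000, rel=0.05)


def test_genome_size_linearity_and_empty_tail():
    sp = _spectrum({1: 100, 10: 50, 20: 25})
    base = estimate_genome_size(sp, cutoff=2, hom_peak_multiplicity=10)
    doubled = KmerSpectrum(k=15, hist={m: 2 * c for m, c in sp.hist.items()})
    assert estimate_genome_size(doubled, 2, 10) == pytest.approx(2 * base)
    below = _spectrum({1: 100, 2: 50})
    assert estimate_genome_size(below, cutoff=5, hom_peak_multiplicity=10) == 0.0


# ---------------------------------------------------------------------------
# reads-vs-assembly completeness
# ---------------------------------------------------------------------------


def _carrier_reads_and_assembly():
    spec = SimulationSpec(
        genome_length=30_000,
        region_length=6_000,
        ploidy=2,
        copy_number=2,
        snp_rate=0.0,
        depth_per_haplotype=10.0,
        error_rate=0.0,
        seed=4,
    )
    reference, truth = simulate_haplotypes(spec)
    reads = simulate_reads(truth)
    return reference, truth, reads


def test_copy_spectrum_exact_assembly_is_complete():
    reference, _, reads = _carrier_reads_and_assembly()
    table = count_kmer_table(reads.seqs, 15)
    cs = assembly_copy_spectrum(table, reference, 15, cutoff=0)
    assert cs.completeness == 1.0


def test_copy_spectrum_missing_kmers_map_to_deleted_region():
    """Deleting the focal region from the assembly leaves exactly the
    region's k-mers unrepresented (set-difference oracle)."""
    reference, truth, reads = _carrier_reads_and_assembly()
    seq = reference.sequence(truth.contig)
    r = truth.region
    deleted = ContigSet.from_records([("del", seq[: r.start] + seq[r.end :])])
    table = count_kmer_table(reads.seqs, 15)
    cs = assembly_copy_spectrum(table, deleted, 15, cutoff=0)
    assert cs.completeness < 1.0
    # oracle: the missing k-mer set == k-mers unique to the region's sequence
    full_table = count_kmer_table([seq], 15)
    del_table = count_kmer_table([seq[: r.start] + seq[r.end :]], 15)
    missing_expected = np.setdiff1d(full_table.codes, del_table.codes)
    present = del_table.lookup(table.codes) > 0
    missing_observed = table.codes[~present]
    assert np.array_equal(np.intersect1d(missing_observed, missing_expected),
                          missing_observed)


def test_copy_spectrum_empty_assembly_completeness_zero(tmp_path):
    _, _, reads = _carrier_reads_and_assembly()
    table = count_kmer_table(reads.seqs, 15)
    empty = ContigSet.from_records([("e", "A" * 14)])  # shorter than k
    cs = assembly_copy_spectrum(table, empty, 15, cutoff=0)
    assert cs.completeness == 0.0


def test_copy_spectrum_k_mismatch_rejected():
    table = count_kmer_table(["ACGTACGTACGT"], 5)
    with pytest.raises(KmerParameterError):
        assembly_copy_spectrum(table, ContigSet.from_records([("a", "ACGT")]), 7, 1)
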