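"""Depth accumulation, windowing, CDS summaries and dosage calls."""
import numpy as np
import pytest

from supergene import (
    Alignment,
    AnnotationSet,
    GenomicInterval,
    SimulationSpec,
    TranscriptModel,
    UnitSummary,
    bootstrap_ratio_ci,
    call_region_dosage,
    cds_depth,
    depth_from_alignments,
    depth_from_segments,
    dosage_call,
    normalize,
    region_flank_medians,
    simulate_haplotypes,
    simulate_reads,
    window_means,
)
from supergene.core import ContigSet
from supergene.depth import DepthProfile
from supergene.errors import (
    AlignmentOutOfBoundsError,
    ConfigError,
    EmptyUnitSetError,
    NoCdsError,
    ZeroFlankDepthError,
)


def _contigs(seq: str, name: str = "c") -> ContigSet:
    return ContigSet.from_records([(name, seq)])


def _aln(pos0, cigar, mapq=60, **kw):
    return Alignment("q", "c", pos0, mapq, cigar, **kw)


# ---------------------------------------------------------------------------
# depth accumulation
# ---------------------------------------------------------------------------


def test_single_read_depth_and_mapq_filter():
    cs = _contigs("A" * 20)
    prof = depth_from_alignments([_aln(0, [("M", 10)])], cs, "c")
    assert prof.depth[:10].tolist() == [1.0] * 10
    assert not prof.depth[10:].any()
    low = depth_from_alignments([_aln(0, [("M", 10)], mapq=10)], cs, "c")
    assert not low.depth.any()


def test_deletion_ops_contribute_no_depth():
    cs = _contigs("A" * 20)
    prof = depth_from_alignments(
        [_aln(0, [("M", 5), ("D", 3), ("M", 5)])], cs, "c"
    )
    assert prof.depth[:5].tolist() == [1.0] * 5
    assert prof.depth[5:8].tolist() == [0.0] * 3
    assert prof.depth[8:13].tolist() == [1.0] * 5


def test_secondary_and_unmapped_records_excluded():
    cs = _contigs("A" * 20)
    alns = [
        _aln(0, [("M", 10)], is_secondary=True),
        Alignment("q", None, -1, 0, [], is_unmapped=True),
    ]
    assert not depth_from_alignments(alns, cs, "c").depth.any()


def test_alignment_past_contig_end_rejected():
    cs = _contigs("A" * 8)
    with pytest.raises(AlignmentOutOfBoundsError):
        depth_from_alignments([_aln(4, [("M", 10)])], cs, "c")


def test_depth_matches_brute_force_position_count(rng):
    """Diff-array depth equals a per-position overlap count."""
    for _ in range(60):
        length = int(rng.integers(20, 120))
        cs = _contigs("A" * length)
        n_reads = int(rng.integers(1, 100))
        alns, brute = [], np.zeros(length)
        for _ in range(n_reads):
            span = int(rng.integers(1, 15))
            pos = int(rng.integers(0, length - span + 1))
            mapq = int(rng.integers(0, 61))
            alns.append(_aln(pos, [("M", span)], mapq=mapq))
            if mapq >= 30:
                brute[pos : pos + span] += 1
        prof = depth_from_alignments(alns, cs, "c", min_mapq=30)
        assert np.array_equal(prof.depth, brute)


def test_segment_fast_path_equals_alignment_path(rng):
    length = 500
    cs = _contigs("A" * length)
    starts = rng.integers(0, 400, 200)
    spans = rng.integers(1, 100, 200)
    ends = np.minimum(starts + spans, length)
    mapq = rng.integers(0, 61, 200)
    alns = [
        _aln(int(s), [("M", int(e - s))], mapq=int(q))
        for s, e, q in zip(starts, ends, mapq)
    ]
    a = depth_from_alignments(alns, cs, "c")
    b = depth_from_segments("c", length, starts, ends, mapq)
    assert np.array_equal(a.depth, b.depth)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def test_normalize_per_gigabase():
    prof = DepthProfile("c", np.full(10, 10.0), np.zeros(10, dtype=bool))
    out = normalize(prof, 2e9)
    assert out.depth.tolist() == [5.0] * 10
    assert out.norm_factor == pytest.approx(0.5)
    with pytest.raises(ConfigError):
        normalize(prof, 0)


def test_normalization_leaves_dosage_ratio_unchanged():
    depth = np.concatenate([np.full(50, 30.0), np.full(50, 15.0)])
    prof = DepthProfile("c", depth, np.zeros(100, dtype=bool))
    region = GenomicInterval("c", 50, 100)
    flanks = [GenomicInterval("c", 0, 50)]
    raw = call_region_dosage(window_means(prof, 10), region, flanks, ploidy=2)
    scaled = call_region_dosage(
        window_means(normalize(prof, 3.3e8), 10), region, flanks, ploidy=2
    )
    assert scaled.ratio == pytest.approx(raw.ratio)
    assert scaled.label == raw.label == "hemizygous"


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


def test_window_tiling_with_trailing_partial():
    prof = DepthProfile("c", np.full(12_000, 8.0), np.zeros(12_000, dtype=bool))
    wins = window_means(prof, 5000)
    assert [w.value for w in wins] == [8.0, 8.0, 8.0]
    assert [w.interval.length for w in wins] == [5000, 5000, 2000]


def test_window_mean_over_unmasked_half():
    mask = np.zeros(10, dtype=bool)
    mask[:5] = True
    prof = DepthProfile("c", np.full(10, 6.0), mask)
    (win,) = window_means(prof, 10)
    assert win.value == 6.0
    assert win.n_unmasked == 5


def test_fully_masked_window_flagged_undefined():
    prof = DepthProfile("c", np.zeros(10), np.ones(10, dtype=bool))
    (win,) = window_means(prof, 10)
    assert not win.defined


# ---------------------------------------------------------------------------
# CDS depth
# ---------------------------------------------------------------------------


def _annotation(cds_ivs, contig="c"):
    txs = []
    for i, (s, e) in enumerate(cds_ivs):
        iv = GenomicInterval(contig, s, e)
        txs.append(
            TranscriptModel(f"g{i}", f"g{i}.1", contig, "+", [iv], [iv])
        )
    return AnnotationSet(txs)


def test_cds_median_uniform_depth():
    prof = DepthProfile("c", np.full(1000, 20.0), np.zeros(1000, dtype=bool))
    (rec,) = cds_depth(prof, _annotation([(100, 400)]))
    assert rec.value == 20.0


def test_cds_in_n_gap_flagged():
    mask = np.zeros(100, dtype=bool)
    mask[10:30] = True
    prof = DepthProfile("c", np.full(100, 5.0), mask)
    recs = cds_depth(prof, _annotation([(10, 30), (50, 70)]))
    assert not recs[0].defined and recs[1].value == 5.0


def test_no_cds_on_contig_is_an_error():
    prof = DepthProfile("c", np.zeros(10), np.zeros(10, dtype=bool))
    with pytest.raises(NoCdsError):
        cds_depth(prof, _annotation([(0, 5)], contig="other"))


def test_hemizygote_cds_depths_split_region_vs_flank(hemizygote):
    _, truth = hemizygote
    from supergene.simulate import make_gene_models, simulate_reads

    ann = make_gene_models(truth, n_genes_in=2, n_genes_out=4)
    reads = simulate_reads(truth)
    starts, ends, mapq = reads.depth_segments()
    prof = depth_from_segments(truth.contig, truth.ref_codes.size, starts, ends, mapq)
    recs = cds_depth(prof, ann, truth.region)
    inside = [r.value for r in recs if r.in_region]
    outside = [r.value for r in recs if not r.in_region]
    c = truth.spec.depth_per_haplotype
    assert np.median(inside) == pytest.approx(c, rel=0.2)
    assert np.median(outside) == pytest.approx(2 * c, rel=0.2)


# ---------------------------------------------------------------------------
# medians and calls
# ---------------------------------------------------------------------------


def _units(vals, start=0, contig="c", step=10):
    out = []
    for i, v in enumerate(vals):
        s = start + i * step
        out.append(
            UnitSummary(GenomicInterval(contig, s, s + step), float(v), step)
        )
    return out


def test_region_flank_medians_with_even_count_rule():
    region = GenomicInterval("c", 0, 30)
    flanks = [GenomicInterval("c", 30, 60)]
    units = _units([5, 5, 6]) + _units([10, 12], start=30)
    assert region_flank_medians(units, region, flanks) == (5.0, 11.0)


def test_undefined_units_skipped_and_empty_is_error():
    region = GenomicInterval("c", 0, 30)
    flanks = [GenomicInterval("c", 30, 60)]
    units = _units([5, 5, 6])
    units += [
        UnitSummary(GenomicInterval("c", 30, 40), float("nan"), 0),
        UnitSummary(GenomicInterval("c", 40, 50), 10.0, 10),
    ]
    assert region_flank_medians(units, region, flanks) == (5.0, 10.0)
    with pytest.raises(EmptyUnitSetError):
        region_flank_medians(_units([5]), region, [GenomicInterval("c", 50, 60)])


@pytest.mark.parametrize(
    "med_r,med_f,ploidy,label,m",
    [
        (15.0, 30.0, 2, "hemizygous", 1),
        (0.0, 30.0, 2, "null", 0),
        (30.0, 30.0, 2, "homozygous", 2),
        (10.0, 30.0, 6, "partial", 2),  # r=1/3, hexaploid with 2 copies
        (7.5, 30.0, 2, "ambiguous", None),  # r*p = 0.5, mid-gap
    ],
)
def test_dosage_call_rounding_and_labels(med_r, med_f, ploidy, label, m):
    call = dosage_call(med_r, med_f, ploidy)
    assert call.label == label
    assert call.copy_number == m


def test_zero_flank_median_is_a_distinct_error():
    with pytest.raises(ZeroFlankDepthError):
        dosage_call(5.0, 0.0, 2)


def test_dosage_scale_invariance():
    for lam in (0.01, 1.0, 250.0):
        call = dosage_call(15.0 * lam, 30.0 * lam, 2)
        assert call.label == "hemizygous"
        assert call.ratio == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def test_bootstrap_identical_units_zero_width_ci():
    ci = bootstrap_ratio_ci([4.0] * 10, [4.0] * 10, B=200, seed=1)
    assert ci == (1.0, 1.0)


def test_bootstrap_deterministic_for_fixed_seed():
    r = [3.0, 4.0, 5.0, 6.0]
    f = [8.0, 9.0, 10.0, 11.0]
    assert bootstrap_ratio_ci(r, f, seed=42) == bootstrap_ratio_ci(r, f, seed=42)


def test_bootstrap_ci_covers_true_hemizygote_ratio(rng):
    """95% CI covers the true ratio 0.5 in >= 93/100 unit-level replicates.

    Units emulate per-CDS medians of a p=2, m=1 sample: Poisson depth
    around c in the region and 2c in the flanks, 40 units per side.
    """
    c, n_units, hits = 15.0, 40, 0
    for rep in range(100):
        region_units = rng.poisson(c, n_units).astype(float)
        flank_units = rng.poisson(2 * c, n_units).astype(float)
        lo, hi = bootstrap_ratio_ci(region_units, flank_units, B=400, seed=rep)
        if lo <= 0.5 <= hi:
            hits += 1
    assert hits >= 93
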