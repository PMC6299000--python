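# Methods

This note documents the models, parameter choices, numerical conventions
and limitations behind the package. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and formats

All internal coordinates are 0-based half-open; GFF3, SAM POS and the
per-base depth TSV are converted at the I/O boundary (`supergene.io`) and
nowhere else. Soft-masked (lowercase) FASTA is uppercased on input — repeat
information is interval-driven (BED), never case-driven. Strand is carried
on intervals but never flips coordinates: depth and interval arithmetic are
strand-agnostic. SAM support is the minimal text dialect (columns 1–9,
header required); BAM/CRAM and VCF are out of scope.

## Read-depth dosage model

A region present on *m* of *p* haplotypes receives shotgun reads from *m*
haplotypes while its flanks receive reads from all *p*; with uniform
coverage the expected depth ratio is m/p. The estimator:

* Depth is accumulated only at reference positions consumed by CIGAR
  M/=/X; D and N spans contribute nothing (the usual per-base depth
  semantics). Unmapped, secondary and supplementary records and records
  below the MAPQ threshold are excluded. Default `min_mapq = 30`.
* Normalization multiplies depth by 1e9 / (total sequenced bases), i.e.
  depth per gigabase. Bases rather than read count were chosen so libraries
  with different read lengths compare fairly; the choice cannot affect the
  dosage call (the ratio is scale-invariant, a tested invariant).
* Summary units are non-overlapping windows (default 5 kb, tiled from
  position 0; a trailing partial window is kept, flagged with its true
  width) or unique CDS intervals (median depth each). CDS restriction is
  the right mode when reads come from a different species than the
  reference, because coding sequence is where cross-species mapping is
  trustworthy. Positions that are N in the reference are masked out of all
  statistics; fully masked units carry NaN and are skipped.
* The region and flank medians are taken over unit-level values, not
  per-base, for robustness against a few high-copy repeat positions. Units
  are assigned to region/flank by interval midpoint. Even counts use the
  midpoint-of-central-pair rule.
* `m̂ = round(r·p)` is accepted only when `|r·p − m̂| ≤ guard·p` with
  `guard = 0.15`; otherwise the call is *ambiguous* rather than forced —
  borderline biological cases deserve a hedge, not a coin flip.
* The 95% CI on r is a percentile bootstrap (default B = 1000), resampling
  units with replacement independently on each side; deterministic for a
  fixed seed. All-equal units legitimately give a zero-width CI.

Known limitation: no duplicate-read handling and no GC-bias correction;
reads are taken as given. The pipeline targets one focal region — it is not
a genome-wide CNV segmenter.

## K-mer spectrum model

K-mers are canonicalized as min(k-mer, reverse complement); k is restricted
to odd values ≤ 31 (no palindromic self-canonical ties; 2 bits/base fits a
uint64). Windows containing N are skipped. Counting is chunked and
vectorized (Horner reduction of 2-bit codes); only the distinct-k-mer table
is held, and the spectrum is the retained product. Default k = 31; analyses
of desk-scale simulations use k = 15, and k is a parameter everywhere.

Spectrum shape analysis:

* The error cutoff is the first local minimum: the smallest multiplicity
  x ≥ 2 with hist(x) ≤ both neighbours on the zero-filled histogram (ties
  resolve to the smallest x). A monotone-decreasing histogram yields "no
  minimum", reported as an undetermined signal rather than an error.
* Peaks are local maxima of the histogram smoothed with a centred moving
  average of width 3, keeping peaks ≥ 5% of the tallest.
* Classification: a secondary peak at 0.4–0.6× the major peak's
  multiplicity with height ≥ 10% of the major marks *heterozygous*; no
  significant secondary peak marks *homozygous*; no peaks, or a significant
  off-band secondary, is *undetermined*. The thresholds make an inherently
  visual judgement deterministic; all are configurable, and smaller
  secondary peaks are treated as histogram noise.
* Genome size = Σ_{x>cutoff} x·hist(x) / (homozygous peak multiplicity):
  error-free k-mer instances divided by per-copy k-mer depth. The expected
  peak multiplicity under coverage c, read length ℓ and error rate ε is
  c·(1−ε)^k·(ℓ−k+1)/ℓ (binomial error thinning × window availability), a
  closed form the tests check against simulation.
* The reads-vs-assembly copy spectrum tallies, for each distinct read k-mer,
  its copy count in an assembly (0/1/2/≥3); completeness is the fraction of
  above-cutoff read k-mers present at least once — low-multiplicity (error)
  k-mers are expected to be absent, genuine genomic k-mers present.

## Synthetic data generator

`SimulationSpec` defaults describe the conditions used throughout the
recovery suites: a 500 kb diploid with a 30 kb centred region carried on one
haplotype, SNP heterozygosity θ = 0.01 between haplotypes, 15× per-haplotype
coverage of 100 bp single-end reads at 1% base error. The reference is a
carrier haplotype, so region coordinates exist on the reference and
non-carrier samples show zero depth over it — reproducing the
presence/absence asymmetry of mapping against a carrier-derived assembly.
For m ≥ 1 the first haplotype *is* the reference; every other haplotype is a
Bernoulli(θ) substitution copy, and non-carriers have the region cleanly
deleted. Zygosity benchmarks use 30× per haplotype: at 15× the heterozygous
(≈ c_k/2) and homozygous (≈ c_k) Poisson components of a k = 15 spectrum
overlap too strongly for any local-maximum detector, while 30× separates
them cleanly.

Repeat planting tiles mutated copies of one unit sequence (default 500 bp,
per-copy divergence d = 0.05) onto non-overlapping unit-aligned slots until
the merged coverage matches the target (region default 0.64, background
0.37) to within one slot; ±0.02 is enforced. Haplotypes are rebuilt after
planting so carriers share the region's copies.

Gene models lay non-overlapping transcripts left-to-right: uniform exon
counts and lengths, log-normal intron and intergenic-gap laws parameterized
by their medians (background introns: median 440 bp, σ = 0.8). Laws carry a
far-upper-tail cap so the worst-case gene footprint provably fits its
compartment for any seed; the cap sits at quantiles ≥ 99% and does not move
the median (a tested recovery). Focal-region laws default to a per-gene
budget derived from the region length. CDS equals exons (UTR-less models).

Reads have uniform start positions per haplotype and i.i.d. base errors.
Truth alignments place each read at its origin with MAPQ 60; a read from a
non-carrier haplotype spanning the deletion junction gets a split
(aM rN bM) truth record. Reads wholly inside a planted repeat copy when the
family has ≥ 2 copies at divergence < 2ε get MAPQ 0 — a deliberate, simple
stand-in for aligner ambiguity in near-identical repeats, documented rather
than claimed realistic. The generator is single-end only, has no indel
polymorphism, no GC or insert-size bias, and no transposition model; passing
recovery tests therefore demonstrate correctness of the inference under the
stated generative model, not robustness to every artefact of real libraries.

All randomness flows from one integer seed through named numpy generators;
identical seeds give byte-identical FASTQ/SAM/JSON outputs (tested).

The multi-contig scene (`SceneSpec`) used by the region-report analyses
places a 150 kb focal region inside a 400 kb contig among 30 background
contigs sized within ±10% of the region length, so both contig selectors
(length > 10 kb; size-matched ±20%) have a comparison sample of n = 30.

## Region statistics conventions

* Repeat fractions use merged (union) interval coverage; the denominator
  includes N positions by default (masked-assembly convention), with an
  unmasked-denominator switch.
* Percentile is the strictly-less convention, 100·#{s < value}/n; "top 5%"
  ⇔ percentile ≥ 95. A value equal to the whole sample sits at 0.
* The contig selector "> 10 kb" is strict; the size-matched selector keeps
  lengths within ±20% of the target, inclusive.
* Intergenic distance is next gene-body start − current gene-body end over
  outermost exon spans, so abutting genes give 0; overlapping pairs give 0
  and are flagged. Per-contig repeat fractions are unweighted by length.
* Intron statistics are per-transcript by default with an optional
  per-gene deduplication of spliceoform-shared introns.
* N50 is the length of the contig where the descending cumulative sum first
  reaches half the assembly total; NG50 uses half an independent genome-size
  estimate instead and is flagged undefined (None) when the assembly never
  reaches G/2.

## Problem sizes in the test and acceptance suites

Recovery suites run at desk scale by design: dosage uses 50 replicates per
copy number on 500 kb genomes; zygosity uses 20 replicates per SNP rate on
200 kb genomes at k = 15; the repeat scene is ~5 Mb over 31 contigs. These
sizes give binomial confidence adequate for the pass thresholds (≥ 95%
label accuracy over n = 150; ≥ 19/20 per zygosity condition) while the full
suite completes in a couple of minutes on one CPU.

## Exit codes and orchestration

The CLI maps error classes to exit codes (0 success, 2 configuration,
3 data, 4 internal), logs to stderr only, and writes machine-readable
output (JSON/TSV) plus the merged effective config to the output directory;
re-running with the same config and seed reproduces the outputs
byte-for-byte. Optional plotting is not implemented; the JSON/TSV outputs
are the supported surface.
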