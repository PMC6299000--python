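"""Canonical k-mer frequency spectra, zygosity classification and
reads-vs-assembly completeness.

A k-mer spectrum is the histogram "multiplicity -> number of distinct
canonical k-mers" over a read library.  For a diploid sequenced at total
coverage c, homozygous k-mers pile up near multiplicity c while k-mers
overlapping a heterozygous site split into two variants near c/2; sequencing
errors contribute a mass of near-unique k-mers below the first local minimum
of the histogram.  The shape of the spectrum beyond that minimum therefore
reads out library zygosity: unimodal = homozygous, a secondary peak at about
half the major peak's multiplicity = heterozygous.

k-mers are canonicalized as the lexicographic minimum of the k-mer and its
reverse complement (k odd, so no self-complementary ties); k-mers containing
N are skipped.  Counting is chunked and vectorized: bases are 2-bit encoded
and each window reduced to a base-4 integer, so k <= 31 fits in uint64.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .core import ContigSet, encode_seq
from .errors import KmerParameterError

_CHUNK_WINDOWS = 1 << 21  # max windows materialized per chunk


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------


def _check_k(k: int) -> None:
    if k <= 0:
        raise KmerParameterError(f"k must be positive (got {k})")
    if k % 2 == 0:
        raise KmerParameterError(f"k must be odd (got {k})")
    if k > 31:
        raise KmerParameterError(f"k must be <= 31 to fit in 64 bits (got {k})")


def _window_values(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical k-mer integer per window of one encoded sequence.

    Base-4 window values are built with k vectorized Horner passes; the
    reverse complement uses the complementary codes with ascending powers.
    Windows containing an invalid base (code 4, i.e. N) are dropped.
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    codes64 = codes.astype(np.uint64)
    comp64 = np.uint64(3) - codes64  # invalid code 4 wraps; masked out below
    four = np.uint64(4)
    fwd = np.zeros(n, dtype=np.uint64)
    rc = np.zeros(n, dtype=np.uint64)
    for j in range(k):  # fwd: descending powers, Horner left-to-right
        fwd *= four
        fwd += codes64[j : j + n]
    for j in range(k - 1, -1, -1):  # rc: ascending powers, Horner high-to-low
        rc *= four
        rc += comp64[j : j + n]
    bad = np.concatenate([[0], np.cumsum(codes == 4)])
    valid = (bad[k:] - bad[:-k]) == 0
    return np.minimum(fwd, rc)[valid]


class _TableAccumulator:
    """Streaming accumulator of (canonical k-mer code, count) pairs.

    Chunks of raw window codes are compacted into a sorted unique table as
    they arrive, so memory stays proportional to the number of distinct
    k-mers plus one pending buffer.
    """

    def __init__(self) -> None:
        self.codes = np.empty(0, dtype=np.uint64)
        self.counts = np.empty(0, dtype=np.int64)
        self._pending: list[np.ndarray] = []
        self._pending_n = 0
        self.total_instances = 0

    def add(self, window_codes: np.ndarray) -> None:
        if window_codes.size == 0:
            return
        self.total_instances += int(window_codes.size)
        self._pending.append(window_codes)
        self._pending_n += window_codes.size
        if self._pending_n >= (1 << 24):
            self.compact()

    def compact(self) -> None:
        if not self._pending:
            return
        u, c = np.unique(np.concatenate(self._pending), return_counts=True)
        self._pending, self._pending_n = [], 0
        if self.codes.size == 0:
            self.codes, self.counts = u, c.astype(np.int64)
            return
        merged = np.concatenate([self.codes, u])
        weights = np.concatenate([self.counts, c])
        order = np.argsort(merged, kind="stable")
        merged, weights = merged[order], weights[order]
        boundary = np.ones(merged.size, dtype=bool)
        boundary[1:] = merged[1:] != merged[:-1]
        (starts,) = np.nonzero(boundary)
        self.codes = merged[starts]
        self.counts = np.add.reduceat(weights, starts)


@dataclass
class KmerTable:
    """Sorted distinct canonical k-mers with their multiplicities."""

    k: int
    codes: np.ndarray  # uint64, sorted
    counts: np.ndarray  # int64
    total_instances: int

    def spectrum(self) -> "KmerSpectrum":
        mult, n = np.unique(self.counts, return_counts=True)
        return KmerSpectrum(
            k=self.k,
            hist={int(m): int(c) for m, c in zip(mult, n)},
        )

    def lookup(self, codes: np.ndarray) -> np.ndarray:
        """Multiplicity in this table for each query code (0 if absent)."""
        idx = np.searchsorted(self.codes, codes)
        idx = np.clip(idx, 0, max(self.codes.size - 1, 0))
        out = np.zeros(codes.size, dtype=np.int64)
        if self.codes.size:
            hit = self.codes[idx] == codes
            out[hit] = self.counts[idx[hit]]
        return out


@dataclass
class KmerSpectrum:
    """Histogram: multiplicity -> number of distinct canonical k-mers."""

    k: int
    hist: dict[int, int] = field(default_factory=dict)

    @property
    def total_kmer_instances(self) -> int:
        return sum(m * c for m, c in self.hist.items())

    @property
    def total_distinct(self) -> int:
        return sum(self.hist.values())

    def dense(self, max_mult: int | None = None) -> np.ndarray:
        """Zero-filled array h where h[x] = hist.get(x, 0), index 0 unused."""
        if not self.hist:
            return np.zeros(1, dtype=np.int64)
        top = max(self.hist)
        if max_mult is not None:
            top = min(top, max_mult)
        h = np.zeros(top + 1, dtype=np.int64)
        for m, c in self.hist.items():
            if m <= top:
                h[m] += c
        return h

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("multiplicity\tdistinct_kmers\n")
            for m in sorted(self.hist):
                fh.write(f"{m}\t{self.hist[m]}\n")

    @classmethod
    def read_tsv(cls, path: str | Path, k: int) -> "KmerSpectrum":
        hist = {}
        with open(path) as fh:
            next(fh)
            for line in fh:
                m, c = line.split("\t")
                hist[int(m)] = int(c)
        return cls(k=k, hist=hist)


@dataclass
class ZygosityCall:
    """Outcome of the spectrum-shape zygosity classification."""

    error_cutoff: int | None
    peaks: list[tuple[int, float]]
    label: str  # homozygous | heterozygous | undetermined
    het_to_hom_height_ratio: float | None = None

    def to_dict(self) -> dict:
        return {
            "error_cutoff": self.error_cutoff,
            "peaks": [[int(m), float(h)] for m, h in self.peaks],
            "label": self.label,
            "het_to_hom_height_ratio": self.het_to_hom_height_ratio,
        }


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------


def count_kmer_table(sequences: Iterable[str] | np.ndarray, k: int) -> KmerTable:
    """Count canonical k-mers over sequences.

    Accepts an iterable of strings, or a 2D uint8 base-code matrix of
    equal-length reads (rows are joined with invalid separators so no
    window spans two reads).  Retains the distinct-k-mer table (needed for
    assembly comparisons); use :func:`count_kmers` when only the spectrum
    is wanted.
    """
    _check_k(k)
    acc = _TableAccumulator()
    if isinstance(sequences, np.ndarray) and sequences.ndim == 2:
        n = sequences.shape[0]
        rows_per_block = max(1, _CHUNK_WINDOWS // max(sequences.shape[1], 1))
        for lo in range(0, n, rows_per_block):
            block = sequences[lo : lo + rows_per_block]
            pad = np.full((block.shape[0], k - 1), 4, dtype=np.uint8)
            flat = np.hstack([block, pad]).ravel()
            acc.add(_window_values(flat, k))
    else:
        for seq in sequences:
            codes = (
                encode_seq(seq)
                if isinstance(seq, str)
                else np.asarray(seq, dtype=np.uint8)
            )
            acc.add(_window_values(codes, k))
    acc.compact()
    return KmerTable(
        k=k, codes=acc.codes, counts=acc.counts, total_instances=acc.total_instances
    )


def count_kmers(sequences: Iterable[str] | np.ndarray, k: int) -> KmerSpectrum:
    """Canonical k-mer spectrum of a read set (streaming over sequences)."""
    return count_kmer_table(sequences, k).spectrum()


# ---------------------------------------------------------------------------
# spectrum shape analysis
# ---------------------------------------------------------------------------


def first_local_minimum(spectrum: KmerSpectrum) -> int | None:
    """Error/noise cutoff: the first dip of the zero-filled histogram.

    Returns the smallest multiplicity x >= 2 with
    hist[x] <= hist[x-1] and hist[x] <= hist[x+1]; ties resolve to the
    smallest qualifying x.  Returns None for a histogram that only decreases
    (no minimum: an undetermined signal, not an error).
    """
    h = spectrum.dense()
    if h.size < 4:
        return None
    for x in range(2, h.size - 1):
        if h[x] <= h[x - 1] and h[x] <= h[x + 1]:
            return x
    return None


def find_peaks(
    spectrum: KmerSpectrum,
    cutoff: int,
    smooth_width: int = 3,
    min_rel_height: float = 0.05,
    max_mult: int = 10000,
) -> list[tuple[int, float]]:
    """Local maxima of the smoothed histogram beyond the error cutoff.

    The histogram is smoothed with a centered moving average (width 3,
    zero-padded); peaks with height below ``min_rel_height`` of the tallest
    retained peak are discarded.  Returns (multiplicity, smoothed height)
    pairs sorted by multiplicity.
    """
    h = spectrum.dense(max_mult=max_mult).astype(np.float64)
    if h.size <= cutoff + 1:
        return []
    pad = smooth_width // 2
    padded = np.concatenate([np.zeros(pad), h, np.zeros(pad)])
    kernel = np.ones(smooth_width) / smooth_width
    s = np.convolve(padded, kernel, mode="valid")  # same length as h
    peaks = []
    x = cutoff + 1
    while x < h.size:
        left = s[x - 1] if x >= 1 else 0.0
        right = s[x + 1] if x + 1 < h.size else 0.0
        if s[x] > 0 and s[x] > left and s[x] >= right:
            # leftmost point of a plateau counts as the peak
            peaks.append((x, float(s[x])))
            while x + 1 < h.size and s[x + 1] == s[x]:
                x += 1
        x += 1
    if not peaks:
        return []
    tallest = max(hh for _, hh in peaks)
    return [(m, hh) for m, hh in peaks if hh >= min_rel_height * tallest]


def classify_zygosity(
    peaks: Sequence[tuple[int, float]],
    error_cutoff: int | None = None,
    het_band: tuple[float, float] = (0.4, 0.6),
    min_secondary_height: float = 0.10,
) -> ZygosityCall:
    """Label a spectrum homozygous / heterozygous / undetermined.

    The major peak is the tallest.  A significant secondary peak (height
    >= 10% of the major) whose multiplicity falls in [0.4, 0.6] x the
    major's marks heterozygosity.  With no significant secondary peak the
    call is homozygous; with a significant secondary outside the band, or
    no peaks at all, it is undetermined.
    """
    peaks = sorted(peaks)
    if not peaks:
        return ZygosityCall(error_cutoff=error_cutoff, peaks=[], label="undetermined")
    major_mult, major_h = max(peaks, key=lambda p: p[1])
    ratio = None
    significant_secondary = [
        (m, h)
        for m, h in peaks
        if m != major_mult and h >= min_secondary_height * major_h
    ]
    for m, h in significant_secondary:
        if het_band[0] * major_mult <= m <= het_band[1] * major_mult:
            return ZygosityCall(
                error_cutoff=error_cutoff,
                peaks=list(peaks),
                label="heterozygous",
                het_to_hom_height_ratio=h / major_h,
            )
    if significant_secondary:
        return ZygosityCall(
            error_cutoff=error_cutoff, peaks=list(peaks), label="undetermined"
        )
    return ZygosityCall(error_cutoff=error_cutoff, peaks=list(peaks), label="homozygous")


def zygosity_from_spectrum(spectrum: KmerSpectrum) -> ZygosityCall:
    """Cutoff -> peaks -> classification in one step."""
    cutoff = first_local_minimum(spectrum)
    if cutoff is None:
        return ZygosityCall(error_cutoff=None, peaks=[], label="undetermined")
    return classify_zygosity(find_peaks(spectrum, cutoff), error_cutoff=cutoff)


def estimate_genome_size(
    spectrum: KmerSpectrum, cutoff: int, hom_peak_multiplicity: int
) -> float:
    """Haploid genome size: error-free k-mer instances / homozygous peak depth."""
    if hom_peak_multiplicity <= cutoff:
        raise KmerParameterError("homozygous peak must lie beyond the cutoff")
    if hom_peak_multiplicity <= 0:
        raise KmerParameterError("homozygous peak depth must be positive")
    total = sum(m * c for m, c in spectrum.hist.items() if m > cutoff)
    return total / hom_peak_multiplicity


# ---------------------------------------------------------------------------
# reads-vs-assembly completeness
# ---------------------------------------------------------------------------


@dataclass
class CopySpectrum:
    """Cross-tabulation of read k-mer multiplicity vs assembly copy count."""

    k: int
    cutoff: int
    # rows: read multiplicity 1..max; columns: assembly copies 0, 1, 2, >=3
    matrix: np.ndarray
    completeness: float  # fraction of read k-mers above cutoff present >= once

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("read_multiplicity\tcopies_0\tcopies_1\tcopies_2\tcopies_3plus\n")
            for m in range(1, self.matrix.shape[0]):
                row = self.matrix[m]
                if row.any():
                    fh.write(f"{m}\t" + "\t".join(str(int(v)) for v in row) + "\n")


def assembly_copy_spectrum(
    reads_table: KmerTable,
    assembly: ContigSet,
    k: int,
    cutoff: int,
    max_mult: int = 1000,
) -> CopySpectrum:
    """Tally assembly copy counts (0/1/2/>=3) of each distinct read k-mer.

    Completeness is the fraction of distinct read k-mers with multiplicity
    above the error cutoff that occur at least once in the assembly — the
    assembly-validation statistic for a read library against the genome it
    should represent.
    """
    if reads_table.k != k:
        raise KmerParameterError(
            f"k mismatch: reads counted at k={reads_table.k}, requested {k}"
        )
    asm_table = count_kmer_table((s for _, s in assembly.items()), k)
    copies = asm_table.lookup(reads_table.codes)
    col = np.minimum(copies, 3)
    row = np.minimum(reads_table.counts, max_mult)
    matrix = np.zeros((max_mult + 1, 4), dtype=np.int64)
    np.add.at(matrix, (row, col), 1)
    above = reads_table.counts > cutoff
    n_above = int(above.sum())
    completeness = float((copies[above] >= 1).sum() / n_above) if n_above else 0.0
    return CopySpectrum(k=k, cutoff=cutoff, matrix=matrix, completeness=completeness)
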