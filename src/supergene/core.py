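"""Core in-memory containers shared by every analysis stage.

All coordinates are 0-based half-open throughout the package; the standard
1-based formats (GFF3, SAM POS, per-base depth TSV) are converted at the I/O
edge and nowhere else.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .errors import DuplicateContigError, IllegalCharacterError

VALID_BASES = frozenset(b"ACGTN")

# 2-bit base codes used by the k-mer and simulation machinery.
# A=0 C=1 G=2 T=3; anything else (including N) = 4 = "invalid".
BASE_CODES = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    BASE_CODES[_b] = _i
    BASE_CODES[_b + 32] = _i  # lowercase
CODE_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode_seq(seq: str | bytes) -> np.ndarray:
    """Sequence -> uint8 code array (A=0 C=1 G=2 T=3, other=4)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return BASE_CODES[np.frombuffer(seq, dtype=np.uint8)]


def decode_seq(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_seq`; code 4 renders as N."""
    return CODE_BASES[codes].tobytes().decode("ascii")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named contig."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def contains(self, pos: float) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class ContigSet:
    """Ordered collection of named uppercase nucleotide sequences.

    Sequences are restricted to {A, C, G, T, N}; the N positions double as
    the ambiguous-base mask used by the depth analyses.
    """

    def __init__(self) -> None:
        self._seqs: dict[str, str] = {}

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "ContigSet":
        cs = cls()
        for name, seq in records:
            cs.add(name, seq)
        return cs

    def add(self, name: str, seq: str) -> None:
        if not name:
            raise DuplicateContigError("empty contig id")
        if name in self._seqs:
            raise DuplicateContigError(f"duplicate contig id {name!r}")
        seq = seq.upper()
        bad = set(seq.encode("ascii")) - VALID_BASES
        if bad:
            raise IllegalCharacterError(
                f"contig {name!r} contains illegal characters "
                f"{sorted(chr(b) for b in bad)}"
            )
        self._seqs[name] = seq

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def sequence(self, name: str) -> str:
        return self._seqs[name]

    def length(self, name: str) -> int:
        return len(self._seqs[name])

    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self._seqs.items()}

    def n_mask(self, name: str) -> np.ndarray:
        """Boolean mask, True at ambiguous (N) positions."""
        arr = np.frombuffer(self._seqs[name].encode("ascii"), dtype=np.uint8)
        return arr == ord("N")

    def n_count(self, name: str) -> int:
        return int(self.n_mask(name).sum())

    def total_bases(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def items(self) -> Iterator[tuple[str, str]]:
        return iter(self._seqs.items())


@dataclass
class TranscriptModel:
    """One transcript: its exon chain and CDS intervals on one contig."""

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt.start < prev.end:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.contig, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons (empty for single-exon models)."""
        out = []
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt.start > prev.end:
                out.append(
                    GenomicInterval(self.contig, prev.end, nxt.start, self.strand)
                )
        return out


class AnnotationSet:
    """Gene models: genes -> transcripts -> exon/CDS intervals."""

    def __init__(self, transcripts: Iterable[TranscriptModel] = ()) -> None:
        self.transcripts: list[TranscriptModel] = list(transcripts)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts)

    def add(self, tx: TranscriptModel) -> None:
        self.transcripts.append(tx)

    def on_contig(self, contig: str) -> list[TranscriptModel]:
        return [t for t in self.transcripts if t.contig == contig]

    def gene_spans(self, contig: str | None = None) -> dict[str, GenomicInterval]:
        """Outermost exon span per gene (union over its transcripts)."""
        spans: dict[str, GenomicInterval] = {}
        for tx in self.transcripts:
            if contig is not None and tx.contig != contig:
                continue
            s = tx.span
            if tx.gene_id in spans:
                old = spans[tx.gene_id]
                s = GenomicInterval(
                    old.contig, min(old.start, s.start), max(old.end, s.end),
                    old.strand,
                )
            spans[tx.gene_id] = s
        return spans

    def cds_intervals(self, contig: str) -> list[GenomicInterval]:
        """Unique CDS intervals on a contig, position-sorted."""
        seen = {
            (iv.start, iv.end)
            for tx in self.transcripts
            if tx.contig == contig
            for iv in tx.cds
        }
        return [
            GenomicInterval(contig, s, e) for s, e in sorted(seen)
        ]


@dataclass
class Alignment:
    """Minimal consumed SAM record (columns 1-9)."""

    query_id: str
    contig: str | None
    pos0: int  # 0-based leftmost reference position; -1 when unmapped
    mapq: int
    cigar: list[tuple[str, int]]
    is_unmapped: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False

    REF_CONSUMING = frozenset("M=XDN")

    def reference_span(self) -> int:
        """Reference bases consumed by the CIGAR (0 if unmapped)."""
        if self.is_unmapped:
            return 0
        return sum(n for op, n in self.cigar if op in self.REF_CONSUMING)
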