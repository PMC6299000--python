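"""Readers and writers for the standard formats (FASTA, GFF3, SAM, BED,
per-base depth TSV).

This is the only module that touches 1-based coordinates: GFF3 and SAM use
1-based inclusive positions on disk, the depth TSV uses 1-based positions,
BED is already 0-based half-open.  Everything handed to the rest of the
package is 0-based half-open.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import gffutils
import numpy as np
import pysam
from Bio import SeqIO

from .core import Alignment, AnnotationSet, ContigSet, GenomicInterval, TranscriptModel
from .depth import DepthProfile
from .errors import (
    DataError,
    DepthTsvError,
    EmptyFastaError,
    ExonOutsideGeneError,
    Gff3ParseError,
    OrphanCdsError,
    SamParseError,
)

# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> ContigSet:
    """Read a FASTA file into a :class:`ContigSet`.

    Sequences are uppercased; characters outside {A,C,G,T,N} raise
    :class:`IllegalCharacterError`, duplicate ids raise
    :class:`DuplicateContigError`, an empty file raises
    :class:`EmptyFastaError`.
    """
    cs = ContigSet()
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        cs.add(rec.id, str(rec.seq))
        n += 1
    if n == 0:
        raise EmptyFastaError(f"no FASTA records in {path}")
    return cs


def write_fasta(contigs: ContigSet, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def iter_read_sequences(path: str | Path) -> Iterator[str]:
    """Stream read sequences (as uppercase strings) from FASTA or FASTQ."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    for rec in SeqIO.parse(str(path), fmt):
        yield str(rec.seq).upper()


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def _prevalidate_gff3(path: str | Path) -> None:
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise Gff3ParseError(f"{path}:{ln}: fewer than 9 columns")
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise Gff3ParseError(f"{path}:{ln}: non-integer coordinate") from exc
            if end < start:
                raise Gff3ParseError(f"{path}:{ln}: end < start ({end} < {start})")
            if start < 1:
                raise Gff3ParseError(f"{path}:{ln}: start < 1")


def read_gff3(path: str | Path) -> AnnotationSet:
    """Read gene/mRNA/exon/CDS features into an :class:`AnnotationSet`.

    1-based inclusive GFF3 coordinates become 0-based half-open; exons are
    sorted per transcript.  Raises :class:`Gff3ParseError` for end < start,
    :class:`ExonOutsideGeneError` and :class:`OrphanCdsError` for structural
    defects.
    """
    _prevalidate_gff3(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )
    ann = AnnotationSet()
    mrna_ids = {f.id for f in db.features_of_type("mRNA")}
    for cds in db.features_of_type("CDS"):
        parents = [p for p in db.parents(cds, level=1)]
        if not parents or not any(p.id in mrna_ids for p in parents):
            raise OrphanCdsError(f"CDS {cds.id or cds.attributes} has no mRNA parent")
    for gene in db.features_of_type("gene"):
        g_iv = (gene.start - 1, gene.end)
        for mrna in db.children(gene, featuretype="mRNA", level=1):
            exons = []
            for ex in db.children(mrna, featuretype="exon", level=1):
                if not (g_iv[0] <= ex.start - 1 and ex.end <= g_iv[1]):
                    raise ExonOutsideGeneError(
                        f"exon {ex.start}-{ex.end} outside gene {gene.id} span"
                    )
                exons.append(
                    GenomicInterval(ex.seqid, ex.start - 1, ex.end, ex.strand or ".")
                )
            cds = [
                GenomicInterval(c.seqid, c.start - 1, c.end, c.strand or ".")
                for c in db.children(mrna, featuretype="CDS", level=1)
            ]
            if exons:
                ann.add(
                    TranscriptModel(
                        gene_id=gene.id,
                        transcript_id=mrna.id,
                        contig=gene.seqid,
                        strand=gene.strand or ".",
                        exons=exons,
                        cds=cds,
                    )
                )
    return ann


def write_gff3(annotation: AnnotationSet, path: str | Path, source: str = "supergene") -> None:
    """Write gene/mRNA/exon/CDS features (1-based inclusive on disk)."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in annotation:
        by_gene.setdefault(tx.gene_id, []).append(tx)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, txs in by_gene.items():
            contig = txs[0].contig
            strand = txs[0].strand
            g_start = min(t.span.start for t in txs)
            g_end = max(t.span.end for t in txs)
            fh.write(
                f"{contig}\t{source}\tgene\t{g_start + 1}\t{g_end}\t.\t{strand}\t.\t"
                f"ID={gene_id}\n"
            )
            for tx in txs:
                s = tx.span
                fh.write(
                    f"{contig}\t{source}\tmRNA\t{s.start + 1}\t{s.end}\t.\t{strand}\t.\t"
                    f"ID={tx.transcript_id};Parent={gene_id}\n"
                )
                for i, ex in enumerate(tx.exons, 1):
                    fh.write(
                        f"{contig}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t{strand}\t.\t"
                        f"ID={tx.transcript_id}.exon{i};Parent={tx.transcript_id}\n"
                    )
                for i, c in enumerate(tx.cds, 1):
                    fh.write(
                        f"{contig}\t{source}\tCDS\t{c.start + 1}\t{c.end}\t.\t{strand}\t0\t"
                        f"ID={tx.transcript_id}.cds{i};Parent={tx.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

_CIGAR_OPS = "MIDNSHP=X"


def read_sam(path: str | Path) -> Iterator[Alignment]:
    """Stream alignments from a text SAM file (header required).

    Unmapped and secondary records are yielded but flagged; CIGARs are parsed
    to (op, length) tuples.  Malformed records raise :class:`SamParseError`.
    """
    try:
        fh = pysam.AlignmentFile(str(path), "r", check_sq=False)
    except ValueError as exc:
        raise SamParseError(f"cannot parse SAM {path}: {exc}") from exc
    with fh:
        it = iter(fh)
        while True:
            try:
                rec = next(it)
            except StopIteration:
                break
            except (ValueError, OSError) as exc:
                raise SamParseError(f"malformed SAM record in {path}: {exc}") from exc
            unmapped = rec.is_unmapped
            if not unmapped and rec.reference_start < 0:
                raise SamParseError(
                    f"mapped record {rec.query_name} with POS < 1"
                )
            cigar = (
                [(_CIGAR_OPS[op], ln) for op, ln in rec.cigartuples]
                if rec.cigartuples
                else []
            )
            yield Alignment(
                query_id=rec.query_name,
                contig=None if unmapped else rec.reference_name,
                pos0=-1 if unmapped else rec.reference_start,
                mapq=rec.mapping_quality,
                cigar=cigar,
                is_unmapped=unmapped,
                is_secondary=rec.is_secondary,
                is_supplementary=rec.is_supplementary,
            )


def write_sam(
    alignments: Iterable[Alignment],
    contigs: ContigSet,
    path: str | Path,
) -> None:
    """Write minimal SAM records (no SEQ/QUAL) against a reference."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": contigs.length(n)} for n in contigs],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = aln.query_id
            rec.mapping_quality = aln.mapq
            flag = 0
            if aln.is_unmapped:
                flag |= 4
            if aln.is_secondary:
                flag |= 256
            if aln.is_supplementary:
                flag |= 2048
            rec.flag = flag
            if not aln.is_unmapped:
                rec.reference_name = aln.contig
                rec.reference_start = aln.pos0
                rec.cigartuples = [
                    (_CIGAR_OPS.index(op), ln) for op, ln in aln.cigar
                ]
            out.write(rec)


# ---------------------------------------------------------------------------
# per-base depth TSV  (contig, 1-based position, depth)
# ---------------------------------------------------------------------------


def read_depth_tsv(
    path: str | Path, contigs: ContigSet | None = None
) -> dict[str, DepthProfile]:
    """Read the three-column per-base depth dialect.

    Positions absent from the file mean depth 0.  When a :class:`ContigSet`
    is supplied, contig lengths and N masks come from it and out-of-range
    positions are an error; otherwise each profile is sized to the largest
    position seen.
    """
    rows: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                raise DepthTsvError(f"{path}:{ln}: fewer than 3 columns")
            contig = cols[0]
            try:
                pos = int(cols[1])
                depth = int(cols[2])
            except ValueError as exc:
                raise DepthTsvError(
                    f"{path}:{ln}: non-integer position or depth"
                ) from exc
            if pos < 1 or depth < 0:
                raise DepthTsvError(f"{path}:{ln}: position < 1 or depth < 0")
            rows.setdefault(contig, []).append((pos, depth))

    profiles: dict[str, DepthProfile] = {}
    names = list(contigs) if contigs is not None else list(rows)
    for name in names:
        pairs = rows.pop(name, [])
        if contigs is not None:
            length = contigs.length(name)
            mask = contigs.n_mask(name)
        else:
            length = max((p for p, _ in pairs), default=0)
            mask = np.zeros(length, dtype=bool)
        depth = np.zeros(length, dtype=np.float64)
        for pos, d in pairs:
            if pos > length:
                raise DepthTsvError(
                    f"position {pos} exceeds length of contig {name} ({length})"
                )
            depth[pos - 1] = d
        profiles[name] = DepthProfile(contig=name, depth=depth, mask=mask)
    if rows:
        raise DepthTsvError(f"depth rows for unknown contigs: {sorted(rows)}")
    return profiles


def write_depth_tsv(
    profiles: DepthProfile | Iterable[DepthProfile], path: str | Path
) -> None:
    """Write non-zero positions as (contig, 1-based position, depth) rows."""
    if isinstance(profiles, DepthProfile):
        profiles = [profiles]
    with open(path, "w") as fh:
        for prof in profiles:
            (nz,) = np.nonzero(prof.depth)
            for i in nz:
                d = prof.depth[i]
                d_str = str(int(d)) if float(d).is_integer() else repr(float(d))
                fh.write(f"{prof.contig}\t{i + 1}\t{d_str}\n")


# ---------------------------------------------------------------------------
# BED (0-based half-open)
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) < 3:
                raise DataError(f"{path}:{ln}: BED line has fewer than 3 columns")
            out.append(GenomicInterval(cols[0], int(cols[1]), int(cols[2])))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\n")
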