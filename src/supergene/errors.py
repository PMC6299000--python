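"""Exception hierarchy.

Every malformed-input condition raises a distinctly named subclass of
:class:`SupergeneError` so callers (and the CLI exit-code mapping) can tell
configuration problems from data problems from internal invariant violations.
"""


class SupergeneError(Exception):
    """Base class for all package errors."""


class ConfigError(SupergeneError):
    """Invalid run configuration or simulation parameters."""


class DataError(SupergeneError):
    """Malformed or inconsistent input data."""


# --- FASTA ---------------------------------------------------------------
class EmptyFastaError(DataError):
    """FASTA file contained no records."""


class DuplicateContigError(DataError):
    """Two FASTA records share an id."""


class IllegalCharacterError(DataError):
    """Sequence contains a character outside {A, C, G, T, N}."""


# --- GFF3 ----------------------------------------------------------------
class Gff3ParseError(DataError):
    """Structurally invalid GFF3 (e.g. end < start)."""


class OrphanCdsError(Gff3ParseError):
    """CDS feature whose parent transcript is missing."""


class ExonOutsideGeneError(Gff3ParseError):
    """Exon not contained in its gene's span."""


# --- SAM -----------------------------------------------------------------
class SamParseError(DataError):
    """Malformed SAM record (unknown CIGAR op, bad POS, ...)."""


# --- depth TSV -----------------------------------------------------------
class DepthTsvError(DataError):
    """Malformed per-base depth table."""


# --- simulation ----------------------------------------------------------
class SimulationParameterError(ConfigError):
    """Simulation spec violates its invariants (m > p, R >= L, ...)."""


class UnreachableFractionError(SimulationParameterError):
    """Requested repeat coverage cannot be tiled with the given unit length."""


class CompartmentTooSmallError(SimulationParameterError):
    """Requested gene models do not fit in their genomic compartment."""


# --- k-mer analysis ------------------------------------------------------
class KmerParameterError(ConfigError):
    """Invalid k (even, non-positive, or mismatched between datasets)."""


# --- depth / dosage ------------------------------------------------------
class AlignmentOutOfBoundsError(DataError):
    """Alignment extends past the end of its contig."""


class ZeroFlankDepthError(DataError):
    """Flank median depth is zero; no dosage ratio can be formed."""


class EmptyUnitSetError(DataError):
    """No usable summary units (windows/CDSs) in a region or flank."""


class NoCdsError(DataError):
    """Annotation has no CDS on the requested contig."""
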