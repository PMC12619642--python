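"""Exception hierarchy shared across the package."""


class ChimeraDetectionError(Exception):
    """Base class for all airrchimera errors."""


class ParameterError(ChimeraDetectionError, ValueError):
    """A configuration value or argument is out of its allowed range."""


class ModeError(ParameterError):
    """An operation was invoked under the wrong HMM mode (DB vs BW)."""


class AlignmentError(ChimeraDetectionError, ValueError):
    """Alignment records are inconsistent (unequal lengths, mismatched ids)."""


class DatabaseTooSmallError(ChimeraDetectionError, ValueError):
    """A reference database with fewer than two alleles cannot define the HMM."""


class InvalidCharacterError(ChimeraDetectionError, ValueError):
    """A sequence contains characters outside the accepted alphabet."""


class SchemaError(ChimeraDetectionError, ValueError):
    """An AIRR table is missing required columns."""


class MalformedRecordError(ChimeraDetectionError, ValueError):
    """A single AIRR row is internally inconsistent."""


class UnknownAlleleError(ChimeraDetectionError, KeyError):
    """A query's assigned allele is absent from the reference database."""


class LatticeError(ChimeraDetectionError, ValueError):
    """Query and model disagree on lattice dimensions, or the lattice vanished."""


class EvaluationError(ChimeraDetectionError, ValueError):
    """Scoring input is degenerate (single class, mismatched lengths...)."""
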