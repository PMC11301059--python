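"""Exception hierarchy.

``EtraceInputError`` covers everything wrong with user-supplied data or
parameters; ``EtraceComputationError`` covers failures of the numerics
(e.g. a Michaelis-Menten fit that does not converge). The CLI maps the
former to exit code 1 and the latter to exit code 2.
"""


class EtraceError(Exception):
    """Base class for all package errors."""


class EtraceInputError(EtraceError):
    """Invalid input data, file, or parameter."""


class EtraceComputationError(EtraceError):
    """A computation failed (non-convergence, undefined quantity)."""


class FastaParseError(EtraceInputError):
    """Malformed FASTA input."""


class DuplicateIdError(FastaParseError):
    """Two records share an id within one collection."""


class AlignmentError(EtraceInputError):
    """Sequences violate alignment constraints (unequal lengths, <2 rows)."""


class UndefinedIdentityError(EtraceComputationError):
    """Pairwise identity undefined: no column carries a residue."""


class UnknownReferenceError(EtraceInputError):
    """A reference sequence id is not present in the alignment."""


class GroupingError(EtraceInputError):
    """Group labels missing, empty groups, or references mislabelled."""


class CompositionError(EtraceComputationError):
    """Amino-acid composition undefined or invalid for KL."""


class KineticsInputError(EtraceInputError):
    """Invalid kinetic trace or rate data."""


class FitError(EtraceComputationError):
    """Nonlinear fit failed; carries the initialization used."""

    def __init__(self, message, init=None):
        super().__init__(message)
        self.init = init


class SimulationConfigError(EtraceInputError):
    """Invalid simulator configuration; names the offending field."""
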