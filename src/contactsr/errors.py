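"""Exception hierarchy.

All package-specific failures derive from :class:`ContactSrError` so callers
(and the CLI) can distinguish data problems from genuine bugs.
"""


class ContactSrError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(ContactSrError):
    """An argument is outside its documented domain."""


class PdbError(ContactSrError):
    """A PDB file could not be interpreted as a usable Cα trace."""


class MissingChainError(PdbError):
    """The requested chain identifier is absent from the file."""


class HetatmOnlyChainError(PdbError):
    """The requested chain contains no polymer (ATOM) records."""


class TooFewResiduesError(PdbError):
    """Fewer than two Cα atoms were found for the requested chain."""


class InsertionCodeError(PdbError):
    """The chain uses residue insertion codes, which are not supported."""


class FeatureTableError(ContactSrError):
    """A feature table is malformed or references unknown residues."""


class RRFormatError(ContactSrError):
    """A CASP-RR contact file line could not be parsed or validated."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class InfeasibleBoundsError(ContactSrError):
    """Distance bounds are triangle-inconsistent (lower exceeds smoothed upper)."""


class NumericalError(ContactSrError):
    """A numerical routine produced non-finite values."""


class ShortfallError(ContactSrError):
    """A strategy bin holds fewer contacts than the requested selection size."""

    def __init__(self, strategy: str, available: int, requested: int):
        super().__init__(
            f"strategy {strategy!r}: bin holds {available} contacts but "
            f"{requested} were requested (deficit {requested - available})"
        )
        self.strategy = strategy
        self.available = available
        self.requested = requested


class CandidateExhaustionError(ContactSrError):
    """Not enough non-native residue pairs exist to inject the requested noise."""


class DegenerateSplitError(ContactSrError):
    """A feature column does not split observations into two non-empty groups."""


class GenerationError(ContactSrError):
    """A synthetic fixture could not be generated within its retry budget."""
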