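"""Exception types shared across the package."""


class CysligandError(Exception):
    """Base class for package-specific errors."""


class FormatError(CysligandError):
    """A required column or field is missing or malformed in an input file."""


class UnresolvedReferenceError(CysligandError):
    """Record table refers to protein uids absent from the sequence file."""

    def __init__(self, uids):
        self.uids = sorted(set(uids))
        super().__init__(f"records reference uids missing from FASTA: {self.uids}")


class PositionBoundsError(CysligandError):
    """A site position falls outside [1, len(sequence)] or is not a Cys."""


class CapabilityError(CysligandError):
    """An optional backend (e.g. a real language-model adapter) is unavailable."""


class ContractError(CysligandError):
    """Caller violated an interface contract (dimension/site-set mismatch...)."""


class DegenerateDataError(CysligandError):
    """Training or metric input lacks both classes or is otherwise degenerate."""
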