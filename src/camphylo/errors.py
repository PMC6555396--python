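"""Exception hierarchy shared across the package.

Everything raised deliberately derives from :class:`CamError` so the CLI can
distinguish usage/data problems (clean nonzero exit) from genuine bugs.
"""


class CamError(Exception):
    """Base class for all errors raised by camphylo."""


class EmptySequenceError(CamError):
    """A record's sequence is empty after normalization."""


class SequenceTooShortError(CamError):
    """A sequence shorter than one codon was passed to an extractor."""


class EmptySpeciesError(CamError):
    """No usable gene records remain for a species."""


class ProfileError(CamError):
    """A species profile violates a precondition (empty motif set, ...)."""


class ConfigurationError(CamError):
    """Invalid configuration value (mode mismatch, unknown code table, ...)."""


class MatrixParseError(CamError):
    """A distance-matrix file could not be parsed.

    Carries a 1-based ``line`` attribute when the offending line is known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class NewickParseError(CamError):
    """A Newick string could not be parsed."""


class InsufficientOverlapError(CamError):
    """Two trees share too few leaves to be compared."""
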