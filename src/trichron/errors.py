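"""Exception hierarchy.

All package errors derive from :class:`TrichronError` so callers can catch
one base class; the leaf classes map onto the failure modes of the
individual analysis stages (bad files, invalid series, degenerate spectra,
missing configuration).
"""


class TrichronError(Exception):
    """Base class for all errors raised by trichron."""


class FormatError(TrichronError):
    """A file is structurally malformed (e.g. a required column is missing)."""


class ValidationError(TrichronError):
    """Data violate a domain invariant (non-positive width, non-finite value)."""


class EmptyInputError(TrichronError):
    """An input file or collection contains no records."""


class LengthError(TrichronError):
    """A series is too short for the requested operation."""


class BandError(TrichronError):
    """A frequency band does not overlap the spectrum grid."""


class DegenerateSpectrumError(TrichronError):
    """A band-variance ratio is undefined because the denominator band is empty."""


class DomainError(TrichronError):
    """A scalar argument is outside its mathematical domain."""


class ConfigurationError(TrichronError):
    """The run configuration is inconsistent or incomplete."""


class SampleSizeError(TrichronError):
    """A statistical comparison was requested with too few values per group."""
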