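"""Exception hierarchy shared across the package.

Every error raised by validation names the offending record (accession,
sample, row index) so that failures in large tables are actionable.
"""


class SpecountError(Exception):
    """Base class for all package errors."""


class ParseError(SpecountError):
    """A file could not be parsed into the expected table shape/types."""


class ValidationError(SpecountError):
    """A parsed table violates a domain invariant."""


class ConfigError(SpecountError):
    """A simulation or pipeline configuration is invalid."""


class DegenerateModelError(SpecountError):
    """A statistical model is non-identifiable on the given data
    (e.g. zero events, constant covariate, perfect separation)."""
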