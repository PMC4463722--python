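"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: data problems exit 3, infeasible
configurations exit 4.
"""


class ToxknnError(Exception):
    """Base class for all package-specific errors."""


class DataFormatError(ToxknnError):
    """A file or table does not conform to the expected schema."""


class DataValidationError(ToxknnError):
    """Values violate a domain invariant (non-positive dose, duplicate id, ...)."""


class ConfigurationError(ToxknnError):
    """A requested computation is infeasible (k too large, bad simulation config, ...)."""
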