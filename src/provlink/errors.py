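"""Exception hierarchy shared across the pipeline.

Exit-code mapping in the CLI: :class:`ConfigurationError` and
:class:`InputError` -> 2 (bad input/config), everything else -> 1.
"""


class ProvlinkError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ProvlinkError):
    """Invalid configuration value (unknown provider type, bad threshold, ...)."""


class FormatError(ProvlinkError):
    """A file does not conform to its expected dialect (e.g. missing column)."""


class InputError(ProvlinkError):
    """Inputs are mutually inconsistent (e.g. truth/prediction cohort mismatch)."""


class MergeError(ProvlinkError):
    """A merged output record violated an output invariant."""


class UndefinedMetricError(ProvlinkError, ZeroDivisionError):
    """A ratio metric was requested with a zero denominator."""
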