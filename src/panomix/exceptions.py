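"""Exception hierarchy.

Readers raise :class:`FormatError` on malformed input instead of silently
coercing; :class:`ConfigError` names the offending configuration key;
:class:`AnalysisError` signals a statistical routine that cannot produce a
valid answer (constant covariate, empty group, non-convergence).
"""


class PanomixError(Exception):
    """Base class for all package errors."""


class FormatError(PanomixError):
    """A file or table violates its format contract."""


class ConfigError(PanomixError):
    """Invalid or unknown configuration."""


class AnalysisError(PanomixError):
    """A statistical operation received degenerate input or failed."""
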