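"""Exception hierarchy shared across the toolkit.

All user-facing failures derive from :class:`ReporterScoreError` so the CLI
can map them to exit status 2 without catching unrelated bugs.
"""


class ReporterScoreError(ValueError):
    """Base class for validation and configuration errors."""


class ValidationError(ReporterScoreError):
    """Input data violates a documented precondition."""


class ConfigError(ReporterScoreError):
    """Unknown method name, infeasible parameter, or conflicting options."""


class ParseError(ReporterScoreError):
    """A file could not be parsed; message names the offending line."""
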