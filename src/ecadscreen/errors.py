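"""Exception hierarchy for the screen pipeline.

Everything user-facing derives from :class:`ScreenError` so the CLI can map
validation failures to exit code 2.
"""


class ScreenError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(ScreenError):
    """Invalid or inconsistent configuration."""


class ParseError(ScreenError):
    """Malformed on-disk artifact (well table, layout, sequences)."""


class LayoutError(ScreenError):
    """Plate layout violates its declared structure."""


class ValidationError(ScreenError):
    """Input data violates a pipeline precondition."""


class DegenerateInputError(ScreenError):
    """Statistically degenerate input (e.g. zero MAD or zero SD)."""
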