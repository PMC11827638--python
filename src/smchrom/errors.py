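"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError``/``PipelineError`` to 3.
"""


class SmchromError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SmchromError):
    """Invalid or inconsistent run configuration."""


class DataError(SmchromError):
    """Input data missing, malformed, or insufficient for an operation."""


class SchemaError(DataError):
    """A table is missing required columns."""

    def __init__(self, source, missing):
        self.source = str(source)
        self.missing = sorted(missing)
        super().__init__(
            f"{self.source}: missing required column(s): {', '.join(self.missing)}"
        )


class PipelineError(SmchromError):
    """A pipeline stage cannot run because an upstream product is absent."""
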