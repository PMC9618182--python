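"""Exception hierarchy shared across the pipeline.

``ConfigError`` marks bad user configuration (exit code 2 in the CLI);
everything else derives from ``SynprotError`` (exit code 1).
"""


class SynprotError(Exception):
    """Base class for all package errors."""


class ConfigError(SynprotError):
    """Invalid configuration: bad thresholds, fractions, designs, paths."""


class SchemaError(SynprotError):
    """An input table does not match the expected schema."""


class PlacementError(SynprotError):
    """Synthetic puncta could not be placed in the requested volume."""
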