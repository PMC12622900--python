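"""Exception hierarchy for the conet pipeline."""


class ConetError(Exception):
    """Base class for all conet errors."""


class FormatError(ConetError):
    """An input file violates the expected dialect (missing columns,
    duplicate keys, malformed identifiers, empty tables)."""


class ConfigError(ConetError):
    """A run configuration is internally inconsistent (no control group,
    thresholds out of order, infeasible simulation parameters)."""
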