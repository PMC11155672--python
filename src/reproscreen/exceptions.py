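"""Exception hierarchy for reproscreen."""


class ReproscreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ReproscreenError, ValueError):
    """A configuration value is missing, out of range, or inconsistent."""


class InvalidRecordError(ReproscreenError, ValueError):
    """An input record violates a structural invariant (e.g. counts)."""


class DegenerateGroupError(ReproscreenError, ValueError):
    """A statistical group is degenerate (zero spread) where spread is required."""
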