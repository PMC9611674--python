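"""Exception hierarchy for the cooltwin runtime."""


class TwinError(Exception):
    """Base class for all cooltwin errors."""


class TopicNameError(TwinError):
    """Topic name does not match ``[A-Za-z0-9_]+``."""


class CodecError(TwinError):
    """Message cannot be (de)serialized to the JSON wire format."""


class SchemaError(CodecError):
    """Well-formed JSON missing a required envelope field."""


class RangeError(TwinError):
    """Offset or horizon outside the valid range."""


class ConfigError(TwinError):
    """Invalid cargo-type configuration document."""


class WiringError(TwinError):
    """Model chain cannot be connected (broken topic chain, missing input)."""


class StabilityError(TwinError):
    """Explicit Euler step would be unstable (dt * k_M >= 1)."""


class IdentifiabilityError(TwinError):
    """No thermal excitation: T_Box tracks T_Supply, k_M not identifiable."""


class DataOutageError(TwinError):
    """Sensor gap exceeds the maximum number of fill-forward ticks."""


class QueryError(TwinError):
    """Malformed prediction query (e.g. missing arrival time)."""


class ScenarioError(TwinError):
    """Scenario specification violates its invariants."""
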