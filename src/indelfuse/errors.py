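"""Exception hierarchy shared across indelfuse modules."""


class IndelFuseError(Exception):
    """Base class for all indelfuse errors."""


class ConfigError(IndelFuseError):
    """Invalid configuration: unknown vocabulary value, bad grid, bad attribute."""


class CapacityError(IndelFuseError):
    """A simulation plan does not fit into the target genome without overlap."""


class CoordinateError(IndelFuseError):
    """A variant or call lies outside its chromosome, or chromosomes differ."""


class OverlapError(IndelFuseError):
    """Two variant footprints overlap where disjointness is required."""


class ParseError(IndelFuseError):
    """A malformed input record; carries the offending line/record context."""


class TrainingError(IndelFuseError):
    """Model training cannot proceed (empty truth, missing class, <2 callers)."""


class InputError(IndelFuseError):
    """A required input (caller named in a rule, file) is missing."""
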