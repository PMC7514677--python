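"""Exception hierarchy shared by all analysis stages."""


class GrpSpaceError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GrpSpaceError, ValueError):
    """Invalid simulation or pipeline configuration."""


class FormatError(GrpSpaceError, ValueError):
    """Malformed input file (expression TSV, annotation, MI container)."""


class ContractError(GrpSpaceError, ValueError):
    """Violation of an inter-stage contract (misaligned inputs, bad shapes)."""


class UndefinedIndicatorError(GrpSpaceError, ValueError):
    """A change indicator is undefined for the given input (e.g. empty deltas)."""
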