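"""Exception hierarchy for csdscope."""


class CsdScopeError(Exception):
    """Base class for all csdscope errors."""


class FormatError(CsdScopeError):
    """A file could not be parsed as a valid recording."""


class RoleMappingError(FormatError):
    """Channel labels could not be resolved to electrode roles."""


class FilterError(CsdScopeError):
    """Invalid filter specification for the given sampling rate."""


class QualityError(CsdScopeError):
    """Input signal fails a quality precondition (flat / DC-dominated)."""


class ChannelQualityError(QualityError):
    """A recording channel is unusable; the subject should be excluded."""


class UndefinedSpeedError(CsdScopeError):
    """Propagation speed cannot be computed (missing events or zero lag)."""


class UndefinedSeverityError(CsdScopeError):
    """Severity ratio undefined (zero power in the reference window)."""


class DegenerateDataError(CsdScopeError):
    """A statistical test received degenerate input (e.g. zero variance)."""
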