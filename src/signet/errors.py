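"""Exception hierarchy shared across the package."""


class SignetError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SignetError):
    """A network or link record violates a structural invariant."""


class DanglingEndpointError(ValidationError):
    """A link refers to a symbol that is not a declared node."""


class DuplicateNodeError(ValidationError):
    """Two nodes share the same symbol."""


class SelfLoopError(ValidationError):
    """A link connects a node to itself and self-loops are not permitted."""


class UnknownLinkTypeError(ValidationError):
    """A link type name outside {interaction, stimulation, inhibition}."""


class FormatError(SignetError):
    """A file could not be parsed in the expected interchange format."""


class ParameterError(SignetError, ValueError):
    """A numeric parameter is outside its valid range."""


class UnmeasuredGeneError(SignetError):
    """A gene required for scoring has no expression values."""


class UndefinedMetricsError(SignetError):
    """Path metrics are undefined (edgeless graph)."""


class NoScorableLinksError(SignetError):
    """No link has both endpoints measured; condensation is impossible."""


class DuplicateLinkWarning(UserWarning):
    """Exact-duplicate link records were merged during network assembly."""
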