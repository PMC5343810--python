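"""Exception hierarchy shared across the package."""


class MirgrnError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MirgrnError):
    """A file could not be parsed; the message names the offending line."""


class NormalizationError(MirgrnError):
    """An identifier could not be normalized to the package namespace."""


class EvidenceClassError(MirgrnError):
    """A target table carried the wrong evidence class for an operation."""


class MembershipError(MirgrnError):
    """A node referenced by an operation is not part of the network."""


class ConsistencyError(MirgrnError):
    """A container invariant (disjoint namespaces, partition coverage, ...) was violated."""


class ParameterError(MirgrnError, ValueError):
    """An operation received an out-of-range or unknown parameter."""


class PipelineError(MirgrnError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
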