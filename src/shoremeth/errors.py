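"""Exception types shared across the package."""


class ShoremethError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ShoremethError):
    """Invalid simulation or pipeline configuration."""


class ParseError(ShoremethError):
    """Malformed input file.

    Carries the offending line number (1-based, counting the header)
    when known.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)


class InsufficientPanelError(ShoremethError):
    """Fewer than the minimum number of evaluable microsatellite markers."""


class MissingControlError(ShoremethError):
    """A qPCR control quantity required for normalization is absent or zero."""


class LowIdentityError(ShoremethError):
    """Clone alignment identity below the hard non-target floor."""

    def __init__(self, identity: float, floor: float):
        self.identity = identity
        self.floor = floor
        super().__init__(
            f"alignment identity {identity:.3f} below non-target floor {floor:.3f}"
        )


class DegenerateTableError(ShoremethError):
    """Contingency table with a zero margin; test not computable."""


class PipelineError(ShoremethError):
    """A pipeline stage failed; names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
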