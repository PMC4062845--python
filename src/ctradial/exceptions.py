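"""Exception types shared across the pipeline."""


class CTRadialError(Exception):
    """Base class for all package-specific errors."""


class DegenerateMaskError(CTRadialError, ValueError):
    """A mask is empty or too small for the requested operation."""


class EmptySignalError(CTRadialError, ValueError):
    """Total probe or DAPI signal inside a nucleus is zero."""


class DegenerateShellError(CTRadialError, ValueError):
    """A shell has zero DAPI signal but non-zero probe signal."""


class InsufficientDataError(CTRadialError, ValueError):
    """Too few observations for the requested statistical test."""
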