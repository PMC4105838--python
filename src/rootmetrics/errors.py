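"""Exception hierarchy shared by all rootmetrics modules."""


class RootmetricsError(Exception):
    """Base class for all package errors."""


class ParameterError(RootmetricsError, ValueError):
    """A parameter is out of its documented range."""


class DimensionError(RootmetricsError, ValueError):
    """Array shapes or grids do not match."""


class ChannelError(RootmetricsError, ValueError):
    """Requested colour channel is unavailable for this image."""


class InvariantError(RootmetricsError, ValueError):
    """A documented data-model invariant is violated."""


class DegenerateInputError(RootmetricsError, ValueError):
    """Input is formally valid but carries no usable signal (e.g. constant image)."""


class MarkupParseError(RootmetricsError, ValueError):
    """Root markup document is not well-formed XML."""


class MarkupSchemaError(RootmetricsError, ValueError):
    """Root markup document is well-formed but violates the schema."""


class PairingError(RootmetricsError, ValueError):
    """Left/right image files could not be paired."""


class MissingCellError(RootmetricsError, ValueError):
    """A factorial table required to be complete has missing cells."""
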