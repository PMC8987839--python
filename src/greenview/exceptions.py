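"""Exception hierarchy for the greenview pipeline.

Every error raised by the library derives from :class:`GreenviewError` so
callers (and the CLI) can catch pipeline failures without masking genuine
bugs such as ``TypeError``.
"""


class GreenviewError(ValueError):
    """Base class for all greenview pipeline errors."""


class SceneSpecError(GreenviewError):
    """A synthetic scene specification is invalid (e.g. region off-canvas)."""


class AnnotationError(GreenviewError):
    """A rectangle annotation is inconsistent with its source image."""


class GenerationError(GreenviewError):
    """Rejection sampling could not satisfy an annotation request."""


class PairingError(GreenviewError):
    """Prediction/reference grids could not be paired for evaluation."""


class InputError(GreenviewError):
    """An operation received structurally invalid input."""
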