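"""Exception hierarchy for vertrom.

All package errors derive from :class:`VertromError` so callers can catch
one base class at pipeline boundaries.
"""


class VertromError(Exception):
    """Base class for all vertrom errors."""


class LoadError(VertromError):
    """A mesh or manifest file is missing or unparseable."""


class MeshValidationError(VertromError):
    """A mesh violates a structural invariant (empty, non-finite, ...)."""


class VocabularyError(VertromError):
    """A part name is outside the controlled anatomical vocabulary."""


class ParameterError(VertromError):
    """Invalid generator or search parameters."""


class PoseError(VertromError):
    """A chain pose cannot be constructed (degenerate frames/landmarks)."""


class LandmarkError(VertromError):
    """Required landmarks are missing or coincident."""


class ReductionError(VertromError):
    """Intervertebral spacing reduction failed to converge."""


class ContactRuleError(VertromError):
    """A contact rule excludes every candidate part pair."""


class SampleError(VertromError):
    """An angle sample is empty or otherwise unusable."""


class StatTestError(VertromError):
    """A statistical test precondition is violated (e.g. group size < 2)."""
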