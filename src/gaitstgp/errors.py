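"""Package-specific exception types."""


class GaitError(RuntimeError):
    """Base class for pipeline failures."""


class GenerationError(GaitError):
    """Synthetic trial could not be realized under the sampled parameters."""


class SegmentationError(GaitError):
    """Gait events or stride windows could not be identified."""


class FormatError(GaitError):
    """Input data violates an assumed sampling or layout convention."""
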