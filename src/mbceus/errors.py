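"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A model or acquisition parameter violates its constraints."""


class MaskError(ValueError):
    """A region-of-interest mask is empty, out of bounds, or inconsistent."""


class FlashDetectionError(RuntimeError):
    """No destructive high-MI flash could be located in a cine loop."""


class WindowError(ValueError):
    """A quantification window contains no frames."""


class StudyDataError(RuntimeError):
    """A cohort record expected by the study pipeline is missing."""
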