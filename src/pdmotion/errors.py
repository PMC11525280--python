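"""Exception hierarchy for pdmotion."""


class PdMotionError(Exception):
    """Base class for all pdmotion errors."""


class FormatError(PdMotionError):
    """On-disk session layout is malformed (missing manifest, absent files)."""


class ValidationError(PdMotionError):
    """A stream or session violates its invariants (non-monotone time,
    NaN rows, missing required streams)."""


class SegmentationError(PdMotionError):
    """A recording cannot be windowed or segmented (e.g. < 2 marker events)."""


class ConfigError(PdMotionError):
    """Run configuration is invalid (unknown keys, bad values)."""
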