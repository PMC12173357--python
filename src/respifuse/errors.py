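"""Exception hierarchy for the respifuse pipeline.

Stage failures inside :func:`respifuse.pipeline.run_pipeline` are caught and
converted to per-window quality flags; these exceptions abort only when an
operation is called directly with invalid input.
"""


class RespifuseError(Exception):
    """Base class for all respifuse errors."""


class ChannelLabelError(RespifuseError):
    """A required channel (ecg/ppg) is missing or its label is ambiguous."""


class DataError(RespifuseError):
    """Input samples are non-finite or otherwise unusable."""


class ShortWindowError(RespifuseError):
    """Window too short for stable filtering or spectral analysis."""


class NoBeatsError(RespifuseError):
    """No heartbeats (R-peaks or PPG troughs) could be located."""


class InsufficientBeatsError(RespifuseError):
    """Fewer usable beats than the minimum required for a beat series."""


class DegenerateSignalError(RespifuseError):
    """Signal has no usable spectral content (e.g. all-constant input)."""


class ConfigurationError(RespifuseError):
    """Invalid pipeline or generator configuration."""
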