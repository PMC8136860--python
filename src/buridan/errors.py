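"""Exception types raised across the pipeline."""


class BuridanError(Exception):
    """Base class for all package errors."""


class ConfigError(BuridanError):
    """Invalid simulation or pipeline configuration."""


class MalformedTrajectoryError(BuridanError):
    """Trajectory data violates its contract (non-increasing time, NaN, overlap)."""


class NoValidFramesError(BuridanError):
    """A per-fly metric has no retained frames (all jumps, or no moving frames)."""


class MalformedRecordError(BuridanError):
    """A proboscis-extension record has the wrong stimulus count or order."""


class DesignError(BuridanError):
    """A statistical design is missing a required group or cell."""
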