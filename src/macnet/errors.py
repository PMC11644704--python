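"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """An invalid configuration field; the message names the field."""


class MontageError(ValueError):
    """A required channel is missing from the montage."""


class EpochBoundsError(ValueError):
    """An event does not leave room for a full epoch window."""


class SegmentationError(ValueError):
    """Trial length is not divisible into the requested windows."""


class TrainingDivergenceError(RuntimeError):
    """Training produced a non-finite loss; carries the epoch index."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")
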