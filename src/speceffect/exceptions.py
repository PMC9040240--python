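"""Package-specific error types."""


class DegenerateDataError(ValueError):
    """Input admits no meaningful fit (e.g. all-zero weight layer, no factor retained)."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested statistic."""


class DivergenceError(RuntimeError):
    """Network training produced non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"training diverged (non-finite loss) at epoch {epoch}")
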