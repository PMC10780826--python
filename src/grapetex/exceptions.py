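"""Exception hierarchy for grapetex."""


class GrapetexError(Exception):
    """Base class for all grapetex errors."""


class ImageFormatError(GrapetexError):
    """Raised when a file cannot be decoded as a raster image."""


class ContractError(GrapetexError):
    """Raised when an operation's input contract is violated."""


class DegenerateHistogramError(GrapetexError):
    """Raised when Otsu thresholding is attempted on a constant image.

    A constant grayscale image has a single-bin histogram; between-class
    variance is identically zero and no threshold is defined. Callers should
    supply a manual threshold instead.
    """


class EmptyPairError(GrapetexError):
    """Raised when a co-occurrence offset admits no valid pixel pair."""


class CannotSplitError(GrapetexError):
    """Raised when a dataset is too small to be split."""


class ConfigurationError(GrapetexError):
    """Raised for inconsistent network architecture configurations."""


class WeightsMissingError(GrapetexError):
    """Raised when pretrained backbone weights are not available."""


class DivergenceError(GrapetexError):
    """Raised when training produces a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite training loss at epoch {epoch}")


class CheckpointError(GrapetexError):
    """Raised when a model checkpoint cannot be loaded."""
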