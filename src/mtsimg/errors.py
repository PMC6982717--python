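"""Exception hierarchy shared across the package."""


class MtsimgError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(MtsimgError, ValueError):
    """Data handed to an operation violates its preconditions."""


class InvalidArgumentError(MtsimgError, ValueError):
    """A parameter (not the data itself) is out of its valid range."""


class FormatError(MtsimgError, ValueError):
    """A file or stream does not conform to the expected on-disk format."""


class EmptyDatasetError(FormatError):
    """A dataset source contained no instances."""


class DegenerateBinningError(InvalidInputError):
    """Quantile binning was requested with more bins than distinct values."""


class ShapeError(InvalidArgumentError):
    """Spatial dimensions are incompatible with the network's pooling plan."""


class DivergenceError(MtsimgError, RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"training loss became non-finite at epoch {epoch}")


class StratificationError(InvalidInputError):
    """A cross-validation fold ended up with single-class training data."""
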