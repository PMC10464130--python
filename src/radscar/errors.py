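"""Exception hierarchy.

Every contract violation raises a distinct, named error so callers (and the
CLI) can react per failure mode instead of pattern-matching messages.
"""


class RadscarError(Exception):
    """Base class for all package errors."""


# --- image_io ---------------------------------------------------------------

class UnsupportedDialectError(RadscarError):
    """File dialect is not one of {png16, tiff, csv-matrix}."""


class RaggedMatrixError(RadscarError):
    """csv-matrix rows have inconsistent lengths."""


class UnsupportedBitDepthError(RadscarError):
    """Raster file has a pixel type the dialect does not define."""


class MaskValueError(RadscarError):
    """Mask file contains a value other than {0, 1} (csv) or {0, 255} (png)."""


class NonFiniteValueError(RadscarError):
    """Image contains NaN or infinite pixel values."""


# --- geometry / shapes ------------------------------------------------------

class ShapeMismatchError(RadscarError):
    """Image and mask grids do not have the same shape."""


class EmptyMaskError(RadscarError):
    """Operation requires at least one true mask pixel."""


class OutOfBoundsSeedError(RadscarError):
    """Region-growing seed lies outside the image."""


class EmptyStructuringElementError(RadscarError):
    """Structuring element has no offsets."""


# --- phantom / patches ------------------------------------------------------

class PhantomSpecError(RadscarError):
    """Phantom specification violates its invariants."""


class PatchSizeError(RadscarError):
    """Patch size is non-positive or larger than the image."""


class InsufficientOriginsError(RadscarError):
    """Fewer eligible patch origins than requested.

    Attributes
    ----------
    needed, available : int
        Requested patch count and the number of origins actually usable
        under the active overlap policy.
    """

    def __init__(self, needed: int, available: int, detail: str = ""):
        self.needed = needed
        self.available = available
        msg = f"requested {needed} patches but only {available} eligible origins"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


# --- radon / features -------------------------------------------------------

class EmptyAngleSetError(RadscarError):
    """Radon transform called with no projection angles."""


class NonSquareImageError(RadscarError):
    """Radon transform input is not square."""


class NeighborCountError(RadscarError):
    """LBP code requires exactly 8 neighbors."""


class LBPCodeRangeError(RadscarError):
    """LBP code outside [0, 255]."""


class ImageTooSmallError(RadscarError):
    """LBP feature extraction needs an image of at least 3x3."""


class UnnormalizedHistogramError(RadscarError):
    """Histogram does not sum to 1 (or has negative mass)."""


class MissingLabelError(RadscarError):
    """No feature vector carries the requested class label."""


# --- classify ---------------------------------------------------------------

class ClassTooSmallError(RadscarError):
    """A class has fewer members than the number of folds."""


class UndefinedMetricError(RadscarError):
    """Sensitivity/specificity undefined because a class is empty."""


# --- pipeline ---------------------------------------------------------------

class StageError(RadscarError):
    """A pipeline stage failed; carries the stage name for exit-code mapping.

    Attributes
    ----------
    stage : str
        One of phantom, localize, patches, radon, features, dissimilarity,
        train.
    """

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
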