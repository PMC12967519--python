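"""Exception hierarchy for the trichrome quantification pipeline."""


class TrichromeError(Exception):
    """Base class for all package-specific errors."""


# --- stain model -----------------------------------------------------------

class EmptyROI(TrichromeError):
    """An ROI selected zero pixels."""


class DegenerateROI(TrichromeError):
    """An ROI's mean optical density is (numerically) the zero vector."""


class CollinearVectors(TrichromeError):
    """Two stain vectors are collinear; no orthogonal complement exists."""


class SingularBasis(TrichromeError):
    """The 3x3 stain matrix is not invertible."""


# --- segmentation ----------------------------------------------------------

class InvalidSigma(TrichromeError):
    """Gaussian blur sigma must be strictly positive."""


class EmptyRegion(TrichromeError):
    """A measurement region contains no pixels."""


class DegenerateHistogram(TrichromeError):
    """Fewer than two occupied bins: auto-thresholding is undefined."""


class DimensionMismatch(TrichromeError):
    """Two masks/images do not share the same pixel grid."""


# --- statistics ------------------------------------------------------------

class SampleTooSmall(TrichromeError):
    """Not enough observations for the requested test."""


class DegenerateSample(TrichromeError):
    """All observations identical where spread is required."""


class DegenerateVariance(TrichromeError):
    """Both groups constant and equal: the t statistic is undefined."""


class DegenerateX(TrichromeError):
    """Regressor has zero variance (or too few points) for OLS."""


class TooFewImages(TrichromeError):
    """Cohort comparison requires at least three images."""


# --- synthetic data / CLI --------------------------------------------------

class InvalidParams(TrichromeError):
    """Scene parameters outside their documented domain."""


class MissingROI(TrichromeError):
    """A required named ROI is absent from the ROI file."""


class IOFailure(TrichromeError):
    """Reading or writing a fixture/output file failed."""
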