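"""Exception types raised across the pipeline."""


class TumortexError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(TumortexError, ValueError):
    """Invalid user-supplied parameter (non-positive axes, bad level count...)."""


class AlignmentError(TumortexError, ValueError):
    """Volume/mask shape mismatch or sample-count mismatch."""


class MaskFormatError(TumortexError, ValueError):
    """Mask contains values other than {0, 1}."""


class EmptyTumorError(TumortexError, ValueError):
    """No axial slice carries enough in-mask pixels to analyse."""


class DegenerateROIError(TumortexError, ValueError):
    """An ROI admits no valid pixel pair / valid pixel for the requested operator."""


class CohortError(TumortexError, ValueError):
    """Cohort-level precondition violated (single class, too few patients)."""


class FitError(TumortexError, ValueError):
    """Classifier cannot be fit (e.g. a single class in the training data)."""


class MetricUndefinedError(TumortexError, ValueError):
    """A requested metric is undefined for the given labels (e.g. one class only)."""
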