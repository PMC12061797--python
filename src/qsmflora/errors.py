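"""Exception types raised across the pipeline."""


class HierarchyError(ValueError):
    """Branch or cylinder parent graph is cyclic or has a dangling link."""


class OrderingError(ValueError):
    """Along-shoot measurement positions are not strictly increasing."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested operation."""


class InconsistencyError(ValueError):
    """Data contradict themselves (e.g. flowers on a zero-length class)."""


class EncodingError(KeyError):
    """A categorical level is unknown to the sampling-space encoding."""


class EmptySelectionError(ValueError):
    """Subsampling was asked to select from an empty pool."""


class DegenerateFitError(ValueError):
    """Model fitting is impossible (all-zero or all-nonzero outcomes)."""


class ConvergenceError(RuntimeError):
    """Optimizer failed to converge."""


class NestingError(ValueError):
    """Likelihood-ratio test called on non-nested models."""


class SpecificationError(ValueError):
    """A requested model term or factor is absent from the fit."""


class MetricError(ValueError):
    """Tree metrics cannot be derived (e.g. tree shorter than 1.3 m)."""


class ThresholdError(ValueError):
    """A branch unit violates the diameter threshold contract."""


class AggregationError(ValueError):
    """Aggregation over an empty replicate set."""


class CorrelationError(ValueError):
    """Correlation undefined (zero-variance predictor)."""


class CIError(RuntimeError):
    """Too many bootstrap repetitions failed to produce an interval."""


class ConfigError(ValueError):
    """Pipeline configuration is invalid or references missing paths."""
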