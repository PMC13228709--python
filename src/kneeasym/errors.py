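"""Exception hierarchy for the knee-asymmetry toolkit."""


class KneeAsymError(Exception):
    """Base class for all package errors."""


class InvariantError(KneeAsymError, ValueError):
    """A domain-type invariant is violated (e.g. inverted joint-space pair)."""


class MeasurementError(KneeAsymError):
    """A landmark needed by a geometric measurement is missing or degenerate."""


class ConstructionError(KneeAsymError):
    """A landmark layout cannot realize the requested measures."""


class RenderError(KneeAsymError):
    """Requested geometry does not fit the phantom canvas."""


class DetectionError(KneeAsymError):
    """Automated landmark/leg/joint-line detection failed."""


class InsufficientDataError(KneeAsymError):
    """Too few observations for the requested statistic."""


class SchemaError(KneeAsymError):
    """An input table does not conform to the documented column schema."""


class ConfigError(KneeAsymError):
    """Inconsistent or invalid run/simulation configuration."""


class ZeroCellError(KneeAsymError):
    """A 2x2 contingency table has an empty cell; OR/CI undefined without correction."""


class ModelError(KneeAsymError):
    """A statistical model could not be fitted (e.g. singular design)."""
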