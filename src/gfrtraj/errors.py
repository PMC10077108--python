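"""Exception hierarchy for gfrtraj."""


class GfrtrajError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GfrtrajError):
    """A simulation or pipeline configuration is invalid."""


class ParameterizationError(ConfigurationError):
    """A variance parameter is outside its admissible set (e.g. non-PSD G)."""


class SchemaError(GfrtrajError):
    """An input table is missing required columns or has wrong types."""


class IntegrityError(GfrtrajError):
    """Cross-table consistency is violated (unknown subject, duplicate visit)."""


class SingularDesignError(GfrtrajError):
    """The fixed-effect design matrix is rank deficient."""


class DegeneratePredictorError(GfrtrajError):
    """A predictor has zero variance where a scale is required."""


class NumericalError(GfrtrajError):
    """A quantity is undefined or non-finite (zero variance ratio, bad likelihood)."""
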