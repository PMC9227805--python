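"""Exception hierarchy for the glycoload pipeline.

Validation failures raise early and name the offending record; the
alternative (silent imputation) is exactly what dietary-GI pipelines must
avoid, because an unresolved GI propagates as a biased daily metric.
"""


class GlycoloadError(Exception):
    """Base class for all package errors."""


class InvalidCompositionError(GlycoloadError):
    """Negative carbohydrate or fiber content in a food record."""


class UnresolvedGIError(GlycoloadError):
    """A food exhausted every GI resolution path (table, zero-class, similar food)."""

    def __init__(self, food_id: str):
        self.food_id = food_id
        super().__init__(
            f"no GI resolution path for food {food_id!r}: "
            "no table entry, no zero-GI class, no similar-food reference"
        )


class FoodTableError(GlycoloadError):
    """Structural problem in a food composition table (schema, ranges, chained references)."""


class SchemaError(GlycoloadError):
    """Input file does not match the documented column layout."""


class DegenerateStandardizationError(GlycoloadError):
    """Standardization requested on a (weighted) constant column."""


class SingularDesignError(GlycoloadError):
    """Design matrix is rank deficient; names the collinear columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; collinear columns: {self.columns}")


class LonelyPSUError(GlycoloadError):
    """A sampling stratum contains a single PSU, so its variance contribution is undefined."""

    def __init__(self, strata):
        self.strata = list(strata)
        super().__init__(
            f"strata with a single PSU: {self.strata}; "
            "use lonely_psu='merge' to merge them into an adjacent stratum"
        )
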