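"""Exception hierarchy for physep.

Degenerate statistical inputs (constant vectors, zero residual variance,
rank-deficient designs) raise explicit errors rather than returning NaN
sentinels, so that a silent numerical problem cannot propagate into a
reported correlation or p value.
"""


class PhysepError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PhysepError):
    """A cohort configuration is internally inconsistent."""


class TrialTableError(PhysepError):
    """A trial table violates its schema or schedule contract."""


class IncompleteDataError(TrialTableError):
    """A participant is missing scheduled primary units for a task."""


class UndefinedCorrelationError(PhysepError):
    """A correlation was requested on constant or too-short input."""


class AICUndefinedError(PhysepError):
    """AIC requested for a saturated fit (zero residual sum of squares)."""


class NonNestedModelsError(PhysepError):
    """A nested-model comparison was requested for non-nested fits."""


class BookkeepingError(PhysepError):
    """Exclusion counts are inconsistent with the number of completers."""
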