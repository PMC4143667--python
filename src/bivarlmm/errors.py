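"""Exception hierarchy for bivarlmm."""


class BivarlmmError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(BivarlmmError, ValueError):
    """A supplied parameter violates its documented domain."""


class UndefinedFrequencyError(BivarlmmError, ValueError):
    """Allele frequency requested for a SNP with no called genotypes."""


class EmptyResultError(BivarlmmError, ValueError):
    """An operation removed every row/column it was given.

    Carries the partial report (if any) on the ``report`` attribute so the
    caller can inspect why everything was filtered out.
    """

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


class EmptyDesignError(BivarlmmError, ValueError):
    """No usable subject remained after assembling the model design."""


class RankDeficiencyError(BivarlmmError, ValueError):
    """The fixed-effect design is collinear; lists aliased columns."""

    def __init__(self, message, aliased=()):
        super().__init__(message)
        self.aliased = tuple(aliased)


class DegenerateCovarianceError(BivarlmmError, ValueError):
    """A marginal covariance matrix is not positive definite."""


class SingularCovarianceError(BivarlmmError, ValueError):
    """Wald-test covariance is singular (SNP collinear with covariates)."""


class IncomparableModelsError(BivarlmmError, ValueError):
    """AIC comparison requested across fits on different responses."""


class OverParameterizedDesignError(BivarlmmError, ValueError):
    """Denominator degrees of freedom would be non-positive."""
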