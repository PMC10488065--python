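"""Exception types shared across the package."""


class TwamatchError(Exception):
    """Base class for all package-specific errors."""


class TraceValidationError(TwamatchError):
    """A vital-sign trace violates its contract (empty, non-uniform spacing,
    mismatched lengths, out-of-range pressures)."""


class AlarmSeriesMissingError(TwamatchError):
    """An alarm-index operation was requested on a trace that carries no
    index channel; distinct from an index that never alarms."""


class DegenerateCohortError(TwamatchError):
    """Simulated group assignment produced an empty treated or control arm."""


class MissingDataError(TwamatchError):
    """Covariate matrix contains missing values; the analysis excludes
    incomplete cases rather than imputing."""


class PerfectSeparationError(TwamatchError):
    """The logistic likelihood is unbounded because some covariate
    combination perfectly predicts treatment."""

    def __init__(self, covariates):
        self.covariates = list(covariates)
        super().__init__(
            "perfect separation detected; separating covariate set: "
            + ", ".join(self.covariates)
        )


class RankDeficientError(TwamatchError):
    """The design matrix is rank deficient (collinear columns)."""

    def __init__(self, covariates):
        self.covariates = list(covariates)
        super().__init__(
            "rank-deficient design; collinear columns: " + ", ".join(self.covariates)
        )
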