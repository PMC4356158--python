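"""Adaptability regressions on standardized points.

Declining adaptability appears as a log-log-linear relationship between the
excess fitness gain y and the initial deficit x of each genotype:

    ln y_i = a + b * ln(-x_i)        (log-log form; beta = |b|)

with an exponential alternative fitted for model comparison:

    ln y_i = a + b * x_i             (y = A * e^(b x))

Both are ordinary least squares on natural logs.  Points that cannot enter a
fit — the reference at x = 0, or genotypes with non-positive excess gain —
are excluded explicitly and logged with a reason; silent dropping is
forbidden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .errors import InsufficientDataError
from .standardization import StandardizedPoint

MIN_POINTS = 3


@dataclass(frozen=True)
class RegressionResult:
    """One fitted adaptability regression with its exclusion log.

    ``beta`` is the magnitude of the log-log slope (the paper-facing
    adaptability exponent); ``r`` the signed correlation coefficient and
    ``r_squared`` the coefficient of determination (r_squared = r**2 for
    these simple linear fits); ``f_pvalue`` the p-value of the regression
    F-test.
    """

    model_form: str
    slope: float
    intercept: float
    beta: float
    r: float
    r_squared: float
    f_pvalue: float
    n_used: int
    excluded: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "model_form": self.model_form,
            "slope": self.slope,
            "intercept": self.intercept,
            "beta": self.beta,
            "r": self.r,
            "r_squared": self.r_squared,
            "f_pvalue": self.f_pvalue,
            "n_used": self.n_used,
            "excluded": [list(e) for e in self.excluded],
        }


@dataclass(frozen=True)
class FitComparison:
    """Log-log versus exponential fit on the same points, ranked by r^2."""

    loglog: RegressionResult
    exponential: RegressionResult
    preferred: str
    tie: bool = False


def _ols(X: np.ndarray, Y: np.ndarray, model_form: str, excluded) -> RegressionResult:
    fit = sm.OLS(Y, sm.add_constant(X)).fit()
    slope = float(fit.params[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = float(fit.rsquared)
    if not math.isfinite(r2):
        r2 = 0.0  # constant response: explained variance undefined, take 0
    return RegressionResult(
        model_form=model_form,
        slope=slope,
        intercept=float(fit.params[0]),
        beta=abs(slope),
        r=math.copysign(math.sqrt(max(r2, 0.0)), slope) if slope != 0 else 0.0,
        r_squared=r2,
        f_pvalue=float(fit.f_pvalue),
        n_used=len(Y),
        excluded=tuple(excluded),
    )


def fit_loglog(points: list[StandardizedPoint]) -> RegressionResult:
    """OLS of ln(y) on ln(-x) over points with x < 0 and y > 0."""
    eligible, excluded = [], []
    for p in points:
        if p.x == 0:
            excluded.append((p.genotype_id, "reference point (x = 0)"))
        elif p.x > 0:
            excluded.append((p.genotype_id, "positive initial deficit (x > 0)"))
        elif p.y <= 0:
            excluded.append((p.genotype_id, "non-positive excess gain (y <= 0)"))
        else:
            eligible.append(p)
    if len(eligible) < MIN_POINTS:
        raise InsufficientDataError(
            f"log-log fit needs >= {MIN_POINTS} points with x < 0 and y > 0, "
            f"got {len(eligible)} (excluded {len(excluded)})"
        )
    X = np.log([-p.x for p in eligible])
    Y = np.log([p.y for p in eligible])
    return _ols(X, Y, "loglog", excluded)


def fit_exponential(points: list[StandardizedPoint]) -> RegressionResult:
    """OLS of ln(y) on x over points with y > 0 (y = A * e^(b x))."""
    eligible, excluded = [], []
    for p in points:
        if p.y <= 0:
            excluded.append((p.genotype_id, "non-positive excess gain (y <= 0)"))
        else:
            eligible.append(p)
    if len(eligible) < MIN_POINTS:
        raise InsufficientDataError(
            f"exponential fit needs >= {MIN_POINTS} points with y > 0, "
            f"got {len(eligible)} (excluded {len(excluded)})"
        )
    X = np.array([p.x for p in eligible])
    Y = np.log([p.y for p in eligible])
    return _ols(X, Y, "exponential", excluded)


def compare_fits(points: list[StandardizedPoint]) -> FitComparison:
    """Fit both forms and pick the winner by r^2 (ties flagged, toward log-log)."""
    ll = fit_loglog(points)
    ex = fit_exponential(points)
    tie = math.isclose(ll.r_squared, ex.r_squared, rel_tol=1e-12, abs_tol=1e-12)
    preferred = "loglog" if (tie or ll.r_squared > ex.r_squared) else "exponential"
    return FitComparison(loglog=ll, exponential=ex, preferred=preferred, tie=tie)
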