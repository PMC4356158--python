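"""Fitness-trajectory extrapolation from a fitted adaptability exponent.

If the log-log-linear relationship between per-interval gain and current
deficit holds with slope magnitude beta, the gain in each successive time
interval shrinks geometrically by a factor (1 - beta), so the cumulative
log-fitness gain after t intervals is a geometric partial sum:

    ln(w_t / w_0) = ln(w_1 / w_0) * (1 - (1 - beta)^t) / beta

which converges (for beta in (0, 2), where |1 - beta| < 1) to the fitness
plateau ln(w_1 / w_0) / beta.  Convergence is monotone for beta in (0, 1)
and oscillating for beta in (1, 2).  Time t counts abstract fitting
intervals, not necessarily single generations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError


def _check_beta(beta: float) -> None:
    if not 0 < beta < 2:
        raise DomainError(
            f"beta must be in (0, 2) for the gain series to converge, got {beta}"
        )


def forecast(beta: float, first_gain: float, t) -> float | np.ndarray:
    """Cumulative log-fitness gain ln(w_t/w_0) after t time steps.

    ``t`` may be a non-negative integer or an array of them.  At t = 1 the
    forecast equals ``first_gain`` for every beta; as t grows it approaches
    :func:`plateau` (small-beta evaluation uses expm1/log1p to avoid
    cancellation).
    """
    _check_beta(beta)
    t_arr = np.asarray(t)
    if np.any(t_arr < 0):
        raise DomainError(f"t must be >= 0, got {t}")
    if beta == 1.0:
        out = np.where(t_arr == 0, 0.0, first_gain)
    elif beta < 1.0:
        out = first_gain * -np.expm1(t_arr * np.log1p(-beta)) / beta
    else:
        out = first_gain * (1.0 - (1.0 - beta) ** t_arr) / beta
    return float(out) if np.isscalar(t) else out


def plateau(beta: float, first_gain: float) -> float:
    """The t -> infinity limit of :func:`forecast`: first_gain / beta."""
    _check_beta(beta)
    return first_gain / beta


@dataclass(frozen=True)
class TrajectoryForecast:
    """A forecast curve over an integer horizon plus its plateau."""

    beta: float
    first_gain: float
    horizon: int
    t: np.ndarray
    cumulative_gain: np.ndarray
    plateau: float

    @classmethod
    def compute(cls, beta: float, first_gain: float, horizon: int) -> "TrajectoryForecast":
        if horizon < 1:
            raise DomainError(f"horizon must be >= 1, got {horizon}")
        t = np.arange(horizon + 1)
        return cls(
            beta=beta,
            first_gain=first_gain,
            horizon=horizon,
            t=t,
            cumulative_gain=forecast(beta, first_gain, t),
            plateau=plateau(beta, first_gain),
        )
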