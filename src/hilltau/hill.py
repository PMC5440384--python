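"""Closed-form and differential forms of the logistic and generalized Hill
(log-logistic) time-response models.

The central object is the Hill survival law

    S(t) = 1 / [1 + (t/tau)**theta],

the survivor function of a log-logistic distribution with scale ``tau`` (the
median response time) and shape ``theta`` (sigmoid steepness).  The same curve
arises as the solution of a generalized autocatalytic rate law

    d(alpha)/dt = k * alpha**(1 - 1/theta) * (1 - alpha)**(1 + 1/theta),

which interpolates between the logistic (Prout–Tompkins) equation
(theta -> inf) and second-order kinetics (theta = 1).  The integration
constant ``t_o`` of the explicit solution is the median time (conversion is
exactly one half at ``t = t_o``); choosing ``t_o = theta / k`` pins the
conversion to zero at ``t = 0`` and collapses the solution onto the Hill
form with ``tau = theta / k``.

All evaluators accept scalars or NumPy arrays for the time argument and are
computed through numerically stable log-space forms (``expit`` of a log-odds),
so extreme ``theta * log(t/tau)`` values neither overflow nor underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "HillTimeResponse",
    "KineticParams",
    "PropertyScale",
    "survival",
    "conversion",
    "odds",
    "logistic_solution",
    "t_o_from_initial_conversion",
    "hill_rate",
    "general_solution",
    "property_curve",
    "invert_property",
    "kinetic_to_hill",
    "hill_to_kinetic",
]


@dataclass(frozen=True)
class HillTimeResponse:
    """Log-logistic time-response law with median ``tau`` and shape ``theta``.

    Parameters
    ----------
    tau : float
        Time constant in hours; the time at which conversion reaches 50%
        (the median of the log-logistic distribution).  Must be positive.
    theta : float
        Dimensionless shape parameter; steepness of the sigmoid.  Must be
        positive.
    """

    tau: float
    theta: float

    def __post_init__(self) -> None:
        if not (self.tau > 0):
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if not (self.theta > 0):
            raise ValueError(f"theta must be > 0, got {self.theta}")


@dataclass(frozen=True)
class KineticParams:
    """Kinetic parameterization of the generalized autocatalytic rate law.

    Parameters
    ----------
    k : float
        Rate constant, 1/hours.  Must be positive.
    theta : float
        Dimensionless shape parameter.  Must be positive.
    t_o : float, default 0.0
        Integration-constant time in hours: the time at which conversion
        equals one half.  Under the generalized model, ``t_o = theta / k``
        forces zero conversion at ``t = 0`` and reduces the solution to the
        Hill form with ``tau = theta / k``.
    """

    k: float
    theta: float
    t_o: float = 0.0

    def __post_init__(self) -> None:
        if not (self.k > 0):
            raise ValueError(f"k must be > 0, got {self.k}")
        if not (self.theta > 0):
            raise ValueError(f"theta must be > 0, got {self.theta}")


@dataclass(frozen=True)
class PropertyScale:
    """Affine map between conversion and a measurable signal.

    ``P_o`` is the signal at zero conversion, ``P_inf`` at complete
    conversion; the two must differ for the map to be invertible.
    """

    P_o: float
    P_inf: float

    def __post_init__(self) -> None:
        if self.P_o == self.P_inf:
            raise ValueError("P_o and P_inf must differ")


def _check_nonneg_time(t: np.ndarray) -> None:
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")


def _log_tratio(t: np.ndarray, tau: float) -> np.ndarray:
    # log(t/tau) with t = 0 mapping to -inf (conversion 0, survival 1)
    with np.errstate(divide="ignore"):
        return np.log(t) - math.log(tau)


def survival(t, model: HillTimeResponse):
    """Survival probability ``S(t) = 1 / [1 + (t/tau)**theta]``.

    Equals 1 at ``t = 0`` and decreases strictly to 0; ``S(tau) = 1/2``.
    """
    t = np.asarray(t, dtype=float)
    _check_nonneg_time(t)
    out = expit(-model.theta * _log_tratio(t, model.tau))
    return out if out.ndim else float(out)


def conversion(t, model: HillTimeResponse):
    """Degree of conversion ``alpha(t) = 1 - S(t)``, the log-logistic CDF."""
    t = np.asarray(t, dtype=float)
    _check_nonneg_time(t)
    out = expit(model.theta * _log_tratio(t, model.tau))
    return out if out.ndim else float(out)


def odds(alpha):
    """Odds ratio ``alpha / (1 - alpha)`` for a conversion in (0, 1).

    For a Hill model evaluated at time ``t`` this equals ``(t/tau)**theta``.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any((alpha <= 0) | (alpha >= 1)):
        raise ValueError("alpha must lie strictly inside (0, 1)")
    out = alpha / (1.0 - alpha)
    return out if out.ndim else float(out)


def logistic_solution(t, params: KineticParams):
    """Conversion under the logistic (Prout–Tompkins) rate law.

    ``alpha(t) = exp(k (t - t_o)) / [1 + exp(k (t - t_o))]``; equals 1/2 at
    ``t = t_o``.
    """
    t = np.asarray(t, dtype=float)
    out = expit(params.k * (t - params.t_o))
    return out if out.ndim else float(out)


def t_o_from_initial_conversion(alpha_o: float, k: float) -> float:
    """Integration constant ``t_o = log(1/alpha_o - 1) / k`` from alpha(0)."""
    if not (0 < alpha_o < 1):
        raise ValueError("alpha_o must lie strictly inside (0, 1)")
    if not (k > 0):
        raise ValueError("k must be > 0")
    return math.log(1.0 / alpha_o - 1.0) / k


def hill_rate(alpha, params: KineticParams):
    """Instantaneous transformation rate of the generalized autocatalytic law.

    ``d(alpha)/dt = k * alpha**(1 - 1/theta) * (1 - alpha)**(1 + 1/theta)``.
    The limit theta -> inf recovers the logistic rate ``k alpha (1 - alpha)``;
    theta = 1 gives second-order kinetics ``k (1 - alpha)**2``.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any((alpha <= 0) | (alpha >= 1)):
        raise ValueError("alpha must lie strictly inside (0, 1)")
    inv = 1.0 / params.theta
    out = params.k * np.exp(
        (1.0 - inv) * np.log(alpha) + (1.0 + inv) * np.log1p(-alpha)
    )
    return out if out.ndim else float(out)


def general_solution(t, params: KineticParams):
    """Explicit solution of the generalized rate law.

    ``alpha = b**theta / (1 + b**theta)`` with ``b = 1 + k (t - t_o)/theta``;
    requires ``b > 0``.  With ``t_o = theta/k`` the bracket becomes ``t/tau``
    and the result is identical to :func:`conversion` with ``tau = theta/k``.
    """
    t = np.asarray(t, dtype=float)
    x = params.k * (t - params.t_o) / params.theta
    if np.any(x <= -1):
        raise ValueError(
            "general solution undefined: 1 + k(t - t_o)/theta must be positive"
        )
    out = expit(params.theta * np.log1p(x))
    return out if out.ndim else float(out)


def property_curve(t, model: HillTimeResponse, scale: PropertyScale):
    """Signal trace ``P(t) = P_o + (P_inf - P_o) * alpha(t)``."""
    a = conversion(t, model)
    return scale.P_o + (scale.P_inf - scale.P_o) * a


def invert_property(P, scale: PropertyScale):
    """Recover conversion from a signal value: ``(P - P_o)/(P_inf - P_o)``."""
    P = np.asarray(P, dtype=float)
    out = (P - scale.P_o) / (scale.P_inf - scale.P_o)
    return out if out.ndim else float(out)


def kinetic_to_hill(params: KineticParams) -> HillTimeResponse:
    """Reduce kinetic parameters to the Hill form ``tau = theta / k``.

    Valid only when the integration constant matches the zero-initial-
    conversion choice ``t_o = theta / k``; any other ``t_o`` describes a
    curve with nonzero conversion at ``t = 0``, which has no Hill reduction.
    """
    tau = params.theta / params.k
    if not math.isclose(params.t_o, tau, rel_tol=1e-12, abs_tol=1e-12):
        raise ValueError(
            "Hill reduction requires t_o = theta/k (zero initial conversion)"
        )
    return HillTimeResponse(tau=tau, theta=params.theta)


def hill_to_kinetic(model: HillTimeResponse) -> KineticParams:
    """Express a Hill law kinetically: ``k = theta/tau``, ``t_o = tau``."""
    return KineticParams(
        k=model.theta / model.tau, theta=model.theta, t_o=model.tau
    )
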