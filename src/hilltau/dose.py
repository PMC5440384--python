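"""Dose dependence of the rate and time constants via the modified Haber rule.

At a fixed effect level (pegged at conversion 1/2), concentration and
exposure time trade off as

    (C - C_o)**beta * t = 1 / kappa,

so the median-response time is ``tau = [kappa (C - C_o)**beta]**-1`` and the
rate constant of the generalized autocatalytic law becomes
``k = kappa * theta * (C - C_o)**beta``.  ``beta < 0`` describes a beneficial
agent (tau grows with dose, e.g. an antioxidant); ``beta > 0`` a harmful one.

The same law rewritten at a fixed evaluation time ``t_e`` is the conventional
Hill dose-response curve with median-effect concentration ``C*`` defined by
``C* - C_o = (kappa t_e)**(-1/beta)``.

Note on the symbol kappa: the Haber coefficient kappa (units
1/(hours (wt.%)**beta)) is distinct from the linear potency slope kappa_i
(hours per wt.%) of the dose regression tau = tau_o + kappa_i C_i.  For
beta = -1 and no threshold the two are reciprocal; explicit converters are
provided rather than overloading one name.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HaberLaw",
    "DoseResponseContext",
    "tau_from_concentration",
    "rate_constant",
    "context_for_time",
    "dose_response_odds",
    "time_concentration_tradeoff",
    "potency_slope_from_haber",
    "haber_from_potency_slope",
]


@dataclass(frozen=True)
class HaberLaw:
    """Modified Haber rule parameters.

    Parameters
    ----------
    kappa : float
        Rate coefficient, units 1/(hours * (wt.%)**beta).  Must be positive.
    beta : float
        Power exponent; nonzero.  Negative for beneficial agents.
    C_o : float, default 0.0
        Threshold concentration in wt.%; below it no finite median-response
        time is defined.
    """

    kappa: float
    beta: float
    C_o: float = 0.0

    def __post_init__(self) -> None:
        if not (self.kappa > 0):
            raise ValueError(f"kappa must be > 0, got {self.kappa}")
        if self.beta == 0:
            raise ValueError("beta must be nonzero")
        if self.C_o < 0:
            raise ValueError("C_o must be >= 0")


@dataclass(frozen=True)
class DoseResponseContext:
    """Fixed-time evaluation context: test time ``t_e`` and the median-effect
    concentration ``C_star`` it induces under a given Haber law."""

    t_e: float
    C_star: float

    def __post_init__(self) -> None:
        if not (self.t_e > 0):
            raise ValueError("t_e must be > 0")

    def validate_against(self, law: HaberLaw, rtol: float = 1e-9) -> None:
        """Check C_star - C_o == (kappa t_e)**(-1/beta) for this law."""
        expected = (law.kappa * self.t_e) ** (-1.0 / law.beta)
        if not np.isclose(self.C_star - law.C_o, expected, rtol=rtol, atol=0.0):
            raise ValueError(
                "inconsistent dose-response context: C_star - C_o = "
                f"{self.C_star - law.C_o!r}, law implies {expected!r}"
            )


def _excess(C, law: HaberLaw):
    C = np.asarray(C, dtype=float)
    if np.any(C <= law.C_o):
        raise ValueError(
            f"concentration must exceed the threshold C_o = {law.C_o}"
        )
    return C - law.C_o


def tau_from_concentration(C, law: HaberLaw):
    """Median-response time ``tau = [kappa (C - C_o)**beta]**-1`` in hours."""
    out = 1.0 / (law.kappa * _excess(C, law) ** law.beta)
    return out if np.ndim(out) else float(out)


def rate_constant(C, law: HaberLaw, theta: float):
    """Rate constant ``k = kappa * theta * (C - C_o)**beta`` in 1/hours."""
    if not (theta > 0):
        raise ValueError("theta must be > 0")
    out = law.kappa * theta * _excess(C, law) ** law.beta
    return out if np.ndim(out) else float(out)


def context_for_time(law: HaberLaw, t_e: float) -> DoseResponseContext:
    """Median-effect concentration at test time t_e: C* = C_o + (kappa t_e)**(-1/beta)."""
    if not (t_e > 0):
        raise ValueError("t_e must be > 0")
    return DoseResponseContext(
        t_e=t_e, C_star=law.C_o + (law.kappa * t_e) ** (-1.0 / law.beta)
    )


def dose_response_odds(C, law: HaberLaw, ctx: DoseResponseContext, theta: float):
    """Fixed-time dose-response odds ``[(C - C_o)/(C* - C_o)]**(beta*theta)``.

    Equals 1 at the median-effect concentration ``C = C*`` and coincides with
    the dose-time odds ``[kappa (C - C_o)**beta t]**theta`` evaluated at
    ``t = t_e``.  The (law, ctx) pair must satisfy the defining relation of
    ``C*``; an inconsistent pair is rejected.
    """
    if not (theta > 0):
        raise ValueError("theta must be > 0")
    ctx.validate_against(law)
    ratio = _excess(C, law) / (ctx.C_star - law.C_o)
    out = ratio ** (law.beta * theta)
    return out if np.ndim(out) else float(out)


def time_concentration_tradeoff(C, law: HaberLaw, ctx: DoseResponseContext):
    """Equi-effect time ratio ``t/tau = [(C - C_o)/(C* - C_o)]**beta``."""
    ctx.validate_against(law)
    out = (_excess(C, law) / (ctx.C_star - law.C_o)) ** law.beta
    return out if np.ndim(out) else float(out)


def potency_slope_from_haber(law: HaberLaw) -> float:
    """Linear potency slope kappa_i = 1/kappa (hours per wt.%).

    Only defined for a beneficial agent with beta = -1 and no threshold,
    where tau = C / kappa_i**-1 ... i.e. tau = (1/kappa) * C grows linearly
    with dose.
    """
    if law.beta != -1 or law.C_o != 0:
        raise ValueError(
            "potency slope conversion requires beta = -1 and C_o = 0"
        )
    return 1.0 / law.kappa


def haber_from_potency_slope(kappa_i: float) -> HaberLaw:
    """Haber law (beta = -1, no threshold) from a linear potency slope."""
    if not (kappa_i > 0):
        raise ValueError("kappa_i must be > 0")
    return HaberLaw(kappa=1.0 / kappa_i, beta=-1.0, C_o=0.0)
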