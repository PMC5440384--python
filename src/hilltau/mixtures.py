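"""Time-constant and odds algebra for mixtures of active agents.

All rules combine the time constants tau_i that each agent would give acting
alone at its dosed concentration, under the assumption that every component
follows a Hill law with one shared shape theta:

* independent chemical action — rate constants add, so tau_mix is the
  harmonic combination [sum 1/tau_i]**-1;
* Concentration Addition (CA) — tau_mix is the power mean of order -1/beta,
  [sum tau_i**(-1/beta)]**(-beta); beta = -1 gives a plain sum, beta = 1
  recovers independent action;
* Plackett–Hewlett — the CA isobole is bent by an interaction exponent
  lambda, giving [sum tau_i**(-1/(beta*lambda))]**(-beta*lambda); lambda = 1
  is CA, and lambda > 1 with beta = -1 models synergy.

The special case beta = -1, lambda = 2 with a substrate baseline tau_o,
tau_mix = tau_o + (sum sqrt(tau_i))**2, is the synergy rule used for the
antioxidant pair in the study data.

The binary forms generalize to any number of components by extending the sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "MixtureSpec",
    "Isobole",
    "independent_action_tau",
    "ca_mixture_tau",
    "ph_mixture_tau",
    "synergy_tau_with_baseline",
    "ca_combined_c_star",
    "isobole_curve",
    "mixture_odds",
]


@dataclass(frozen=True)
class MixtureSpec:
    """Per-agent time constants plus the shared Haber and interaction exponents.

    ``component_taus`` are the tau values each agent would give acting alone
    at its dosed concentration (hours, all positive).  ``lam = 1`` recovers
    Concentration Addition exactly.
    """

    component_taus: tuple[float, ...]
    beta: float
    lam: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "component_taus", tuple(float(x) for x in self.component_taus)
        )
        if len(self.component_taus) == 0:
            raise ValueError("at least one component is required")
        if any(not (x > 0) for x in self.component_taus):
            raise ValueError("all component taus must be > 0")
        if self.beta == 0:
            raise ValueError("beta must be nonzero")
        if not (self.lam > 0):
            raise ValueError("lam must be > 0")


@dataclass(frozen=True)
class Isobole:
    """Equi-effect curve for a binary mixture.

    ``C_A_star`` and ``C_B_star`` are the concentrations at which each agent
    alone produces the reference effect (e.g. the median effect); ``lam``
    bends the curve: lam = 1 is the straight Concentration Addition line,
    lam > 1 bows it toward the origin (synergy).
    """

    C_A_star: float
    C_B_star: float
    lam: float = 1.0

    def __post_init__(self) -> None:
        if not (self.C_A_star > 0 and self.C_B_star > 0):
            raise ValueError("median-effect concentrations must be > 0")
        if not (self.lam > 0):
            raise ValueError("lam must be > 0")


def _as_taus(taus: Sequence[float]) -> np.ndarray:
    arr = np.asarray(taus, dtype=float)
    if arr.size == 0:
        raise ValueError("at least one component is required")
    if np.any(arr <= 0):
        raise ValueError("all component taus must be > 0")
    return arr


def independent_action_tau(taus: Sequence[float]) -> float:
    """Mixture tau when rate constants simply add: ``[sum 1/tau_i]**-1``.

    This harmonic combination never exceeds the smallest component tau.  It
    is *not* the response-multiplication "Independent Action" of classical
    mixture toxicology.
    """
    arr = _as_taus(taus)
    return float(1.0 / np.sum(1.0 / arr))


def ca_mixture_tau(taus: Sequence[float], beta: float) -> float:
    """Concentration-Addition mixture tau: power mean of order -1/beta.

    ``tau_mix = [sum tau_i**(-1/beta)]**(-beta)``; beta = -1 reduces to
    ``sum tau_i`` (beneficial agents) and beta = 1 to the harmonic form of
    :func:`independent_action_tau` (harmful agents).
    """
    if beta == 0:
        raise ValueError("beta must be nonzero")
    arr = _as_taus(taus)
    return float(np.sum(arr ** (-1.0 / beta)) ** (-beta))


def ph_mixture_tau(spec: MixtureSpec) -> float:
    """Plackett–Hewlett mixture tau:
    ``[sum tau_i**(-1/(beta*lam))]**(-beta*lam)``; lam = 1 is CA."""
    p = spec.beta * spec.lam
    arr = np.asarray(spec.component_taus)
    return float(np.sum(arr ** (-1.0 / p)) ** (-p))


def synergy_tau_with_baseline(taus: Sequence[float], tau_o: float) -> float:
    """Synergistic mixture tau on top of a substrate baseline:
    ``tau_o + (sum sqrt(tau_i))**2``.

    Identical to the Plackett–Hewlett rule with beta = -1, lam = 2 plus
    ``tau_o``.  Zero component taus are allowed here (an absent agent simply
    drops out of the sum).  The result always meets the synergy bound
    ``>= tau_o + sum tau_i``.
    """
    arr = np.asarray(taus, dtype=float)
    if tau_o < 0 or np.any(arr < 0):
        raise ValueError("tau_o and component taus must be >= 0")
    return float(tau_o + np.sum(np.sqrt(arr)) ** 2)


def ca_combined_c_star(
    x_fractions: Sequence[float], c_stars: Sequence[float]
) -> float:
    """Median-effect concentration of a CA mixture with composition fractions
    x_i: ``1/C_mix* = sum x_i / C_i*``."""
    x = np.asarray(x_fractions, dtype=float)
    cs = np.asarray(c_stars, dtype=float)
    if x.shape != cs.shape:
        raise ValueError("x_fractions and c_stars must have equal length")
    if np.any(x < 0):
        raise ValueError("fractions must be >= 0")
    if abs(x.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {x.sum()!r}")
    if np.any(cs <= 0):
        raise ValueError("all C* must be > 0")
    return float(1.0 / np.sum(x / cs))


def isobole_curve(iso: Isobole, C_A) -> np.ndarray:
    """Concentration of agent B completing the equi-effect pair with C_A.

    Solves ``(C_A/C_A*)**(1/lam) + (C_B/C_B*)**(1/lam) = 1``; for lam = 1
    this is the straight line ``C_B = C_B* (1 - C_A/C_A*)``.  Defined for
    0 <= C_A <= C_A*.
    """
    C_A = np.asarray(C_A, dtype=float)
    if np.any((C_A < 0) | (C_A > iso.C_A_star)):
        raise ValueError("C_A must lie in [0, C_A_star]")
    out = iso.C_B_star * (1.0 - (C_A / iso.C_A_star) ** (1.0 / iso.lam)) ** iso.lam
    return out if out.ndim else float(out)


def mixture_odds(
    component_odds: Sequence[float], beta: float, theta: float, lam: float = 1.0
) -> float:
    """Mixture response odds from per-agent odds:
    ``[sum odds_i**(1/(lam*beta*theta))]**(lam*beta*theta)``.

    With odds_i = (t/tau_i)**theta this is algebraically the Hill odds
    ``(t/tau_mix)**theta`` of :func:`ph_mixture_tau`; lam = 1 gives the
    Concentration Addition form.
    """
    p = lam * beta * theta
    if p == 0:
        raise ValueError("lam * beta * theta must be nonzero")
    arr = np.asarray(component_odds, dtype=float)
    if arr.size == 0:
        raise ValueError("at least one component is required")
    if np.any(arr <= 0):
        raise ValueError("all odds must be > 0")
    return float(np.sum(arr ** (1.0 / p)) ** p)
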