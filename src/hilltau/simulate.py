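"""Seeded synthetic-data generators mirroring the structures the fits assume.

Two forward models are emulated:

* monitor curves — baseline offset + linear drift + scaled log-logistic rise
  with additive Gaussian noise scaled as a fraction of the rise amplitude
  (the Thermomat-style conductivity trace);
* composition designs — a dose grid of agent concentrations whose true
  median-response times follow the potency model (additive with optional
  synergy pairs), observed through replicate Gaussian noise on tau.

Every generator takes a single integer seed and is bit-reproducible for a
given seed.  The provided grid preset mirrors the study layout: three agents
at four single doses each, nine binary blends at a 0.25 wt.% total dose, and
the neat substrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fitting import (
    CompositionRecord,
    ConductivityCurve,
    PotencyModel,
    predict_tau,
)
from .hill import HillTimeResponse, conversion

__all__ = [
    "CurveGenSpec",
    "DesignGenSpec",
    "generate_curve",
    "generate_design",
    "table1_layout_grid",
    "study_like_potency_model",
]

_STUDY_AGENTS = ("Orox PK", "Naugard P", "Anox 20")
_STUDY_SINGLE_DOSES = (0.083, 0.125, 0.167, 0.250)
_STUDY_BINARY_SPLITS = ((0.167, 0.083), (0.125, 0.125), (0.083, 0.167))


@dataclass(frozen=True)
class CurveGenSpec:
    """Forward-model parameters for one synthetic monitor curve.

    noise_frac scales the Gaussian signal noise as a fraction of the rise
    amplitude P; defaults emulate a stabilized-substrate run at 1% noise.
    """

    sigma_min: float = 5.0
    m: float = 0.1
    P: float = 100.0
    tau: float = 8.0
    theta: float = 3.45
    t_max: float = 20.0
    n_points: int = 200
    noise_frac: float = 0.01
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_points < 8:
            raise ValueError("n_points must be >= 8")
        if self.noise_frac < 0:
            raise ValueError("noise_frac must be >= 0")
        if not (self.t_max > 0):
            raise ValueError("t_max must be > 0")


@dataclass(frozen=True)
class DesignGenSpec:
    """Forward-model parameters for a synthetic composition design."""

    potency: PotencyModel
    grid: tuple[dict[str, float], ...]
    noise_sd: float = 0.3
    n_rep: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", tuple(dict(g) for g in self.grid))
        if not any(all(v == 0 for v in g.values()) for g in self.grid):
            raise ValueError("grid must include the neat (all-zero) composition")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_rep < 1:
            raise ValueError("n_rep must be >= 1")


def generate_curve(spec: CurveGenSpec) -> ConductivityCurve:
    """Simulate one monitor curve on an equally spaced time grid."""
    rng = np.random.default_rng(spec.seed)
    t = np.linspace(0.0, spec.t_max, spec.n_points)
    model = HillTimeResponse(tau=spec.tau, theta=spec.theta)
    y = spec.sigma_min + spec.m * t + spec.P * conversion(t, model)
    if spec.noise_frac > 0:
        y = y + rng.normal(0.0, spec.noise_frac * spec.P, size=t.size)
    return ConductivityCurve(times=t, signal=y, label=spec.label)


def generate_design(spec: DesignGenSpec) -> list[CompositionRecord]:
    """Simulate a design table: replicate noisy tau draws per composition.

    Each record stores the replicate mean and (ddof=1) standard deviation;
    with one replicate the sd is reported as 0.  The generating model is the
    spec's potency model, so zero-noise output round-trips exactly through
    the potency fit.
    """
    rng = np.random.default_rng(spec.seed)
    out = []
    for i, comp in enumerate(spec.grid):
        true_tau = predict_tau(comp, spec.potency)
        draws = true_tau + rng.normal(0.0, spec.noise_sd, size=spec.n_rep)
        sd = float(np.std(draws, ddof=1)) if spec.n_rep > 1 else 0.0
        out.append(
            CompositionRecord(
                composition=comp,
                tau_obs=float(np.mean(draws)),
                tau_sd=sd,
                n_rep=spec.n_rep,
                label=f"composition-{i}",
            )
        )
    return out


def table1_layout_grid() -> tuple[dict[str, float], ...]:
    """The study's dose grid: neat substrate, 3 agents x 4 single doses, and
    9 binary blends at a constant 0.25 wt.% total dose."""
    zero = {a: 0.0 for a in _STUDY_AGENTS}
    grid = [dict(zero)]
    for agent in _STUDY_AGENTS:
        for dose in _STUDY_SINGLE_DOSES:
            comp = dict(zero)
            comp[agent] = dose
            grid.append(comp)
    pairs = (
        (_STUDY_AGENTS[1], _STUDY_AGENTS[2]),  # Naugard P + Anox 20
        (_STUDY_AGENTS[0], _STUDY_AGENTS[1]),  # Orox PK + Naugard P
        (_STUDY_AGENTS[0], _STUDY_AGENTS[2]),  # Orox PK + Anox 20
    )
    for a, b in pairs:
        for c_a, c_b in _STUDY_BINARY_SPLITS:
            comp = dict(zero)
            comp[a], comp[b] = c_a, c_b
            grid.append(comp)
    return tuple(grid)


def study_like_potency_model(
    tau_o: float = 5.66,
    kappa: dict[str, float] | None = None,
    lam: float = 2.0,
) -> PotencyModel:
    """A potency model with the study's baseline, slope magnitudes and the
    synergistic amine/phenolic pair; convenient ground truth for recovery
    studies."""
    if kappa is None:
        kappa = {"Orox PK": 4.48, "Naugard P": 0.88, "Anox 20": 28.32}
    return PotencyModel(
        tau_o=tau_o,
        potencies=kappa,
        synergy_pairs=frozenset({frozenset({"Orox PK", "Anox 20"})}),
        lam=lam,
    )
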