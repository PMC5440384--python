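"""Two-level least-squares estimation for induction-time monitor curves.

Level 1 — curve decomposition.  Each conductivity-vs-time trace is modelled
as

    sigma(t) = sigma_min + m*t + P*alpha(t; tau, theta),

a baseline offset, a linear drift term, and a scaled log-logistic rise.  The
model is linear in (sigma_min, m, P) given (tau, theta), so fits use variable
projection: the nonlinear search runs over log tau (and log theta when theta
is free) with the linear coefficients solved exactly at every step.  A shared
shape theta across a batch of curves is estimated by profiling: an outer
one-dimensional minimization over theta with per-curve tau re-optimized
inside.

Level 2 — dose regression.  Recovered time constants are regressed against
composition: tau = tau_o + sum_i kappa_i C_i for independently acting agents,
with a Plackett–Hewlett synergy term tau_o + (sum_i (kappa_i C_i)**(1/lam))**lam
(lam = 2 by default) replacing the additive contribution of flagged agent
pairs.  tau_o is pinned to the observed neat-substrate value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize_scalar
from scipy.special import expit

__all__ = [
    "ConductivityCurve",
    "CurveFitResult",
    "SharedThetaResult",
    "CompositionRecord",
    "PotencyModel",
    "PotencyFitResult",
    "FitError",
    "fit_curve",
    "fit_shared_theta",
    "fit_potency",
    "predict_tau",
    "percent_difference",
]

Composition = Mapping[str, float]

DEFAULT_THETA_GUESS = 3.45  # shape typical of oxidation-induction monitor data


class FitError(RuntimeError):
    """Raised when a least-squares fit fails to converge or is degenerate."""


@dataclass(frozen=True)
class ConductivityCurve:
    """A monitor trace: sampling times (hours) and signal (e.g. µS/cm)."""

    times: np.ndarray
    signal: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", y)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
            raise ValueError("times and signal must be 1-D and equal length")
        if t.size < 8:
            raise ValueError("at least 8 points are required for a curve fit")
        if t[0] < 0:
            raise ValueError("times must be nonnegative")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class CurveFitResult:
    """Converged decomposition of one monitor curve."""

    sigma_min: float
    m: float
    P: float
    tau: float
    theta: float
    rss: float
    se_tau: float
    label: str = ""

    def predict(self, t) -> np.ndarray:
        """Reconstructed signal sigma_min + m*t + P*alpha(t)."""
        t = np.asarray(t, dtype=float)
        return self.sigma_min + self.m * t + self.P * _alpha(t, self.tau, self.theta)


@dataclass(frozen=True)
class SharedThetaResult:
    """Joint fit of several curves with one global shape parameter."""

    theta: float
    se_theta: float
    fits: tuple[CurveFitResult, ...]
    rss: float


@dataclass(frozen=True)
class CompositionRecord:
    """One design row: agent concentrations (wt.%) and the observed tau."""

    composition: dict[str, float]
    tau_obs: float
    tau_sd: float = 0.0
    n_rep: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        comp = {str(k): float(v) for k, v in self.composition.items()}
        object.__setattr__(self, "composition", comp)
        if any(v < 0 for v in comp.values()):
            raise ValueError("concentrations must be >= 0")
        if not (self.tau_obs > 0):
            raise ValueError("tau_obs must be > 0")

    @property
    def is_neat(self) -> bool:
        return all(v == 0 for v in self.composition.values())

    def active_agents(self) -> tuple[str, ...]:
        return tuple(a for a, c in self.composition.items() if c > 0)


@dataclass(frozen=True)
class PotencyModel:
    """Dose-regression model: baseline tau_o, per-agent potency slopes
    kappa_i (hours per wt.%), and synergy-flagged agent pairs with a shared
    interaction exponent lam."""

    tau_o: float
    potencies: dict[str, float]
    synergy_pairs: frozenset[frozenset[str]] = frozenset()
    lam: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "potencies", {str(k): float(v) for k, v in self.potencies.items()}
        )
        pairs = frozenset(frozenset(p) for p in self.synergy_pairs)
        for p in pairs:
            if len(p) != 2:
                raise ValueError("synergy pairs must contain exactly two agents")
            unknown = set(p) - set(self.potencies)
            if unknown:
                raise ValueError(f"synergy pair references unknown agents {unknown}")
        object.__setattr__(self, "synergy_pairs", pairs)
        if not (self.tau_o > 0):
            raise ValueError("tau_o must be > 0")
        if not (self.lam > 0):
            raise ValueError("lam must be > 0")


@dataclass(frozen=True)
class PotencyFitResult:
    """Fitted potency model plus per-record predictions and diagnostics."""

    model: PotencyModel
    records: tuple[CompositionRecord, ...]
    predictions: np.ndarray
    percent_differences: np.ndarray
    rss: float
    negative_potency_agents: tuple[str, ...] = field(default=())


# ---------------------------------------------------------------------------
# level 1: curve decomposition


def _alpha(t: np.ndarray, tau: float, theta: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return expit(theta * (np.log(t) - math.log(tau)))


def _solve_linear(t, y, a):
    """Exact least squares for (sigma_min, m, P) given the alpha column."""
    A = np.column_stack([np.ones_like(t), t, a])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return coef, resid


def _profiled_residual(x, t, y, theta_fixed):
    if theta_fixed is None:
        tau, theta = math.exp(x[0]), math.exp(x[1])
    else:
        tau, theta = math.exp(x[0]), theta_fixed
    _, resid = _solve_linear(t, y, _alpha(t, tau, theta))
    return resid


def _initial_guesses(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Heuristic starting values (sigma_min, m, P, tau) from curve geometry."""
    sigma_min0 = float(np.quantile(y, 0.1))
    n_head = max(int(0.2 * t.size), 2)
    m0, b0 = np.polyfit(t[:n_head], y[:n_head], 1)
    detrended = y - (b0 + m0 * t)
    rise = float(detrended.max())
    scale = max(abs(float(y.max() - y.min())), 1e-12)
    if rise <= 1e-3 * scale:
        raise FitError(
            "no sigmoidal rise detected above the baseline drift (P ~ 0); "
            "curve appears to be pure baseline + drift"
        )
    above = np.nonzero(detrended >= 0.5 * rise)[0]
    tau0 = float(t[above[0]]) if above.size and t[above[0]] > 0 else float(
        t[max(t.size // 2, 1)]
    )
    return sigma_min0, float(m0), rise, tau0


def _fit_tau_theta(
    t: np.ndarray,
    y: np.ndarray,
    tau0: float,
    theta0: float,
    theta_fixed: float | None,
    seed: int,
    max_nfev: int,
) -> tuple[float, float, float]:
    """Variable-projection search over log tau (and log theta).

    The profiled objective can hold spurious minima with a negative fitted
    amplitude when the starting tau is far off, so the search multi-starts
    from the half-rise heuristic plus a fixed grid of fractions of the time
    span and keeps the best *valid* solution (positive amplitude, tau within
    (0, 2 t_max]).  Seeded jittered restarts are a last resort.
    """
    t_max = float(t[-1])

    def attempt(tau_init, theta_init):
        x0 = [math.log(tau_init)]
        if theta_fixed is None:
            x0.append(math.log(theta_init))
        res = least_squares(
            _profiled_residual,
            x0,
            args=(t, y, theta_fixed),
            method="lm",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=max_nfev,
        )
        tau = math.exp(res.x[0])
        theta = theta_fixed if theta_fixed is not None else math.exp(res.x[1])
        (_, _, P), _ = _solve_linear(t, y, _alpha(t, tau, theta))
        valid = res.status > 0 and P > 0 and 0 < tau <= 2 * t_max
        return tau, theta, float(np.sum(res.fun**2)), valid

    starts = [tau0] + [f * t_max for f in (0.15, 0.3, 0.5, 0.75)]
    best = None
    for s in starts:
        try:
            ta, th, c, ok = attempt(s, theta0)
        except (ValueError, FloatingPointError):
            continue
        if ok and (best is None or c < best[2]):
            best = (ta, th, c)
    if best is None:
        rng = np.random.default_rng(seed)
        for _ in range(5):
            jt = tau0 * math.exp(rng.normal(0, 0.7))
            jth = theta0 * math.exp(rng.normal(0, 0.3))
            try:
                ta, th, c, ok = attempt(jt, jth)
            except (ValueError, FloatingPointError):
                continue
            if ok and (best is None or c < best[2]):
                best = (ta, th, c)
    if best is None:
        raise FitError(
            "curve fit failed to converge to a valid solution after "
            "multi-start (no positive-amplitude fit with tau inside the "
            "trusted window)"
        )
    return best


def _full_jacobian(t, P, tau, theta, theta_free):
    """Jacobian of the full model w.r.t. (sigma_min, m, P, tau[, theta])."""
    a = _alpha(t, tau, theta)
    w = a * (1.0 - a)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(t > 0, np.log(t) - math.log(tau), 0.0)
    cols = [np.ones_like(t), t, a, P * w * (-theta / tau)]
    if theta_free:
        cols.append(P * w * u)
    return np.column_stack(cols)


def _covariance_se(J, rss, n):
    p = J.shape[1]
    dof = max(n - p, 1)
    s2 = rss / dof
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)
    d = np.diag(cov)
    return np.sqrt(np.where(d > 0, d, np.nan))


def fit_curve(
    curve: ConductivityCurve,
    theta: float | Literal["free"] = "free",
    *,
    seed: int = 0,
    max_nfev: int = 10_000,
) -> CurveFitResult:
    """Decompose one monitor curve into baseline + drift + scaled Hill rise.

    Parameters
    ----------
    curve : ConductivityCurve
        The trace to fit; at least 8 points.
    theta : float or "free"
        Fix the shape parameter at the given value, or estimate it from this
        curve alone.
    seed : int
        Seed for jittered multi-start restarts on non-convergence.

    Returns
    -------
    CurveFitResult
        Converged parameters with residual sum of squares and the standard
        error of tau from the Gauss–Newton covariance of the *full*
        (unprofiled) model.

    Raises
    ------
    FitError
        If no sigmoidal rise is detectable, the fit does not converge, the
        fitted amplitude is non-positive, or the fitted tau falls outside
        (0, 2 * t_max].
    """
    theta_fixed: float | None
    if theta == "free":
        theta_fixed = None
    else:
        theta_fixed = float(theta)
        if not (theta_fixed > 0):
            raise ValueError("fixed theta must be > 0")

    t, y = curve.times, curve.signal
    n_par = 4 if theta_fixed is not None else 5
    if t.size <= n_par:
        raise ValueError(f"need more than {n_par} points, got {t.size}")

    _, _, _, tau0 = _initial_guesses(t, y)
    tau_hat, theta_hat, rss = _fit_tau_theta(
        t, y, tau0, DEFAULT_THETA_GUESS if theta_fixed is None else theta_fixed,
        theta_fixed, seed, max_nfev,
    )
    (sigma_min, m, P), resid = _solve_linear(t, y, _alpha(t, tau_hat, theta_hat))
    rss = float(np.sum(resid**2))

    t_max = float(t[-1])
    if not (0 < tau_hat <= 2 * t_max):
        raise FitError(
            f"fitted tau = {tau_hat:.4g} h outside the trusted window "
            f"(0, {2 * t_max:.4g}] for this curve"
        )
    if P <= 0:
        raise FitError("fitted response amplitude P is non-positive (non-sigmoidal)")

    J = _full_jacobian(t, P, tau_hat, theta_hat, theta_fixed is None)
    se = _covariance_se(J, rss, t.size)
    return CurveFitResult(
        sigma_min=float(sigma_min),
        m=float(m),
        P=float(P),
        tau=float(tau_hat),
        theta=float(theta_hat),
        rss=rss,
        se_tau=float(se[3]),
        label=curve.label,
    )


def fit_shared_theta(
    curves: Sequence[ConductivityCurve],
    *,
    theta_bounds: tuple[float, float] = (0.5, 30.0),
    seed: int = 0,
) -> SharedThetaResult:
    """Jointly fit several curves with one global shape parameter.

    The total residual sum of squares is minimized over a single theta with
    per-curve (sigma_min, m, P, tau) re-optimized at every theta (profiling).
    The standard error of theta comes from the Gauss–Newton covariance of the
    full joint model (4 parameters per curve plus the shared theta).

    Raises
    ------
    ValueError
        If fewer than two curves are supplied (a shared parameter is
        undefined for a single curve).
    FitError
        If any per-curve profile fails; the offending curve label is named.
    """
    curves = list(curves)
    if len(curves) < 2:
        raise ValueError("a shared theta requires at least two curves")

    inits = []
    for c in curves:
        try:
            _, _, _, tau0 = _initial_guesses(c.times, c.signal)
        except FitError as exc:
            raise FitError(f"curve {c.label!r}: {exc}") from exc
        inits.append(math.log(tau0))
    warm = list(inits)

    def profile_curve(i: int, theta: float) -> tuple[float, float]:
        c = curves[i]
        res = least_squares(
            _profiled_residual,
            [warm[i]],
            args=(c.times, c.signal, theta),
            method="lm",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=2000,
        )
        warm[i] = float(res.x[0])
        return math.exp(res.x[0]), float(np.sum(res.fun**2))

    def total_cost(theta: float) -> float:
        return sum(profile_curve(i, theta)[1] for i in range(len(curves)))

    opt = minimize_scalar(
        total_cost, bounds=theta_bounds, method="bounded",
        options={"xatol": 1e-6},
    )
    theta_hat = float(opt.x)

    fits = []
    for i, c in enumerate(curves):
        warm[i] = inits[i]
        try:
            fits.append(fit_curve(c, theta=theta_hat, seed=seed + i))
        except FitError as exc:
            raise FitError(f"curve {c.label!r}: {exc}") from exc

    # joint covariance: block-diagonal per-curve params + shared theta column
    blocks, theta_col, resids = [], [], []
    for f, c in zip(fits, curves):
        t = c.times
        a = _alpha(t, f.tau, theta_hat)
        w = a * (1.0 - a)
        with np.errstate(divide="ignore", invalid="ignore"):
            u = np.where(t > 0, np.log(t) - math.log(f.tau), 0.0)
        blocks.append(
            np.column_stack([np.ones_like(t), t, a, f.P * w * (-theta_hat / f.tau)])
        )
        theta_col.append(f.P * w * u)
        resids.append(c.signal - f.predict(t))
    n_tot = sum(b.shape[0] for b in blocks)
    p_tot = 4 * len(curves) + 1
    J = np.zeros((n_tot, p_tot))
    row = 0
    for i, b in enumerate(blocks):
        J[row : row + b.shape[0], 4 * i : 4 * i + 4] = b
        J[row : row + b.shape[0], -1] = theta_col[i]
        row += b.shape[0]
    rss = float(sum(np.sum(r**2) for r in resids))
    se = _covariance_se(J, rss, n_tot)
    return SharedThetaResult(
        theta=theta_hat, se_theta=float(se[-1]), fits=tuple(fits), rss=rss
    )


# ---------------------------------------------------------------------------
# level 2: dose regression


def predict_tau(composition: Composition, model: PotencyModel) -> float:
    """Predicted median-response time for a composition.

    Additive rule tau_o + sum kappa_i C_i, except that agents belonging to a
    flagged synergy pair with both members dosed contribute
    ``(sum (kappa_i C_i)**(1/lam))**lam`` instead of their plain sum.
    """
    unknown = {a for a, c in composition.items() if c > 0} - set(model.potencies)
    if unknown:
        raise ValueError(f"composition references unknown agents {sorted(unknown)}")
    contrib = {a: model.potencies[a] * c for a, c in composition.items() if c > 0}
    tau = model.tau_o
    consumed: set[str] = set()
    for pair in model.synergy_pairs:
        members = [a for a in pair if a in contrib]
        if len(members) == 2:
            vals = np.array([max(contrib[a], 0.0) for a in members])
            tau += float(np.sum(vals ** (1.0 / model.lam)) ** model.lam)
            consumed.update(members)
    tau += sum(v for a, v in contrib.items() if a not in consumed)
    return float(tau)


def percent_difference(tau_obs: float, tau_pred: float) -> float:
    """Relative deviation 100 * |tau_obs - tau_pred| / tau_obs, in percent."""
    if not (tau_obs > 0):
        raise ValueError("tau_obs must be > 0")
    return 100.0 * abs(tau_obs - tau_pred) / tau_obs


def _single_agent_slopes(
    records: Sequence[CompositionRecord], agents: Sequence[str], tau_o: float
) -> dict[str, float]:
    """Per-agent potency slope through the origin from single-agent rows."""
    out = {}
    for agent in agents:
        C, y = [], []
        for r in records:
            active = r.active_agents()
            if active == (agent,):
                C.append(r.composition[agent])
                y.append(r.tau_obs - tau_o)
        if not C:
            raise ValueError(
                f"agent {agent!r} has no single-agent record; potency is "
                "unidentifiable"
            )
        C, y = np.asarray(C), np.asarray(y)
        out[agent] = float(np.sum(C * y) / np.sum(C * C))
    return out


def fit_potency(
    records: Sequence[CompositionRecord],
    synergy_pairs: Iterable[tuple[str, str]] = (),
    lam: float = 2.0,
    *,
    records_used: Literal["single", "all"] = "single",
) -> PotencyFitResult:
    """Estimate the dose-regression model from a design table.

    tau_o is pinned to the observed neat-substrate tau (the design must
    contain exactly the neat row for this).  Potency slopes kappa_i are then
    estimated by unweighted least squares, either

    * ``records_used="single"`` (default): per-agent slopes through the
      origin from that agent's single-agent rows only, with every mixture
      row *predicted* from those slopes — the scheme that reproduces the
      study's fitted table; or
    * ``records_used="all"``: one simultaneous nonlinear least-squares fit of
      all kappa_i over every non-neat record, mixture rows included.

    A negative fitted slope (an agent that shortens the induction time) is
    kept but reported in ``negative_potency_agents`` with a warning.
    """
    records = list(records)
    neat = [r for r in records if r.is_neat]
    if not neat:
        raise ValueError("design must include the neat-substrate record")
    tau_o = neat[0].tau_obs

    agents = sorted({a for r in records for a in r.active_agents()})
    if not agents:
        raise ValueError("design contains no dosed agents")
    for a, b in synergy_pairs:
        if a not in agents or b not in agents:
            raise ValueError(f"synergy pair ({a!r}, {b!r}) references unknown agents")

    # identifiability guard applies to both schemes
    slopes = _single_agent_slopes(records, agents, tau_o)

    if records_used == "all":
        fit_rec = [r for r in records if not r.is_neat]
        pairs = frozenset(frozenset(p) for p in synergy_pairs)

        def residual(kv):
            model = PotencyModel(
                tau_o=tau_o,
                potencies=dict(zip(agents, kv)),
                synergy_pairs=pairs,
                lam=lam,
            )
            return np.array([predict_tau(r.composition, model) - r.tau_obs for r in fit_rec])

        x0 = np.array([max(slopes[a], 1e-3) for a in agents])
        res = least_squares(residual, x0, method="lm", xtol=1e-10, ftol=1e-10)
        if res.status <= 0:
            raise FitError("potency regression failed to converge")
        slopes = dict(zip(agents, (float(v) for v in res.x)))
    elif records_used != "single":
        raise ValueError("records_used must be 'single' or 'all'")

    negative = tuple(a for a in agents if slopes[a] < 0)
    if negative:
        warnings.warn(
            f"negative potency slope for {negative}: agent acts as a "
            "destabilizer over this dose range",
            stacklevel=2,
        )

    model = PotencyModel(
        tau_o=tau_o,
        potencies=slopes,
        synergy_pairs=frozenset(frozenset(p) for p in synergy_pairs),
        lam=lam,
    )
    preds = np.array([predict_tau(r.composition, model) for r in records])
    pdiff = np.array([percent_difference(r.tau_obs, p) for r, p in zip(records, preds)])
    rss = float(np.sum((preds - np.array([r.tau_obs for r in records])) ** 2))
    return PotencyFitResult(
        model=model,
        records=tuple(records),
        predictions=preds,
        percent_differences=pdiff,
        rss=rss,
        negative_potency_agents=negative,
    )
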