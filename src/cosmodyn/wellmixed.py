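"""Well-mixed two-strain community dynamics.

The community obeys four coupled ODEs: each live population grows at a
Moser birth rate on its required metabolite minus a constant death rate,
and each metabolite is released by the partner strain and consumed in
proportion to births:

    dNL/dt = (bL(L) - dL) NL
    dNA/dt = (bA(A) - dA) NA
    dL/dt  = rL NA 1e-6 - cL bL(L) NL 1e-6
    dA/dt  = rA NL 1e-6 - cA bA(A) NA 1e-6

with densities in cells/mL and concentrations in uM.  The lysine release
rate rL may be a constant, a linear function of the instantaneous net
growth rate of the releasing strain, or a piecewise-linear function of the
local hypoxanthine concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .params import (
    UM_PER_FMOL_PER_ML,
    CommunityState,
    EstimateWithCI,
    LinearReleaseLaw,
    MoserParams,
    ParameterError,
    PiecewiseReleaseLaw,
    StrainPhenotype,
)

__all__ = [
    "Trajectory",
    "SolverFailure",
    "moser_birth_rate",
    "simulate_wellmixed",
    "accumulate_densities",
    "fit_steady_state_growth_rate",
    "fit_log_linear",
]


class SolverFailure(RuntimeError):
    """ODE integration failed; carries the last valid state."""

    def __init__(self, message: str, last_state=None, last_time=None):
        super().__init__(message)
        self.last_state = last_state
        self.last_time = last_time


@dataclass
class Trajectory:
    """Time course of the community state, optionally with dilution factors.

    ``dilution_factor[i]`` is the cumulative factor by which raw measured
    densities at ``t[i]`` must be multiplied to obtain accumulative
    densities comparable across dilution events.
    """

    t: np.ndarray
    NL: np.ndarray
    NA: np.ndarray
    L: np.ndarray
    A: np.ndarray
    dead_NL: np.ndarray | None = None
    dead_NA: np.ndarray | None = None
    dilution_factor: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ParameterError("trajectory times must be strictly increasing")
        if self.dilution_factor is not None:
            f = np.asarray(self.dilution_factor, dtype=float)
            if np.any(f < 1) or np.any(np.diff(f) < 0):
                raise ParameterError("dilution factors must be >=1 and non-decreasing")

    @property
    def total_live(self) -> np.ndarray:
        """Accumulative total live density (dilution-corrected if recorded)."""
        total = np.asarray(self.NL) + np.asarray(self.NA)
        if self.dilution_factor is not None:
            total = total * np.asarray(self.dilution_factor)
        return total


def moser_birth_rate(s, p: MoserParams):
    """Moser birth rate b(s) = b_max s^n / (s^n + K^n) at concentration s (uM).

    Accepts scalars or arrays; raises for negative concentrations (callers
    integrating ODEs should clamp transient undershoots first).
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ParameterError("metabolite concentration must be >= 0")
    sn = s**p.n
    out = p.b_max * sn / (sn + p.K**p.n)
    return out if out.ndim else float(out)


def _release_rate_L(release, A: float, bA: float, dA: float) -> float:
    """Lysine release rate of the hypoxanthine-requiring strain.

    Growth-rate-based laws are evaluated at the instantaneous net growth
    rate g = bA(A) - dA; concentration-based laws at the local
    hypoxanthine concentration A.
    """
    if isinstance(release, LinearReleaseLaw):
        return release.rate_at_growth(bA - dA)
    if isinstance(release, PiecewiseReleaseLaw):
        return float(release.rate_at_H(A))
    return float(release)


def simulate_wellmixed(
    lys_consumer: StrainPhenotype,
    hyp_consumer: StrainPhenotype,
    init: CommunityState,
    t_end: float,
    *,
    n_points: int = 201,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    track_dead: bool = True,
) -> Trajectory:
    """Integrate the community ODEs from ``init`` to ``t_end`` hours.

    ``lys_consumer`` is the lysine-requiring / hypoxanthine-releasing strain
    (release attribute = r_A); ``hyp_consumer`` the hypoxanthine-requiring /
    lysine-releasing strain (release attribute = r_L, possibly a law).
    Metabolite arguments are clamped at zero when evaluating birth rates so
    transient numerical undershoots cannot propagate.
    """
    if t_end <= 0:
        raise ParameterError("t_end must be > 0")
    pL, pA = lys_consumer, hyp_consumer
    if not isinstance(pL.release, (int, float)):
        raise ParameterError("the lysine consumer's hypoxanthine release rate must be a fixed value")
    rA = float(pL.release)

    def rhs(t, y):
        NL, NA, L, A, dNL, dNA = y
        bL = moser_birth_rate(max(L, 0.0), pL.birth)
        bA = moser_birth_rate(max(A, 0.0), pA.birth)
        rL = _release_rate_L(pA.release, max(A, 0.0), bA, pA.death_rate)
        births_L = bL * max(NL, 0.0)
        births_A = bA * max(NA, 0.0)
        return [
            births_L - pL.death_rate * NL,
            births_A - pA.death_rate * NA,
            (rL * max(NA, 0.0) - pL.consumption * births_L) * UM_PER_FMOL_PER_ML,
            (rA * max(NL, 0.0) - pA.consumption * births_A) * UM_PER_FMOL_PER_ML,
            pL.death_rate * max(NL, 0.0),
            pA.death_rate * max(NA, 0.0),
        ]

    y0 = [init.NL, init.NA, init.L, init.A, init.dead_NL, init.dead_NA]
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(rhs, (0.0, t_end), y0, method=method, t_eval=t_eval,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise SolverFailure(
            f"community ODE integration failed: {sol.message}",
            last_state=sol.y[:, -1] if sol.y.size else y0,
            last_time=sol.t[-1] if sol.t.size else 0.0,
        )
    y = np.clip(sol.y, 0.0, None)
    return Trajectory(
        t=sol.t, NL=y[0], NA=y[1], L=y[2], A=y[3],
        dead_NL=y[4] if track_dead else None,
        dead_NA=y[5] if track_dead else None,
    )


def accumulate_densities(times, raw_densities, dilution_events):
    """Correct raw densities for dilutions taken during a growth experiment.

    Each event is ``(t_event, factor)``; every density measured at
    ``t >= t_event`` is multiplied by ``factor`` (multiplicatively across
    events), so the returned series is continuous across dilutions.
    """
    times = np.asarray(times, dtype=float)
    out = np.asarray(raw_densities, dtype=float).copy()
    for t_event, factor in dilution_events:
        if factor <= 0:
            raise ParameterError("dilution factor must be > 0")
        if not (times[0] <= t_event <= times[-1]):
            raise ParameterError(f"dilution event at t={t_event} outside time range")
        out[times >= t_event] *= factor
    return out


def fit_log_linear(t, density) -> EstimateWithCI:
    """Least-squares slope of ln(density) vs t with its standard error."""
    t = np.asarray(t, dtype=float)
    y = np.log(np.asarray(density, dtype=float))
    n = len(t)
    if n < 3:
        raise ParameterError("growth-rate fit needs >= 3 points")
    X = np.column_stack([np.ones(n), t])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sxx = np.sum((t - t.mean()) ** 2)
    s2 = np.sum(resid**2) / (n - 2)
    sem = float(np.sqrt(s2 / sxx))
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return EstimateWithCI(
        value=float(coef[1]), sem=sem, method="log-linear OLS",
        slope=float(coef[1]), intercept=float(coef[0]), r_squared=float(r2),
        n_points=n,
    )


def fit_steady_state_growth_rate(
    traj: Trajectory,
    *,
    window: str = "stable",
    threshold: float = 9e7,
    exclude_above: float | None = None,
    rate_tol: float = 0.01,
) -> EstimateWithCI:
    """Post-lag exponential growth rate of the total live population.

    Window policies:

    * ``"threshold"``: fit from the first point where total accumulative
      density exceeds ``threshold`` (cells/mL, or total cells if the caller
      works in counts), optionally dropping points above ``exclude_above``.
    * ``"stable"`` (default for simulations): fit from the first point where
      the instantaneous rate d ln(N)/dt stays within ``rate_tol`` (relative)
      of its value one doubling later, i.e. the rate has stopped drifting.

    Returns the slope of ln(total) vs time with its standard error.
    """
    total = traj.total_live
    t = traj.t
    if window == "threshold":
        mask = total >= threshold
        if exclude_above is not None:
            mask &= total <= exclude_above
    elif window == "stable":
        lnN = np.log(np.clip(total, 1e-300, None))
        rate = np.gradient(lnN, t)
        start = len(t) - 3
        for i in range(len(t) - 1):
            r_i = rate[i]
            if r_i <= 0:
                continue
            # index one doubling time later
            j = np.searchsorted(t, t[i] + np.log(2) / r_i)
            if j >= len(t):
                break
            if abs(rate[j] - r_i) < rate_tol * abs(r_i):
                start = i
                break
        mask = np.zeros(len(t), dtype=bool)
        mask[start:] = True
    else:
        raise ParameterError(f"unknown window policy {window!r}")
    if mask.sum() < 3:
        raise ParameterError("growth-rate window selects fewer than 3 points")
    est = fit_log_linear(t[mask], total[mask])
    est.method = f"log-linear OLS, window={window}"
    return est
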