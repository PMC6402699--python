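"""Two-genotype (ancestor/mutant) dynamics and fitness arithmetic.

The hypoxanthine-requiring strain throws off aneuploid mutants at an
extraordinarily high rate (order 0.01 per cell per generation, consistent
with chromosome mis-segregation).  Mutants have a higher affinity for the
limiting metabolite (lower K) but grow ~50% slower in excess metabolite, a
trade-off that makes them invade under limitation and linger as a minority
in batch growth.  "Per cell per generation" conversion is implemented as a
per-birth probability: a fraction mu of ancestor births yields mutants,
the only formulation consistent with a continuous-time birth process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .chemostat import ChemostatConfig
from .params import (
    UM_PER_FMOL_PER_ML,
    EstimateWithCI,
    MoserParams,
    ParameterError,
)
from .wellmixed import SolverFailure, fit_log_linear, moser_birth_rate

__all__ = [
    "EvoParams",
    "simulate_batch_mutant_dynamics",
    "simulate_chemostat_competition",
    "fitness_advantage_from_ratio",
    "initial_mutant_frequency",
    "expected_preexisting_mutants",
]


@dataclass
class EvoParams:
    """Ancestor/mutant parameters for a two-genotype simulation.

    ``mu``: probability that an ancestor birth yields a mutant.
    Birth parameters are either fixed exponential rates (for batch growth in
    excess metabolite) or Moser laws (for metabolite-limited competition).
    """

    mu: float
    initial_fraction: float = 0.0
    anc_birth_rate: float | None = None
    mut_birth_rate: float | None = None
    anc_birth: MoserParams | None = None
    mut_birth: MoserParams | None = None
    anc_death: float = 0.0
    mut_death: float = 0.0
    anc_consumption: float | None = None
    mut_consumption: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.mu <= 1:
            raise ParameterError("mu must be in [0, 1]")
        if not 0 <= self.initial_fraction <= 1:
            raise ParameterError("initial mutant fraction must be in [0, 1]")


def simulate_batch_mutant_dynamics(
    p: EvoParams,
    t_end: float,
    *,
    lag_h: float = 0.0,
    n_total0: float = 1e5,
    n_points: int = 201,
):
    """Mutant fraction over a batch growth cycle in excess metabolite.

    During the lag the population is frozen; afterwards both genotypes grow
    exponentially at their fixed birth rates, with a fraction ``mu`` of
    ancestor births converted into mutants:

        dN_anc/dt = (1 - mu) b_anc N_anc
        dN_mut/dt = b_mut N_mut + mu b_anc N_anc

    Returns ``(t, fraction)`` arrays covering lag + exponential phase.
    """
    if p.anc_birth_rate is None or p.mut_birth_rate is None:
        raise ParameterError("batch dynamics needs fixed anc/mut birth rates")
    b_a, b_m, mu = p.anc_birth_rate, p.mut_birth_rate, p.mu
    n_mut0 = p.initial_fraction * n_total0
    n_anc0 = n_total0 - n_mut0

    def rhs(t, y):
        na, nm = y
        return [(1.0 - mu) * b_a * na, b_m * nm + mu * b_a * na]

    t_grow = max(t_end - lag_h, 0.0)
    t_eval = np.linspace(0.0, t_grow, n_points)
    sol = solve_ivp(rhs, (0.0, t_grow), [n_anc0, n_mut0], t_eval=t_eval,
                    rtol=1e-10, atol=1e-6)
    if not sol.success:
        raise SolverFailure(f"batch mutant dynamics failed: {sol.message}")
    t = sol.t + lag_h
    frac = sol.y[1] / (sol.y[0] + sol.y[1])
    if lag_h > 0:
        t = np.concatenate([[0.0], t])
        frac = np.concatenate([[p.initial_fraction], frac])
    return t, frac


def simulate_chemostat_competition(
    p: EvoParams,
    cfg: ChemostatConfig,
    t_end: float,
    *,
    n_total0: float = 1e5,
    n_points: int = 201,
    rtol: float = 1e-8,
):
    """Two genotypes competing for one limiting metabolite in a chemostat.

    Extends the single-strain chemostat equations with genotype-specific
    Moser birth laws and the ancestor-to-mutant conversion term:

        dN_a/dt = ((1-mu) b_a(S) - d_a - dil) N_a
        dN_m/dt = (b_m(S) - d_m - dil) N_m + mu b_a(S) N_a
        dS/dt   = (S0 - S) dil - (c_a b_a N_a + c_m b_m N_m) 1e-6

    Returns ``(t, mutant_fraction, limiting_uM)``.
    """
    if p.anc_birth is None or p.mut_birth is None:
        raise ParameterError("competition needs Moser birth laws for both genotypes")
    c_a = p.anc_consumption if p.anc_consumption is not None else 1.0
    c_m = p.mut_consumption if p.mut_consumption is not None else c_a
    mu, dil = p.mu, cfg.dil
    n_m0 = p.initial_fraction * n_total0
    n_a0 = n_total0 - n_m0

    def rhs(t, y):
        na, nm, S = y
        b_a = moser_birth_rate(max(S, 0.0), p.anc_birth)
        b_m = moser_birth_rate(max(S, 0.0), p.mut_birth)
        births_a = b_a * max(na, 0.0)
        births_m = b_m * max(nm, 0.0)
        return [
            (1.0 - mu) * births_a - (p.anc_death + dil) * na,
            births_m + mu * births_a - (p.mut_death + dil) * nm,
            (cfg.reservoir_uM - S) * dil
            - (c_a * births_a + c_m * births_m) * UM_PER_FMOL_PER_ML,
        ]

    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(rhs, (0.0, t_end), [n_a0, n_m0, cfg.init_limiting_uM],
                    method="LSODA", t_eval=t_eval, rtol=rtol, atol=1e-10)
    if not sol.success:
        raise SolverFailure(f"chemostat competition failed: {sol.message}")
    y = np.clip(sol.y, 0.0, None)
    frac = y[1] / np.clip(y[0] + y[1], 1e-300, None)
    return sol.t, frac, y[2]


def fitness_advantage_from_ratio(times, fractions) -> EstimateWithCI:
    """Fitness difference (per h) from the log-ratio of two competing types.

    For E (focal) and A (reference) growing exponentially,
    ln(E/A) is linear in time with slope r_E - r_A; given fractions f, the
    ratio is f/(1-f).  Fractions must lie strictly inside (0, 1).
    """
    times = np.asarray(times, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if np.any(f <= 0) or np.any(f >= 1):
        raise ParameterError("fractions must be strictly inside (0, 1)")
    log_ratio = np.log(f / (1.0 - f))
    if len(times) == 2:
        slope = (log_ratio[1] - log_ratio[0]) / (times[1] - times[0])
        return EstimateWithCI(value=float(slope), sem=0.0,
                              method="two-point log-ratio", n_points=2)
    est = fit_log_linear(times, f / (1.0 - f))
    est.method = "log-ratio OLS"
    return est


def initial_mutant_frequency(f_obs: float, fitness_diff: float, t: float) -> float:
    """Back-extrapolated initial mutant frequency f0 = f_obs / exp(s t).

    Under exponential outgrowth at fitness advantage s (per h) for t hours,
    an observed frequency f_obs implies the founding frequency f0.
    """
    if f_obs <= 0 or fitness_diff < 0 or t < 0:
        raise ParameterError("inputs must be positive (t, s >= 0)")
    return f_obs / math.exp(fitness_diff * t)


def expected_preexisting_mutants(n_pop: float, rate_range) -> tuple[float, float]:
    """Expected pre-existing mutant count range 2 * N * rate.

    In a culture grown from a single cell to N cells the total number of
    mutation opportunities is (1 + 2 + ... + 2^n) ~ 2 * 2^n = 2N, so a
    phenotypic mutation rate per cell per generation translates into
    2 N rate expected pre-existing mutants.
    """
    if n_pop <= 0:
        raise ParameterError("population size must be > 0")
    lo, hi = rate_range
    if lo < 0 or hi < lo:
        raise ParameterError("rate range must satisfy 0 <= lo <= hi")
    return 2.0 * n_pop * lo, 2.0 * n_pop * hi
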