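"""Single-strain chemostat dynamics and phenotype estimators.

In a metabolite-limited chemostat, fresh medium at reservoir concentration
S0 flows in at a fixed dilution rate while culture flows out at the same
rate.  With live density N, dead density Ndead, limiting metabolite S and
released metabolite M (all in the package units):

    dN/dt     = (b(S) - d - dil) N
    dNdead/dt = d N - dil Ndead
    dS/dt     = (S0 - S) dil - c b(S) N 1e-6
    dM/dt     = r N 1e-6 - dil M              (release by live cells)
    dM/dt     = r_d d N 1e-6 - dil M          (release upon death)

At steady state the net growth rate equals the dilution rate, and the four
balances invert into estimators for consumption per birth, death rate and
release rate.  Regression estimators use the exponentially weighted
integral of live density, which linearises the pre-steady-state dynamics.

Batch-culture estimators (consumption in exponential and saturated
cultures, the release-rate upper bound in excess metabolite, and the
dead/live death-rate ratio) live here too, as does the live-vs-dead
release-mode discrimination used on starvation time courses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .params import (
    UM_PER_FMOL_PER_ML,
    EstimateWithCI,
    ParameterError,
    StrainPhenotype,
)
from .wellmixed import SolverFailure, moser_birth_rate

__all__ = [
    "ChemostatConfig",
    "ChemostatSeries",
    "ReleaseModeReport",
    "dilution_rate_from_doubling",
    "simulate_chemostat",
    "steady_state_window",
    "estimate_consumption_ss",
    "estimate_death_ss",
    "estimate_release_ss",
    "exp_weighted_integral",
    "estimate_release_regression",
    "estimate_death_regression",
    "compare_release_models",
    "dead_release_required",
    "dead_release_concentration",
    "estimate_consumption_exponential",
    "estimate_consumption_saturation",
    "release_rate_upper_bound",
    "batch_death_rate",
]


def dilution_rate_from_doubling(volume_ml: float, doubling_h: float):
    """Pump flow rate (mL/h) and dilution rate (per h) for a target doubling.

    flow = V ln(2)/T; dil = ln(2)/T.  A 19-mL vessel at an 8-h doubling
    needs 19 * ln(2)/8 = 1.646 mL/h.
    """
    if volume_ml <= 0 or doubling_h <= 0:
        raise ParameterError("volume and doubling time must be > 0")
    dil = math.log(2.0) / doubling_h
    return volume_ml * dil, dil


@dataclass
class ChemostatConfig:
    """Vessel and feed configuration for a single-strain chemostat run.

    Either ``dil`` (per h) or ``doubling_h`` must be given.  ``release_mode``
    selects whether the partner metabolite is released by live cells at a
    constant per-cell rate or liberated in a fixed amount per cell death
    (``dead_release_fmole`` per death).
    """

    reservoir_uM: float
    dil: float | None = None
    doubling_h: float | None = None
    volume_ml: float = 19.0
    release_mode: str = "live"
    dead_release_fmole: float | None = None
    init_live: float = 1e5
    init_dead: float = 0.0
    init_limiting_uM: float = 0.0
    init_released_uM: float = 0.0

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ParameterError("vessel volume must be > 0")
        if self.reservoir_uM < 0:
            raise ParameterError("reservoir concentration must be >= 0")
        if self.dil is None:
            if self.doubling_h is None:
                raise ParameterError("give either dil or doubling_h")
            _, self.dil = dilution_rate_from_doubling(self.volume_ml, self.doubling_h)
        if self.dil <= 0:
            raise ParameterError("dilution rate must be > 0")
        if self.release_mode not in ("live", "dead"):
            raise ParameterError("release_mode must be 'live' or 'dead'")
        if self.release_mode == "dead" and self.dead_release_fmole is None:
            raise ParameterError("dead release mode needs dead_release_fmole")

    @property
    def flow_ml_per_h(self) -> float:
        return self.volume_ml * self.dil


@dataclass
class ChemostatSeries:
    """Time course of a chemostat run (or a starvation assay with dil=0)."""

    t: np.ndarray
    live: np.ndarray
    dead: np.ndarray
    limiting_uM: np.ndarray
    released_uM: np.ndarray
    dil: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ParameterError("series times must be strictly increasing")
        for name in ("live", "dead", "limiting_uM", "released_uM"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))


def simulate_chemostat(
    strain: StrainPhenotype,
    cfg: ChemostatConfig,
    t_end: float,
    *,
    times=None,
    n_points: int = 201,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "LSODA",
) -> ChemostatSeries:
    """Integrate the chemostat ODEs for one strain.

    The strain's ``release`` attribute must be a fixed rate (fmole/cell/h)
    for live-release mode; in dead-release mode the per-death amount comes
    from the config and the strain's release attribute is ignored.
    ``times`` overrides the uniform output grid with explicit sampling times.
    """
    if t_end <= 0:
        raise ParameterError("t_end must be > 0")
    r_live = float(strain.release) if isinstance(strain.release, (int, float)) else 0.0
    dil, d, c = cfg.dil, strain.death_rate, strain.consumption
    dead_mode = cfg.release_mode == "dead"
    r_d = cfg.dead_release_fmole or 0.0

    def rhs(t, y):
        N, Nd, S, M = y
        b = moser_birth_rate(max(S, 0.0), strain.birth)
        births = b * max(N, 0.0)
        release = (r_d * d * max(N, 0.0)) if dead_mode else (r_live * max(N, 0.0))
        return [
            births - (d + dil) * N,
            d * max(N, 0.0) - dil * Nd,
            (cfg.reservoir_uM - S) * dil - c * births * UM_PER_FMOL_PER_ML,
            release * UM_PER_FMOL_PER_ML - dil * M,
        ]

    y0 = [cfg.init_live, cfg.init_dead, cfg.init_limiting_uM, cfg.init_released_uM]
    t_eval = np.asarray(times, dtype=float) if times is not None else np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(rhs, (0.0, t_end), y0, method=method, t_eval=t_eval,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise SolverFailure(f"chemostat integration failed: {sol.message}",
                            last_state=sol.y[:, -1] if sol.y.size else y0)
    y = np.clip(sol.y, 0.0, None)
    return ChemostatSeries(t=sol.t, live=y[0], dead=y[1], limiting_uM=y[2],
                           released_uM=y[3], dil=dil)


def steady_state_window(series: ChemostatSeries, *, rel_change: float = 0.05) -> np.ndarray:
    """Boolean mask of the steady-state portion of a chemostat series.

    The window is the final third of the series after the first point where
    the live density changes by less than ``rel_change`` per sampling
    interval; falls back to the final third if no such point exists.
    """
    live = series.live
    rel = np.abs(np.diff(live)) / np.clip(live[:-1], 1e-300, None)
    settled = np.nonzero(rel < rel_change)[0]
    start = settled[0] + 1 if settled.size else 0
    start = max(start, (2 * len(live)) // 3)
    mask = np.zeros(len(live), dtype=bool)
    mask[start:] = True
    return mask


def estimate_consumption_ss(reservoir_uM, dil, limiting_ss_uM, birth_rate, live_ss):
    """Consumption per birth from steady-state balances (fmole/cell).

    Returns ``(exact, approximate)``: the exact inversion
    (S0 - S_ss) dil/(b N_ss) and the approximation S0/N_ss valid when the
    residual concentration is negligible and b ~ dil.
    """
    if live_ss <= 0:
        raise ParameterError("steady-state live density must be > 0")
    exact = (reservoir_uM - limiting_ss_uM) * dil / (birth_rate * live_ss) / UM_PER_FMOL_PER_ML
    approx = reservoir_uM / live_ss / UM_PER_FMOL_PER_ML
    return exact, approx


def estimate_death_ss(dil, dead_ss, live_ss) -> float:
    """Death rate (per h) from steady-state dead/live densities: dil * dead/live."""
    if live_ss <= 0:
        raise ParameterError("steady-state live density must be > 0")
    return dil * dead_ss / live_ss


def estimate_release_ss(dil, released_ss_uM, live_ss) -> float:
    """Release rate (fmole/cell/h) from the steady-state released metabolite."""
    if live_ss <= 0:
        raise ParameterError("steady-state live density must be > 0")
    return dil * released_ss_uM / live_ss / UM_PER_FMOL_PER_ML


def exp_weighted_integral(t, f, dil) -> np.ndarray:
    """Running trapezoid integral of f(tau) e^(dil tau) from 0 to each t.

    The integral is 0 at the first point; each increment is
    dt (w(t)f(t) + w(t+dt)f(t+dt))/2 with w = e^(dil t), exactly the
    composite rule applied to sampled data.
    """
    t = np.asarray(t, dtype=float)
    f = np.asarray(f, dtype=float)
    if len(t) < 2:
        raise ParameterError("integral needs >= 2 points")
    if np.any(np.diff(t) <= 0):
        raise ParameterError("times must be strictly increasing")
    g = f * np.exp(dil * t)
    out = np.zeros_like(g)
    out[1:] = np.cumsum(np.diff(t) * (g[1:] + g[:-1]) / 2.0)
    return out


def _origin_regression(x, y):
    """Through-origin OLS: slope, slope sem, and R^2 about zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = np.sum(x * x)
    if sxx == 0:
        raise ParameterError("degenerate regressor (all zero)")
    slope = np.sum(x * y) / sxx
    resid = y - slope * x
    n = len(x)
    sem = math.sqrt(np.sum(resid**2) / max(n - 1, 1) / sxx)
    ss_tot = np.sum(y * y)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(sem), float(r2)


def _free_regression(x, y):
    """OLS with intercept: slope, intercept, slope sem, R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise ParameterError("degenerate regressor (constant)")
    X = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    s2 = np.sum(resid**2) / max(n - 2, 1)
    sem = math.sqrt(s2 / sxx)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return float(coef[1]), float(coef[0]), float(sem), float(r2)


def estimate_release_regression(series: ChemostatSeries, dil: float | None = None) -> EstimateWithCI:
    """Release rate from regression of M e^(dil t) on the weighted live integral.

    Uses the whole series (pre-steady-state included).  The regression is
    through the origin because the released metabolite starts at zero (or
    must be baseline-subtracted first).  With dil = 0 this reduces to the
    starvation estimator: M against the plain integral of live density.
    """
    dil = series.dil if dil is None else dil
    if len(series.t) < 3:
        raise ParameterError("regression needs >= 3 points")
    x = exp_weighted_integral(series.t, series.live, dil)
    y = series.released_uM * np.exp(dil * series.t) / UM_PER_FMOL_PER_ML
    slope, sem, r2 = _origin_regression(x, y)
    return EstimateWithCI(value=slope, sem=sem, method="release regression (origin)",
                          slope=slope, intercept=0.0, r_squared=r2, n_points=len(x))


def estimate_death_regression(series: ChemostatSeries, dil: float | None = None) -> EstimateWithCI:
    """Death rate from regression of Ndead e^(dil t) on the weighted live integral.

    The intercept is free (it estimates the initial dead density)."""
    dil = series.dil if dil is None else dil
    if len(series.t) < 3:
        raise ParameterError("regression needs >= 3 points")
    x = exp_weighted_integral(series.t, series.live, dil)
    y = series.dead * np.exp(dil * series.t)
    slope, intercept, sem, r2 = _free_regression(x, y)
    return EstimateWithCI(value=slope, sem=sem, method="death regression",
                          slope=slope, intercept=intercept, r_squared=r2,
                          n_points=len(x))


@dataclass
class ReleaseModeReport:
    """Live-vs-dead release discrimination on a starvation time course."""

    live_slope: float          # fmole/cell/h if live release holds
    live_r2: float | None
    dead_slope: float          # fmole released per death if dead release holds
    dead_r2: float | None
    preferred: str             # 'live' | 'dead' | 'indeterminate'


def compare_release_models(t, live, dead, metabolite_uM, *, tie_tol: float = 1e-6) -> ReleaseModeReport:
    """Fit both release models to a starvation series and flag the better one.

    Live model: metabolite scales linearly with live density integrated over
    time (through-origin fit; slope = release rate, fmole/cell/h).  Dead
    model: metabolite scales linearly with dead density (slope = fmole
    liberated per death).  Linearity is scored by R^2 (computed about zero
    for the origin-constrained live model).  If the two R^2 values differ by
    less than ``tie_tol`` the report flags the comparison as indeterminate
    (this happens exactly when dead density is proportional to the live
    integral, e.g. constant death rate without dilution).
    """
    t = np.asarray(t, dtype=float)
    if len(t) < 4:
        raise ParameterError("model comparison needs >= 4 points")
    y = np.asarray(metabolite_uM, dtype=float) / UM_PER_FMOL_PER_ML
    x_live = exp_weighted_integral(t, live, 0.0)
    live_slope = live_r2 = None
    try:
        live_slope, _, live_r2 = _origin_regression(x_live, y)
    except ParameterError:
        pass
    dead_slope = dead_r2 = None
    try:
        dead_slope, _, _, dead_r2 = _free_regression(np.asarray(dead, dtype=float), y)
    except ParameterError:
        pass
    if live_r2 is None and dead_r2 is None:
        raise ParameterError("both regressors degenerate")
    if live_r2 is None:
        preferred = "dead"
    elif dead_r2 is None:
        preferred = "live"
    elif abs(live_r2 - dead_r2) < tie_tol:
        preferred = "indeterminate"
    else:
        preferred = "live" if live_r2 > dead_r2 else "dead"
    return ReleaseModeReport(
        live_slope=live_slope if live_slope is not None else math.nan,
        live_r2=live_r2,
        dead_slope=dead_slope if dead_slope is not None else math.nan,
        dead_r2=dead_r2,
        preferred=preferred,
    )


def dead_release_required(metabolite_uM: float, dead_density: float) -> float:
    """Per-cell content (fmole/cell) dead cells would need to explain a
    supernatant concentration: M / (dead density * 1e-6)."""
    if dead_density <= 0:
        raise ParameterError("dead density must be > 0")
    return metabolite_uM / (dead_density * UM_PER_FMOL_PER_ML)


def dead_release_concentration(content_fmole: float, dead_density: float) -> float:
    """Forward plausibility check: concentration (uM) if every dead cell
    liberated its measured content: content * density * 1e-6."""
    return content_fmole * dead_density * UM_PER_FMOL_PER_ML


def estimate_consumption_exponential(
    density, metabolite_uM, *, floor_uM: float = 10.0
) -> EstimateWithCI:
    """Consumption per birth from an exponential batch culture (fmole/cell).

    In excess metabolite, M(t) - M(0) = -c (N(t) - N(0)), so the slope of M
    against N is -c.  Points where the metabolite has dropped below
    ``floor_uM`` are excluded (the linear relation is only trusted above
    that floor); excluded points trigger a warning.
    """
    density = np.asarray(density, dtype=float)
    metabolite_uM = np.asarray(metabolite_uM, dtype=float)
    keep = metabolite_uM >= floor_uM
    if keep.sum() < 2:
        raise ParameterError(f"all points below the {floor_uM} uM validity floor")
    if not keep.all():
        warnings.warn(
            f"excluded {int((~keep).sum())} point(s) below the "
            f"{floor_uM} uM consumption validity floor", stacklevel=2)
    slope, intercept, sem, r2 = _free_regression(density[keep], metabolite_uM[keep])
    c = -slope / UM_PER_FMOL_PER_ML
    return EstimateWithCI(value=c, sem=sem / UM_PER_FMOL_PER_ML,
                          method="exponential batch consumption",
                          slope=slope, intercept=intercept, r_squared=r2,
                          n_points=int(keep.sum()))


def estimate_consumption_saturation(input_uM, final_density) -> EstimateWithCI:
    """Consumption per birth from saturated-culture yields (fmole/cell).

    Through-origin regression of final total density on input metabolite
    concentration; consumption is 1/slope (unit-converted).
    """
    input_uM = np.asarray(input_uM, dtype=float)
    final_density = np.asarray(final_density, dtype=float)
    if len(input_uM) < 2 or len(np.unique(input_uM)) < 2:
        raise ParameterError("need >= 2 distinct input concentrations")
    slope, sem, r2 = _origin_regression(input_uM, final_density)
    if slope <= 0:
        raise ParameterError("non-positive yield slope")
    c = 1.0 / (slope * UM_PER_FMOL_PER_ML)
    return EstimateWithCI(value=c, sem=sem / slope * c, method="saturation yield",
                          slope=slope, intercept=0.0, r_squared=r2,
                          n_points=len(input_uM))


def release_rate_upper_bound(metabolite_uM: float, growth_rate: float, density: float) -> float:
    """Upper bound on release in an exponentially growing culture (fmole/cell/h).

    Integrating dM/dt = r N along N(t) = N(0) e^(gt) gives
    M(T) ~ (r/g) N(T) when N(T) >> N(0), so r = g M(T)/N(T).  With the
    assay sensitivity as M(T) the result bounds an undetectable release.
    """
    if growth_rate <= 0 or density <= 0:
        raise ParameterError("growth rate and density must be > 0")
    return growth_rate * metabolite_uM / (density * UM_PER_FMOL_PER_ML)


def batch_death_rate(dead_live_ratio: float, net_growth: float) -> float:
    """Death rate in a non-limited batch culture (per h).

    In balanced exponential growth the dead/live ratio equals the ratio of
    death rate to net growth rate, so d = g * dead/live.
    """
    if net_growth <= 0:
        raise ParameterError("net growth rate must be > 0")
    if dead_live_ratio < 0:
        raise ParameterError("dead/live ratio must be >= 0")
    return net_growth * dead_live_ratio
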