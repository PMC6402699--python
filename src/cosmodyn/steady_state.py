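"""Closed-form steady-state community growth rate and its uncertainty.

At steady state both strains grow at the community rate g_comm and the two
metabolite balances combine into

    r_A r_L = c_A c_L (g + d_L)(g + d_A),

whose positive solution is

    g = -(d_A + d_L)/2 + sqrt(r_A r_L/(c_A c_L) + (d_A - d_L)^2/4).

Because the death-rate asymmetry term is tiny for the measured strains, the
working approximation drops it:

    g ~ -(d_A + d_L)/2 + sqrt(r_A r_L/(c_A c_L)).

When the lysine release rate depends linearly on the releasing strain's net
growth rate, substituting r_L(g) into the approximation yields a monic
quadratic g^2 + B g - C = 0 whose positive root is the self-consistent
community growth rate.  Uncertainty is propagated through the approximation
by the variance formula with analytic partial derivatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .params import LinearReleaseLaw, ParameterError

__all__ = [
    "GrowthPrediction",
    "gcomm_exact",
    "gcomm_approx",
    "variable_release_quadratic",
    "gcomm_variable_release",
    "doubling_time",
    "gcomm_partials",
    "propagate_error",
]

_PARAMS = ("d_A", "d_L", "r_A", "r_L", "c_A", "c_L")


@dataclass
class GrowthPrediction:
    """Predicted community growth rate with propagated uncertainty.

    ``terms`` maps each parameter name to its contribution
    (dg/dx_i * s_i)^2 to the variance; the contributions sum to sem^2.
    """

    g_comm: float
    sem: float
    terms: dict[str, float] = field(default_factory=dict)

    @property
    def doubling_time(self) -> float:
        return doubling_time(self.g_comm)

    @property
    def ci95_halfwidth(self) -> float:
        return 2.0 * self.sem


def _check(d_A, d_L, r_A, r_L, c_A, c_L) -> None:
    if c_A <= 0 or c_L <= 0:
        raise ParameterError("consumption per birth must be > 0")
    if r_A < 0 or r_L < 0:
        raise ParameterError("release rates must be >= 0")
    if d_A < 0 or d_L < 0:
        raise ParameterError("death rates must be >= 0")


def gcomm_exact(d_A, d_L, r_A, r_L, c_A, c_L) -> float:
    """Exact steady-state community growth rate (per h)."""
    _check(d_A, d_L, r_A, r_L, c_A, c_L)
    return -(d_A + d_L) / 2.0 + math.sqrt(
        r_A * r_L / (c_A * c_L) + (d_A - d_L) ** 2 / 4.0
    )


def gcomm_approx(d_A, d_L, r_A, r_L, c_A, c_L) -> float:
    """Community growth rate with the death-asymmetry term dropped (per h).

    Always <= :func:`gcomm_exact`; equal iff d_A == d_L.  The absolute
    difference is bounded by (d_A-d_L)^2 / (8 sqrt(r_A r_L/(c_A c_L))).
    """
    _check(d_A, d_L, r_A, r_L, c_A, c_L)
    return -(d_A + d_L) / 2.0 + math.sqrt(r_A * r_L / (c_A * c_L))


def variable_release_quadratic(d_A, d_L, r_A, c_A, c_L, law: LinearReleaseLaw):
    """Coefficients (B, C) of g^2 + B g - C = 0 for a linear release law.

    Substituting r_L = intercept + slope*g into the approximate balance and
    expanding (g + (d_A+d_L)/2)^2 = r_A/(c_A c_L) (intercept + slope g)
    gives the monic quadratic with

        B = (d_A + d_L) - slope * r_A/(c_A c_L)
        C = intercept * r_A/(c_A c_L) - ((d_A + d_L)/2)^2
    """
    _check(d_A, d_L, r_A, max(law.intercept, 0.0), c_A, c_L)
    k = r_A / (c_A * c_L)
    B = (d_A + d_L) - law.slope * k
    C = law.intercept * k - ((d_A + d_L) / 2.0) ** 2
    return B, C


def gcomm_variable_release(d_A, d_L, r_A, c_A, c_L, law: LinearReleaseLaw) -> float:
    """Self-consistent community growth rate under a linear r_L(g) law.

    Returns the larger root of the monic quadratic; raises if no positive
    real root exists (the community cannot sustain growth).
    """
    B, C = variable_release_quadratic(d_A, d_L, r_A, c_A, c_L, law)
    disc = B * B + 4.0 * C
    if disc < 0:
        raise ParameterError("no real root: community cannot sustain growth")
    g = (-B + math.sqrt(disc)) / 2.0
    if g <= 0:
        raise ParameterError("no positive root: community cannot sustain growth")
    return g


def doubling_time(g: float) -> float:
    """Doubling time ln(2)/g in hours for a positive exponential rate g."""
    if g <= 0:
        raise ParameterError("growth rate must be > 0 for a doubling time")
    return math.log(2.0) / g


def gcomm_partials(d_A, d_L, r_A, r_L, c_A, c_L) -> dict[str, float]:
    """Analytic partial derivatives of the approximate growth rate.

    dg/dd_A = dg/dd_L = -1/2;
    dg/dr_A = sqrt(r_L/(c_A c_L r_A))/2   (and symmetrically for r_L);
    dg/dc_A = -sqrt(r_A r_L/(c_L c_A^3))/2 (and symmetrically for c_L).
    """
    _check(d_A, d_L, r_A, r_L, c_A, c_L)
    if r_A == 0 or r_L == 0:
        raise ParameterError("partials require positive release rates")
    return {
        "d_A": -0.5,
        "d_L": -0.5,
        "r_A": 0.5 * math.sqrt(r_L / (c_A * c_L * r_A)),
        "r_L": 0.5 * math.sqrt(r_A / (c_A * c_L * r_L)),
        "c_A": -0.5 * math.sqrt(r_A * r_L / (c_L * c_A**3)),
        "c_L": -0.5 * math.sqrt(r_A * r_L / (c_A * c_L**3)),
    }


def propagate_error(values: dict[str, float], sems: dict[str, float]) -> GrowthPrediction:
    """Variance-formula error propagation through the approximate rate.

    ``values`` and ``sems`` must provide the six parameters ``d_A, d_L,
    r_A, r_L, c_A, c_L`` (r_L fixed at a measured chemostat value, not the
    variable-release law).  Returns the prediction with per-parameter
    variance contributions; sem^2 = sum of contributions.
    """
    missing = [k for k in _PARAMS if k not in values or k not in sems]
    if missing:
        raise ParameterError(f"missing parameters for propagation: {missing}")
    if any(sems[k] < 0 for k in _PARAMS):
        raise ParameterError("SEMs must be >= 0")
    args = [values[k] for k in _PARAMS]
    g = gcomm_approx(*args)
    partials = gcomm_partials(*args)
    terms = {k: (partials[k] * sems[k]) ** 2 for k in _PARAMS}
    return GrowthPrediction(g_comm=g, sem=math.sqrt(sum(terms.values())), terms=terms)
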