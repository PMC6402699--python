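"""Synthetic measurement generators for testing the estimators end to end.

Latent time courses come from the package's own forward models; observed
values multiply the latent ones by independent mean-one lognormal noise
whose coefficient of variation emulates flow-cytometry density counts
(CV ~5-10%) and metabolite bioassays (CV ~10%).  Noise is independent
across time points and channels.  Every generator is deterministic under a
fixed seed, records the seed and the generating truth in the series
metadata, and reduces to the noiseless latent model at CV = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemostat import ChemostatConfig, ChemostatSeries, simulate_chemostat
from .params import UM_PER_FMOL_PER_ML, CommunityState, ParameterError, StrainPhenotype
from .wellmixed import Trajectory, simulate_wellmixed

__all__ = [
    "NoiseModel",
    "generate_chemostat_series",
    "generate_starvation_series",
    "generate_cosmo_trajectory",
]


@dataclass
class NoiseModel:
    """Multiplicative measurement noise for densities and metabolite assays."""

    density_cv: float = 0.075
    metabolite_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density_cv < 0 or self.metabolite_cv < 0:
            raise ParameterError("CVs must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    @staticmethod
    def _factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
        """Mean-one lognormal multipliers with the requested CV."""
        if cv == 0:
            return np.ones(size)
        sigma = np.sqrt(np.log1p(cv**2))
        return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=size)

    def perturb_density(self, rng, x) -> np.ndarray:
        return np.asarray(x, dtype=float) * self._factors(rng, self.density_cv, np.shape(x))

    def perturb_metabolite(self, rng, x) -> np.ndarray:
        return np.asarray(x, dtype=float) * self._factors(rng, self.metabolite_cv, np.shape(x))


def generate_chemostat_series(
    strain: StrainPhenotype,
    cfg: ChemostatConfig,
    times,
    noise: NoiseModel,
) -> ChemostatSeries:
    """Noisy observed chemostat series at the requested sampling times.

    The latent series solves the chemostat ODEs exactly at the sampling
    times; the returned metadata embeds the generating truth (release,
    death, consumption) and the noise seed.
    """
    times = np.asarray(times, dtype=float)
    latent = simulate_chemostat(strain, cfg, float(times[-1]), times=times)
    rng = noise.rng()
    series = ChemostatSeries(
        t=times,
        live=noise.perturb_density(rng, latent.live),
        dead=noise.perturb_density(rng, latent.dead),
        limiting_uM=noise.perturb_metabolite(rng, latent.limiting_uM),
        released_uM=noise.perturb_metabolite(rng, latent.released_uM),
        dil=cfg.dil,
        metadata={
            "seed": noise.seed,
            "truth": {
                "release": float(strain.release) if isinstance(strain.release, (int, float)) else None,
                "death_rate": strain.death_rate,
                "consumption": strain.consumption,
            },
        },
    )
    return series


def generate_starvation_series(
    mode: str,
    *,
    n0: float = 1e6,
    death_rate: float = 0.005,
    late_death_rate: float | None = 0.02,
    death_switch_h: float = 12.0,
    release_rate: float | None = None,
    release_per_death: float | None = None,
    times=None,
    noise: NoiseModel | None = None,
) -> ChemostatSeries:
    """Starving population (no births) with accumulating released metabolite.

    Death follows the two-phase pattern seen in starved auxotrophs: a slow
    early rate (``death_rate``) switching to a faster late rate
    (``late_death_rate``) at ``death_switch_h``.  Pass
    ``late_death_rate=None`` for a constant rate; note that with a constant
    rate the dead density is exactly proportional to the time-integrated
    live density, so live and dead release are mathematically
    indistinguishable -- the two-phase default is what makes the
    release-mode comparison informative.  Latent dynamics are closed-form:
    live decays piecewise-exponentially, dead accumulates the deaths, and
    the metabolite integrates the live curve (live mode, ``release_rate``
    fmole/cell/h) or tracks the dead density (dead mode,
    ``release_per_death`` fmole).  Default cadence: every 6 h to 24 h.
    """
    if mode not in ("live", "dead"):
        raise ParameterError("mode must be 'live' or 'dead'")
    if mode == "live" and release_rate is None:
        raise ParameterError("live mode needs release_rate (fmole/cell/h)")
    if mode == "dead" and release_per_death is None:
        raise ParameterError("dead mode needs release_per_death (fmole)")
    t = np.asarray(times if times is not None else np.arange(0.0, 24.1, 6.0), dtype=float)
    d1 = death_rate
    d2 = d1 if late_death_rate is None else late_death_rate
    ts = death_switch_h
    early = np.minimum(t, ts)
    late = np.maximum(t - ts, 0.0)
    live = n0 * np.exp(-d1 * early - d2 * late)
    dead = n0 - live

    def _phase_integral(d, t0, tau):
        # integral of e^(-d s) ds over [0, tau], scaled by survival to t0
        return tau if d == 0 else (1.0 - np.exp(-d * tau)) / d

    surv_switch = np.exp(-d1 * ts)
    integral = np.where(
        t <= ts,
        n0 * _phase_integral(d1, 0.0, early),
        n0 * (_phase_integral(d1, 0.0, ts) + surv_switch * _phase_integral(d2, ts, late)),
    )
    if mode == "live":
        metabolite = release_rate * integral * UM_PER_FMOL_PER_ML
    else:
        metabolite = release_per_death * dead * UM_PER_FMOL_PER_ML
    noise = noise or NoiseModel(density_cv=0.0, metabolite_cv=0.0)
    rng = noise.rng()
    return ChemostatSeries(
        t=t,
        live=noise.perturb_density(rng, live),
        dead=noise.perturb_density(rng, dead),
        limiting_uM=np.zeros_like(t),
        released_uM=noise.perturb_metabolite(rng, metabolite),
        dil=0.0,
        metadata={"seed": noise.seed, "truth": {
            "mode": mode, "death_rate": d1, "late_death_rate": d2,
            "death_switch_h": ts,
            "release_rate": release_rate, "release_per_death": release_per_death,
            "latent_live": live, "latent_dead": dead,
            "latent_metabolite": metabolite}},
    )


def generate_cosmo_trajectory(
    lys_consumer: StrainPhenotype,
    hyp_consumer: StrainPhenotype,
    init: CommunityState,
    t_end: float,
    *,
    noise: NoiseModel | None = None,
    dilution_threshold: float | None = None,
    dilution_factor: float = 10.0,
    sample_every_h: float = 2.0,
    rtol: float = 1e-8,
) -> Trajectory:
    """Well-mixed community growth curve with threshold-triggered dilutions.

    Whenever the total live density exceeds ``dilution_threshold``
    (cells/mL) at a sampling time, cells and metabolites are diluted by
    ``dilution_factor`` (fresh-medium dilution) and the cumulative factor is
    recorded, so accumulative densities can be reconstructed downstream.
    Observed densities carry multiplicative noise; the latent noiseless
    trajectory is embedded in the metadata.
    """
    noise = noise or NoiseModel(density_cv=0.0, metabolite_cv=0.0)
    n_seg = max(int(round(t_end / sample_every_h)), 1)
    state = CommunityState(init.NL, init.NA, init.L, init.A, init.dead_NL, init.dead_NA)
    t_pts = [0.0]
    cols = {k: [getattr(state, k)] for k in ("NL", "NA", "L", "A", "dead_NL", "dead_NA")}
    factors = [1.0]
    cum = 1.0
    for i in range(n_seg):
        seg = simulate_wellmixed(lys_consumer, hyp_consumer, state, sample_every_h,
                                 n_points=11, rtol=rtol)
        state = CommunityState(
            NL=seg.NL[-1], NA=seg.NA[-1], L=seg.L[-1], A=seg.A[-1],
            dead_NL=seg.dead_NL[-1], dead_NA=seg.dead_NA[-1])
        if dilution_threshold is not None and state.NL + state.NA > dilution_threshold:
            cum *= dilution_factor
            state = CommunityState(
                NL=state.NL / dilution_factor, NA=state.NA / dilution_factor,
                L=state.L / dilution_factor, A=state.A / dilution_factor,
                dead_NL=state.dead_NL / dilution_factor,
                dead_NA=state.dead_NA / dilution_factor)
        t_pts.append((i + 1) * sample_every_h)
        for k in cols:
            cols[k].append(getattr(state, k))
        factors.append(cum)

    t_arr = np.asarray(t_pts)
    latent = {k: np.asarray(v) for k, v in cols.items()}
    rng = noise.rng()
    return Trajectory(
        t=t_arr,
        NL=noise.perturb_density(rng, latent["NL"]),
        NA=noise.perturb_density(rng, latent["NA"]),
        L=noise.perturb_metabolite(rng, latent["L"]),
        A=noise.perturb_metabolite(rng, latent["A"]),
        dead_NL=latent["dead_NL"], dead_NA=latent["dead_NA"],
        dilution_factor=np.asarray(factors),
        metadata={"seed": noise.seed, "latent": latent,
                  "dilution_factor": np.asarray(factors)},
    )
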