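"""Reduced-scale spatial community simulation on an agarose column.

The two strains sit in a single surface layer of a 3-D agar domain.
Metabolites diffuse through the agar (no-flux boundaries); in each time
step every surface grid element grows by Moser kinetics on its local
metabolite, consumes a fixed amount per birth and releases at a per-cell
rate, with the lysine release rate interpolated from the piecewise
concentration law at the local hypoxanthine concentration.  Cells are
represented as a continuum biomass density per surface element rather than
individuals: since consumption and release scale linearly with biomass,
the continuum limit is equivalent for community-level growth rates.

Explicit operator-split stepping: reaction then diffusion, with the time
step bounded by the 3-D diffusion stability (CFL) limit.  The grid may be
anisotropic (coarse vertical spacing through the agar column) to keep
reduced-scale runs fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import (
    UM_PER_FMOL_PER_ML,
    LinearReleaseLaw,
    ParameterError,
    PiecewiseReleaseLaw,
    StrainPhenotype,
)
from .wellmixed import moser_birth_rate

__all__ = ["SpatialConfig", "SpatialResult", "interpolate_release_rate", "simulate_spatial"]

_S_PER_H = 3600.0
_ML_PER_UM3 = 1e-12


def interpolate_release_rate(H, law: PiecewiseReleaseLaw):
    """Piecewise-linear release rate at local metabolite concentration H (uM).

    Linear between knots, clamped to the end values outside the knot range
    and to zero from below.
    """
    if not isinstance(law, PiecewiseReleaseLaw):
        raise ParameterError("interpolation needs a piecewise release law")
    return law.rate_at_H(H)


@dataclass
class SpatialConfig:
    """Geometry and physics of the agar domain.

    Lateral domain ``lateral_um`` x ``lateral_um`` at spacing ``dx_um``;
    depth ``depth_um`` at spacing ``dz_um`` (anisotropy is deliberate: the
    vertical metabolite gradient through centimetres of agar is shallow).
    Inoculation is uniform over the surface or a central square spot
    covering ``spot_fraction`` of the surface area.  ``D_community_um2_s``
    optionally replaces the agar diffusivity within the cell layer.
    """

    lateral_um: float = 200.0
    dx_um: float = 50.0
    depth_um: float = 5000.0
    dz_um: float = 500.0
    inoculation: str = "uniform"
    spot_fraction: float = 1.0 / 16.0
    D_agar_um2_s: float = 360.0
    D_community_um2_s: float | None = None
    surface_density_per_mm2: float = 3000.0
    dt_h: float | None = None
    cfl_safety: float = 0.9

    def __post_init__(self) -> None:
        if self.dx_um <= 0 or self.dz_um <= 0:
            raise ParameterError("grid spacings must be > 0")
        if self.D_agar_um2_s < 0:
            raise ParameterError("diffusion coefficient must be >= 0")
        if not 0 < self.spot_fraction <= 1:
            raise ParameterError("spot fraction must be in (0, 1]")
        if self.inoculation not in ("uniform", "spot"):
            raise ParameterError("inoculation must be 'uniform' or 'spot'")

    @property
    def shape(self) -> tuple[int, int, int]:
        n_lat = max(int(round(self.lateral_um / self.dx_um)), 1)
        n_z = max(int(round(self.depth_um / self.dz_um)), 1)
        return n_lat, n_lat, n_z

    @property
    def element_volume_ml(self) -> float:
        return self.dx_um**2 * self.dz_um * _ML_PER_UM3

    def max_stable_dt(self) -> float:
        """CFL bound for explicit 3-D diffusion on this (possibly
        anisotropic) grid, in hours."""
        D = max(self.D_agar_um2_s, self.D_community_um2_s or 0.0) * _S_PER_H
        if D == 0:
            return np.inf
        denom = 2.0 * D * (2.0 / self.dx_um**2 + 1.0 / self.dz_um**2)
        return self.cfl_safety / denom


@dataclass
class SpatialResult:
    """Growth curves and final metabolite fields from a spatial run."""

    t: np.ndarray
    total_L: np.ndarray       # total lysine-requiring cells on the pad
    total_A: np.ndarray       # total hypoxanthine-requiring cells
    L_field: np.ndarray       # final lysine field, uM, shape (nx, ny, nz)
    A_field: np.ndarray
    biomass_L: np.ndarray     # final cells per surface element
    biomass_A: np.ndarray
    dt_h: float
    metadata: dict = field(default_factory=dict)

    @property
    def total(self) -> np.ndarray:
        return self.total_L + self.total_A

    def metabolite_means(self, which: str = "A") -> tuple[float, float]:
        """(community mean, agar mean) of a metabolite at the final time.

        Community: surface-layer concentration averaged over elements
        carrying biomass; agar: average over all sub-surface elements.
        """
        f = self.A_field if which == "A" else self.L_field
        occupied = (self.biomass_L + self.biomass_A) > 0
        community = float(f[:, :, 0][occupied].mean())
        agar = float(f[:, :, 1:].mean()) if f.shape[2] > 1 else community
        return community, agar


def _diffuse(c: np.ndarray, D_layer: np.ndarray, dt: float, dx: float, dz: float) -> None:
    """One explicit flux-form diffusion step, in place; no-flux boundaries.

    ``D_layer`` gives the diffusivity of each z layer (um^2/h); face values
    are arithmetic means, so the summed flux over the domain is exactly
    zero and total mass is conserved to machine precision.
    """
    D = D_layer[np.newaxis, np.newaxis, :]
    for axis, h in ((0, dx), (1, dx), (2, dz)):
        grad = np.diff(c, axis=axis) / h
        sl = [slice(None)] * 3
        sl[axis] = slice(None, -1)
        D_lo = D if axis != 2 else D[:, :, :-1]
        sl_hi = [slice(None)] * 3
        sl_hi[axis] = slice(1, None)
        D_hi = D if axis != 2 else D[:, :, 1:]
        D_face = 0.5 * (np.broadcast_to(D_lo, grad.shape) + np.broadcast_to(D_hi, grad.shape))
        flux = D_face * grad
        c[tuple(sl)] += dt / h * flux
        c[tuple(sl_hi)] -= dt / h * flux


def simulate_spatial(
    lys_consumer: StrainPhenotype,
    hyp_consumer: StrainPhenotype,
    cfg: SpatialConfig,
    t_end: float,
    *,
    record_every_h: float = 0.5,
    init_L_uM: float = 0.0,
    init_A_uM: float = 0.0,
) -> SpatialResult:
    """Run the reduced-scale reaction-diffusion community simulation.

    Checks the CFL bound before running (a user-supplied ``dt_h`` above the
    bound is an error).  Births in an element are capped by the metabolite
    available there, so fields can never go negative.
    """
    if t_end <= 0:
        raise ParameterError("t_end must be > 0")
    nx, ny, nz = cfg.shape
    dt_max = cfg.max_stable_dt()
    dt = cfg.dt_h if cfg.dt_h is not None else min(dt_max, 0.01)
    if dt > dt_max:
        raise ParameterError(
            f"time step {dt} h violates the diffusion stability bound {dt_max:.3g} h")

    pL, pA = lys_consumer, hyp_consumer
    rA = float(pL.release) if isinstance(pL.release, (int, float)) else 0.0

    cells_per_element = cfg.surface_density_per_mm2 * (cfg.dx_um / 1000.0) ** 2
    B_L = np.zeros((nx, ny))
    B_A = np.zeros((nx, ny))
    if cfg.inoculation == "uniform":
        B_L[:] = cells_per_element / 2.0
        B_A[:] = cells_per_element / 2.0
    else:
        side = max(int(round(nx * np.sqrt(cfg.spot_fraction))), 1)
        lo = (nx - side) // 2
        B_L[lo:lo + side, lo:lo + side] = cells_per_element / 2.0
        B_A[lo:lo + side, lo:lo + side] = cells_per_element / 2.0

    L3 = np.full((nx, ny, nz), init_L_uM, dtype=float)
    A3 = np.full((nx, ny, nz), init_A_uM, dtype=float)
    D_layer = np.full(nz, cfg.D_agar_um2_s * _S_PER_H)
    if cfg.D_community_um2_s is not None:
        D_layer[0] = cfg.D_community_um2_s * _S_PER_H

    vol_ml = cfg.element_volume_ml
    fmole_to_uM = 1.0 / (vol_ml / UM_PER_FMOL_PER_ML)  # uM change per fmole in one element

    n_steps = int(np.ceil(t_end / dt))
    record_stride = max(int(round(record_every_h / dt)), 1)
    times, tot_L, tot_A = [0.0], [B_L.sum()], [B_A.sum()]

    for step in range(1, n_steps + 1):
        Ls = L3[:, :, 0]
        As = A3[:, :, 0]
        bL = moser_birth_rate(Ls, pL.birth)
        bA = moser_birth_rate(As, pA.birth)
        # births capped by locally available metabolite
        births_L = np.minimum(bL * B_L * dt, Ls / fmole_to_uM / pL.consumption)
        births_A = np.minimum(bA * B_A * dt, As / fmole_to_uM / pA.consumption)
        if isinstance(pA.release, PiecewiseReleaseLaw):
            rL = interpolate_release_rate(As, pA.release)
        elif isinstance(pA.release, LinearReleaseLaw):
            rL = np.maximum(pA.release.intercept + pA.release.slope * (bA - pA.death_rate), 0.0)
        else:
            rL = float(pA.release)
        Ls += (rL * B_A * dt - pL.consumption * births_L) * fmole_to_uM
        As += (rA * B_L * dt - pA.consumption * births_A) * fmole_to_uM
        B_L += births_L - pL.death_rate * B_L * dt
        B_A += births_A - pA.death_rate * B_A * dt
        np.clip(Ls, 0.0, None, out=Ls)
        np.clip(As, 0.0, None, out=As)
        if cfg.D_agar_um2_s > 0:
            _diffuse(L3, D_layer, dt, cfg.dx_um, cfg.dz_um)
            _diffuse(A3, D_layer, dt, cfg.dx_um, cfg.dz_um)
        if step % record_stride == 0 or step == n_steps:
            times.append(step * dt)
            tot_L.append(B_L.sum())
            tot_A.append(B_A.sum())

    return SpatialResult(
        t=np.asarray(times), total_L=np.asarray(tot_L), total_A=np.asarray(tot_A),
        L_field=L3, A_field=A3, biomass_L=B_L, biomass_A=B_A, dt_h=dt,
        metadata={"shape": (nx, ny, nz), "dt_max_h": dt_max},
    )
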