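"""Domain types and the packaged strain-phenotype registry.

The community couples two engineered *Saccharomyces cerevisiae* auxotrophs:
a lysine-requiring strain that overproduces hypoxanthine (strain ``1335``,
"L-A+") and a hypoxanthine-requiring strain that overproduces lysine
(strain ``1340``, "A-L+").  Each strain is characterised by a Moser birth
law on its required metabolite, a death rate, a consumption amount per
birth, and a release rate of its partner's metabolite.

Units are fixed package-wide:

* time: h
* cell densities: cells/mL
* metabolite concentrations: uM
* per-cell amounts: fmole/cell

so that a per-cell amount times a density converts to a concentration via
``uM = fmole/cell * cells/mL * 1e-6`` (:data:`UM_PER_FMOL_PER_ML`).

Confidence bounds on every measured phenotype are stored as the 95%
interval (mean +/- 2 SEM); :func:`sem_from_bounds` recovers the SEM.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd

__all__ = [
    "UM_PER_FMOL_PER_ML",
    "ParameterError",
    "MoserParams",
    "LinearReleaseLaw",
    "PiecewiseReleaseLaw",
    "ReleaseRateLaw",
    "StrainPhenotype",
    "CommunityState",
    "EstimateWithCI",
    "sem_from_bounds",
    "load_parameter_table",
    "write_parameter_table",
    "registry_to_json",
    "default_registry",
    "LYSINE_RELEASE_VS_GROWTH",
    "CHEMOSTAT_7H_RELEASE_KEY",
]

#: 1 uM = 1e6 fmole/mL; multiplying fmole/cell by cells/mL and this constant
#: yields a concentration change in uM.
UM_PER_FMOL_PER_ML = 1e-6


class ParameterError(ValueError):
    """Raised when a phenotype value or registry file violates an invariant."""


@dataclass(frozen=True)
class MoserParams:
    """Moser (generalised Monod) birth kinetics b(s) = b_max s^n/(s^n + K^n).

    Parameters
    ----------
    b_max : maximal birth rate, per h.
    K : metabolite concentration at half-maximal birth, uM.
    n : dimensionless growth cooperativity (Hill-like exponent).
    """

    b_max: float
    K: float
    n: float

    def __post_init__(self) -> None:
        if not (self.b_max > 0 and self.K > 0 and self.n > 0):
            raise ParameterError(
                f"Moser parameters must be positive, got b_max={self.b_max}, "
                f"K={self.K}, n={self.n}"
            )


@dataclass(frozen=True)
class LinearReleaseLaw:
    """Release rate as a linear function of net growth rate g, clamped at 0.

    ``rate(g) = max(intercept + slope * g, 0)`` in fmole/cell/h.
    """

    intercept: float
    slope: float

    def rate_at_growth(self, g: float) -> float:
        return max(self.intercept + self.slope * g, 0.0)

    def __call__(self, g: float) -> float:
        return self.rate_at_growth(g)


@dataclass(frozen=True)
class PiecewiseReleaseLaw:
    """Release rate as a piecewise-linear function of local metabolite (uM).

    Knots must be strictly increasing in concentration; evaluation clamps to
    the end values outside the knot range and to 0 from below.
    """

    H: tuple[float, ...]
    rate: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.H) < 2 or len(self.H) != len(self.rate):
            raise ParameterError("piecewise release law needs >=2 (H, rate) knots")
        if not np.all(np.diff(self.H) > 0):
            raise ParameterError("piecewise release-law knots must be strictly increasing in H")

    def rate_at_H(self, H):
        return np.maximum(np.interp(H, self.H, self.rate), 0.0)

    def __call__(self, H):
        return self.rate_at_H(H)


ReleaseRateLaw = Union[LinearReleaseLaw, PiecewiseReleaseLaw]


@dataclass
class EstimateWithCI:
    """A point estimate with its standard error and fit diagnostics."""

    value: float
    sem: float
    method: str = ""
    slope: float | None = None
    intercept: float | None = None
    r_squared: float | None = None
    n_points: int | None = None

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ParameterError("sem must be non-negative")

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.value - 2 * self.sem, self.value + 2 * self.sem)


@dataclass
class CommunityState:
    """Instantaneous state of the two-strain community.

    NL, NA: live densities of the lysine-requiring and hypoxanthine-requiring
    strains (cells/mL); L, A: lysine and hypoxanthine concentrations (uM);
    dead densities optional.
    """

    NL: float
    NA: float
    L: float
    A: float
    dead_NL: float = 0.0
    dead_NA: float = 0.0

    def __post_init__(self) -> None:
        for name in ("NL", "NA", "L", "A", "dead_NL", "dead_NA"):
            if getattr(self, name) < 0:
                raise ParameterError(f"CommunityState.{name} must be >= 0")


@dataclass
class StrainPhenotype:
    """One strain's measured rates with 95% confidence bounds.

    ``release`` is either a fixed rate (fmole/cell/h) or a
    :class:`PiecewiseReleaseLaw` / :class:`LinearReleaseLaw` when the rate
    depends on the environment.  ``bounds`` maps parameter keys (``b_max``,
    ``K``, ``n``, ``death_rate``, ``consumption``, ``release_rate`` or
    ``release_rate@H=<conc>``) to (lower, upper) of the 95% interval.
    """

    strain: str
    birth: MoserParams
    death_rate: float
    consumption: float
    release: Union[float, ReleaseRateLaw]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.death_rate < 0:
            raise ParameterError("death rate must be >= 0")
        if self.consumption <= 0:
            raise ParameterError("consumption per birth must be > 0")
        if isinstance(self.release, (int, float)) and self.release < 0:
            raise ParameterError("release rate must be >= 0")

    def sem(self, key: str) -> float:
        """SEM of a bounded parameter, from its 95% interval."""
        lo, hi = self.bounds[key]
        return sem_from_bounds(lo, hi)

    def value(self, key: str) -> float:
        """Point value of a scalar parameter by its registry key."""
        if key == "b_max":
            return self.birth.b_max
        if key == "K":
            return self.birth.K
        if key == "n":
            return self.birth.n
        if key == "death_rate":
            return self.death_rate
        if key == "consumption":
            return self.consumption
        if key == "release_rate" and isinstance(self.release, (int, float)):
            return float(self.release)
        if key.startswith("release_rate@H=") and isinstance(self.release, PiecewiseReleaseLaw):
            H = float(key.split("=", 1)[1])
            idx = [i for i, h in enumerate(self.release.H) if math.isclose(h, H)]
            if not idx:
                raise KeyError(key)
            return self.release.rate[idx[0]]
        raise KeyError(key)


def sem_from_bounds(lower: float, upper: float) -> float:
    """SEM implied by a 95% confidence interval stated as mean +/- 2 SEM.

    The half-width of the interval is 2 SEM, so SEM = (upper - lower) / 4.
    """
    if upper < lower:
        raise ParameterError(f"upper bound {upper} < lower bound {lower}")
    return (upper - lower) / 4.0


_EXPECTED_UNITS = {
    "b_max": "per_h",
    "K": "uM",
    "n": "dimensionless",
    "death_rate": "per_h",
    "consumption": "fmole_per_cell",
    "release_rate": "fmole_per_cell_per_h",
}
_REQUIRED = ("b_max", "K", "n", "death_rate", "consumption", "release_rate")


def load_parameter_table(source: str | Path) -> dict[str, StrainPhenotype]:
    """Read a phenotype-registry CSV into a strain -> phenotype mapping.

    The file is flat tabular with columns ``strain, parameter, H_uM, value,
    lower, upper, unit``.  Multiple ``release_rate`` rows with distinct
    ``H_uM`` values assemble into a :class:`PiecewiseReleaseLaw`; a single
    row with empty ``H_uM`` yields a fixed rate.
    """
    df = pd.read_csv(source, dtype={"strain": str})
    required_cols = {"strain", "parameter", "H_uM", "value", "lower", "upper", "unit"}
    missing = required_cols - set(df.columns)
    if missing:
        raise ParameterError(f"registry missing columns: {sorted(missing)}")

    registry: dict[str, StrainPhenotype] = {}
    for strain, grp in df.groupby("strain", sort=False):
        scalars: dict[str, tuple[float, float, float]] = {}
        knots: list[tuple[float, float, float, float]] = []
        for row in grp.itertuples(index=False):
            p = row.parameter
            if p not in _EXPECTED_UNITS:
                raise ParameterError(f"strain {strain}: unknown parameter {p!r}")
            if row.unit != _EXPECTED_UNITS[p]:
                raise ParameterError(
                    f"strain {strain}, parameter {p}: unit {row.unit!r} "
                    f"(expected {_EXPECTED_UNITS[p]!r})"
                )
            v, lo, hi = float(row.value), float(row.lower), float(row.upper)
            if hi < lo:
                raise ParameterError(f"strain {strain}, parameter {p}: lower > upper")
            if not (lo <= v <= hi):
                raise ParameterError(f"strain {strain}, parameter {p}: value outside bounds")
            if p == "release_rate" and not pd.isna(row.H_uM):
                knots.append((float(row.H_uM), v, lo, hi))
            else:
                scalars[p] = (v, lo, hi)
        for p in _REQUIRED:
            if p not in scalars and not (p == "release_rate" and knots):
                raise ParameterError(f"strain {strain}: missing parameter {p!r}")

        bounds = {p: (lo, hi) for p, (v, lo, hi) in scalars.items()}
        release: Union[float, ReleaseRateLaw]
        if knots:
            knots.sort()
            release = PiecewiseReleaseLaw(
                H=tuple(k[0] for k in knots), rate=tuple(k[1] for k in knots)
            )
            for H, v, lo, hi in knots:
                bounds[f"release_rate@H={H:g}"] = (lo, hi)
        else:
            release = scalars["release_rate"][0]
        registry[str(strain)] = StrainPhenotype(
            strain=str(strain),
            birth=MoserParams(*(scalars[k][0] for k in ("b_max", "K", "n"))),
            death_rate=scalars["death_rate"][0],
            consumption=scalars["consumption"][0],
            release=release,
            bounds=bounds,
        )
    return registry


def write_parameter_table(registry: Mapping[str, StrainPhenotype], path: str | Path) -> None:
    """Write a registry back to the flat CSV format (bit-exact round trip)."""
    rows = []
    for strain, ph in registry.items():
        scalar_items = [
            ("b_max", ph.birth.b_max),
            ("K", ph.birth.K),
            ("n", ph.birth.n),
            ("death_rate", ph.death_rate),
            ("consumption", ph.consumption),
        ]
        if isinstance(ph.release, (int, float)):
            scalar_items.append(("release_rate", float(ph.release)))
        for key, value in scalar_items:
            lo, hi = ph.bounds[key]
            rows.append((strain, key, "", value, lo, hi, _EXPECTED_UNITS[key]))
        if isinstance(ph.release, PiecewiseReleaseLaw):
            for H, v in zip(ph.release.H, ph.release.rate):
                lo, hi = ph.bounds[f"release_rate@H={H:g}"]
                rows.append((strain, "release_rate", repr(H), v, lo, hi,
                             _EXPECTED_UNITS["release_rate"]))
    with open(path, "w") as fh:
        fh.write("strain,parameter,H_uM,value,lower,upper,unit\n")
        for strain, p, H, v, lo, hi, unit in rows:
            fh.write(f"{strain},{p},{H},{v!r},{lo!r},{hi!r},{unit}\n")


def registry_to_json(registry: Mapping[str, StrainPhenotype]) -> str:
    """JSON export of a registry (values, bounds, and release-law knots)."""
    out: dict[str, dict] = {}
    for strain, ph in registry.items():
        entry: dict = {
            "birth": {"b_max": ph.birth.b_max, "K": ph.birth.K, "n": ph.birth.n},
            "death_rate": ph.death_rate,
            "consumption": ph.consumption,
            "bounds": {k: list(v) for k, v in ph.bounds.items()},
        }
        if isinstance(ph.release, PiecewiseReleaseLaw):
            entry["release"] = {"H_uM": list(ph.release.H), "rate": list(ph.release.rate)}
        elif isinstance(ph.release, LinearReleaseLaw):
            entry["release"] = {"intercept": ph.release.intercept, "slope": ph.release.slope}
        else:
            entry["release"] = float(ph.release)
        out[strain] = entry
    return json.dumps(out, indent=2)


def default_registry() -> dict[str, StrainPhenotype]:
    """The packaged chemostat-measured phenotype registry for both strains."""
    with resources.as_file(
        resources.files("cosmodyn").joinpath("data/strain_phenotypes.csv")
    ) as path:
        return load_parameter_table(path)


#: Empirical regression of the lysine release rate of the hypoxanthine-
#: requiring strain on its net growth rate g (per h), valid over community-
#: like doubling times (5.5-8 h): r_L = 1.853 - 11.388 g  (fmole/cell/h).
LYSINE_RELEASE_VS_GROWTH = LinearReleaseLaw(intercept=1.853, slope=-11.388)

#: Registry key of the lysine release rate measured in 7-h-doubling
#: chemostats (the rate used, with its bounds, for error propagation because
#: a 7-h doubling closely matches the community's steady-state growth).
CHEMOSTAT_7H_RELEASE_KEY = "release_rate@H=0.65"
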