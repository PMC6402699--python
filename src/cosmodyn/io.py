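"""CSV and JSON readers/writers for time series and prediction reports.

Series files are plain CSV with an optional ``#``-prefixed metadata header
(``# key=value`` lines: package version, seed, config digest).  Floats are
written with ``repr`` so a write/read round trip is bit-exact.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import __version__
from .chemostat import ChemostatSeries
from .wellmixed import Trajectory

__all__ = [
    "write_trajectory_csv", "read_trajectory_csv",
    "write_chemostat_csv", "read_chemostat_csv",
    "write_json_report", "config_digest",
]

_TRAJ_COLS = ("time_h", "NL_per_ml", "NA_per_ml", "L_uM", "A_uM",
              "deadL_per_ml", "deadA_per_ml", "dilution_factor")
_CHEMO_COLS = ("time_h", "live_per_ml", "dead_per_ml", "limiting_uM", "released_uM")


def config_digest(obj) -> str:
    """Short stable digest of a configuration mapping/dataclass dict."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _write_table(path, columns, arrays, metadata):
    with open(path, "w") as fh:
        fh.write(f"# cosmodyn={__version__}\n")
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}={v}\n")
        fh.write(",".join(columns) + "\n")
        for row in zip(*arrays):
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def _read_table(path):
    meta, rows, header = {}, [], None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            if header is None:
                header = line.split(",")
                continue
            rows.append([float(x) for x in line.split(",")])
    if header is None or not rows:
        raise ValueError(f"{path}: no data rows")
    data = {c: np.asarray(col) for c, col in zip(header, zip(*rows))}
    return data, meta


def write_trajectory_csv(traj: Trajectory, path: str | Path, metadata: dict | None = None) -> None:
    n = len(traj.t)
    zeros = np.zeros(n)
    arrays = [
        traj.t, traj.NL, traj.NA, traj.L, traj.A,
        traj.dead_NL if traj.dead_NL is not None else zeros,
        traj.dead_NA if traj.dead_NA is not None else zeros,
        traj.dilution_factor if traj.dilution_factor is not None else np.ones(n),
    ]
    _write_table(path, _TRAJ_COLS, arrays, metadata)


def read_trajectory_csv(path: str | Path) -> Trajectory:
    data, meta = _read_table(path)
    return Trajectory(
        t=data["time_h"], NL=data["NL_per_ml"], NA=data["NA_per_ml"],
        L=data["L_uM"], A=data["A_uM"],
        dead_NL=data.get("deadL_per_ml"), dead_NA=data.get("deadA_per_ml"),
        dilution_factor=data.get("dilution_factor"), metadata=meta,
    )


def write_chemostat_csv(series: ChemostatSeries, path: str | Path,
                        metadata: dict | None = None) -> None:
    meta = {"dil_per_h": repr(float(series.dil))}
    meta.update(metadata or {})
    _write_table(path, _CHEMO_COLS,
                 [series.t, series.live, series.dead, series.limiting_uM,
                  series.released_uM], meta)


def read_chemostat_csv(path: str | Path) -> ChemostatSeries:
    data, meta = _read_table(path)
    dil = float(meta.get("dil_per_h", 0.0))
    return ChemostatSeries(
        t=data["time_h"], live=data["live_per_ml"], dead=data["dead_per_ml"],
        limiting_uM=data["limiting_uM"], released_uM=data["released_uM"],
        dil=dil, metadata=meta,
    )


def write_json_report(payload: dict, path: str | Path, *, seed: int | None = None,
                      config: dict | None = None) -> None:
    """Write a JSON report with a reproducibility header."""
    report = {
        "cosmodyn_version": __version__,
        "seed": seed,
        "config_digest": config_digest(config) if config is not None else None,
    }
    report.update(payload)
    Path(path).write_text(json.dumps(report, indent=2, default=float) + "\n")
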