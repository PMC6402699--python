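"""Mutant accounting and two-genotype dynamics.

Reproduces the evolutionary arithmetic -- fitness advantage from the
observed frequency sweep, back-extrapolated founding mutant frequency,
expected pre-existing mutant counts -- and simulates batch and chemostat
ancestor/mutant dynamics under a high chromosome-mis-segregation rate.
Writes results/evolution.json.
"""

from pathlib import Path

import numpy as np

from cosmodyn.chemostat import ChemostatConfig
from cosmodyn.evolution import (
    EvoParams,
    expected_preexisting_mutants,
    fitness_advantage_from_ratio,
    initial_mutant_frequency,
    simulate_batch_mutant_dynamics,
    simulate_chemostat_competition,
)
from cosmodyn.io import write_json_report
from cosmodyn.params import MoserParams

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    fitness = fitness_advantage_from_ratio([0.0, 5.7], [0.04, 0.40]).value
    f0 = initial_mutant_frequency(0.04, 0.4, 26.3)
    lo, hi = expected_preexisting_mutants(8e7, (0.5e-7, 30e-7))
    print(f"fitness advantage of evolved clones: {fitness:.3f}/h")
    print(f"founding mutant frequency: {f0:.2e} (order 1e-6)")
    print(f"expected pre-existing mutants in the inoculum: {lo:.0f}-{hi:.0f}")

    # batch growth in excess hypoxanthine: conversion at 0.01/birth against
    # a ~50% growth deficit keeps mutants a few-percent minority
    batch = EvoParams(mu=0.01, initial_fraction=0.05,
                      anc_birth_rate=0.45, mut_birth_rate=0.225)
    t_b, f_b = simulate_batch_mutant_dynamics(batch, 22.0, lag_h=6.0)
    print(f"batch mutant fraction: starts {f_b[0]:.3f}, ends {f_b[-1]:.3f} "
          f"(stays in the observed 1-10% band)")

    # chemostat competition: a pre-existing high-affinity mutant takes over
    comp = EvoParams(mu=0.0, initial_fraction=1.1e-6,
                     anc_birth=MoserParams(0.51, 2.1, 3.2),
                     mut_birth=MoserParams(0.51, 0.2, 3.2),
                     anc_death=0.0024, mut_death=0.0024, anc_consumption=5.4)
    cfg = ChemostatConfig(reservoir_uM=20.0, doubling_h=8.0,
                          init_limiting_uM=5.0, init_live=3e6)
    t_c, f_c, _ = simulate_chemostat_competition(comp, cfg, 60.0, n_points=601)
    t_cross = float(t_c[np.argmax(f_c > 0.10)])
    print(f"chemostat competition: population >90% ancestral until "
          f"{t_cross:.1f} h, mutants dominate by {float(t_c[np.argmax(f_c > 0.5)]):.1f} h")

    OUT.mkdir(exist_ok=True)
    write_json_report(
        {"fitness_advantage_per_h": fitness,
         "founding_mutant_frequency": f0,
         "preexisting_mutants": [lo, hi],
         "batch_fraction_start_end": [float(f_b[0]), float(f_b[-1])],
         "chemostat_10pct_crossing_h": t_cross},
        OUT / "evolution.json")


if __name__ == "__main__":
    main()
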