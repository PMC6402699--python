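"""Predict the steady-state community growth rate analytically.

Substitutes the growth-rate-dependent lysine release law into the
steady-state metabolite balance, solves the resulting quadratic, and
propagates the measured phenotype uncertainties through the closed form.
Writes results/growth_prediction.json.
"""

from pathlib import Path

from cosmodyn.io import write_json_report
from cosmodyn.params import (
    CHEMOSTAT_7H_RELEASE_KEY,
    LYSINE_RELEASE_VS_GROWTH,
    default_registry,
)
from cosmodyn.steady_state import (
    doubling_time,
    gcomm_variable_release,
    propagate_error,
    variable_release_quadratic,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    registry = default_registry()
    pL, pA = registry["1335"], registry["1340"]
    core = dict(d_A=pA.death_rate, d_L=pL.death_rate, r_A=float(pL.release),
                c_A=pA.consumption, c_L=pL.consumption)

    g = gcomm_variable_release(law=LYSINE_RELEASE_VS_GROWTH, **core)
    B, C = variable_release_quadratic(law=LYSINE_RELEASE_VS_GROWTH, **core)

    values = dict(core, r_L=pA.value(CHEMOSTAT_7H_RELEASE_KEY))
    sems = dict(
        d_A=pA.sem("death_rate"), d_L=pL.sem("death_rate"),
        r_A=pL.sem("release_rate"), r_L=pA.sem(CHEMOSTAT_7H_RELEASE_KEY),
        c_A=pA.sem("consumption"), c_L=pL.sem("consumption"))
    pred = propagate_error(values, sems)

    print(f"self-consistent quadratic: g^2 + {B:.4f} g - {C:.4f} = 0")
    print(f"predicted community growth rate: {g:.4f}/h "
          f"(doubling time {doubling_time(g):.2f} h)")
    print(f"propagated error: {pred.sem:.4f}/h -> 95% CI +/- {pred.ci95_halfwidth:.4f}")
    for name, term in sorted(pred.terms.items(), key=lambda kv: -kv[1]):
        print(f"  variance share {name}: {term:.2e}")

    OUT.mkdir(exist_ok=True)
    write_json_report(
        {"g_comm_per_h": g, "doubling_time_h": doubling_time(g),
         "quadratic_B": B, "quadratic_C": C,
         "sem": pred.sem, "ci95_halfwidth": pred.ci95_halfwidth,
         "variance_terms": pred.terms},
        OUT / "growth_prediction.json")


if __name__ == "__main__":
    main()
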