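"""Closed-form growth-rate prediction and error propagation."""

import math

import numpy as np
import pytest

from cosmodyn.params import LYSINE_RELEASE_VS_GROWTH, LinearReleaseLaw, ParameterError
from cosmodyn.steady_state import (
    doubling_time,
    gcomm_approx,
    gcomm_exact,
    gcomm_partials,
    gcomm_variable_release,
    propagate_error,
    variable_release_quadratic,
)

TABLE = dict(d_A=0.015, d_L=0.0024, r_A=0.27, c_A=3.1, c_L=5.4)


class TestGcommExact:
    def test_zero_deaths_reduce_to_geometric_mean(self):
        assert gcomm_exact(0, 0, 0.4, 0.9, 2.0, 5.0) == pytest.approx(
            math.sqrt(0.4 * 0.9 / 10.0))

    def test_zero_release_gives_minus_min_death(self):
        assert gcomm_exact(0.02, 0.005, 0.0, 0.7, 3.0, 5.0) == pytest.approx(-0.005)
        assert gcomm_exact(0.003, 0.01, 0.5, 0.0, 3.0, 5.0) == pytest.approx(-0.003)

    def test_measured_parameters_with_fixed_release(self):
        g = gcomm_exact(r_L=0.78, **TABLE)
        expected = -(0.015 + 0.0024) / 2 + math.sqrt(
            0.27 * 0.78 / (3.1 * 5.4) + (0.015 - 0.0024) ** 2 / 4)
        assert g == pytest.approx(expected, rel=1e-12)
        assert g == pytest.approx(0.1036, abs=5e-5)

    def test_exact_at_least_approx(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            dA, dL = rng.uniform(0, 0.05, 2)
            rA, rL = rng.uniform(0.01, 1, 2)
            cA, cL = rng.uniform(1, 10, 2)
            ge = gcomm_exact(dA, dL, rA, rL, cA, cL)
            ga = gcomm_approx(dA, dL, rA, rL, cA, cL)
            assert ge >= ga - 1e-15
            if dA == dL:
                assert ge == pytest.approx(ga)

    def test_nonpositive_consumption_rejected(self):
        with pytest.raises(ParameterError):
            gcomm_exact(0.01, 0.01, 0.3, 0.7, 0.0, 5.0)


class TestGcommApprox:
    def test_equal_deaths_match_exact(self):
        assert gcomm_approx(0.01, 0.01, 0.3, 0.7, 3.0, 5.0) == pytest.approx(
            gcomm_exact(0.01, 0.01, 0.3, 0.7, 3.0, 5.0))

    def test_measured_parameters(self):
        g = gcomm_approx(r_L=0.78, **TABLE)
        assert g == pytest.approx(-0.0087 + math.sqrt(0.27 * 0.78 / (3.1 * 5.4)),
                                  rel=1e-12)
        assert g == pytest.approx(0.1035, abs=1e-4)

    def test_unit_ratio(self):
        assert gcomm_approx(0, 0, 1.0, 1.0, 1.0, 1.0) == pytest.approx(1.0)

    def test_error_bound_versus_exact(self):
        dA, dL, rA, rL, cA, cL = 0.04, 0.002, 0.3, 0.7, 3.0, 5.0
        bound = (dA - dL) ** 2 / (8 * math.sqrt(rA * rL / (cA * cL)))
        diff = gcomm_exact(dA, dL, rA, rL, cA, cL) - gcomm_approx(dA, dL, rA, rL, cA, cL)
        assert 0 <= diff <= bound * (1 + 1e-9)


class TestVariableRelease:
    def test_headline_prediction(self):
        g = gcomm_variable_release(law=LYSINE_RELEASE_VS_GROWTH, **TABLE)
        assert round(g, 2) == 0.10

    def test_monic_quadratic_coefficient(self):
        """The linear coefficient of g^2 + B g - C = 0 prints as 0.200 with
        rounded intermediates; full precision gives 0.2011."""
        B, C = variable_release_quadratic(law=LYSINE_RELEASE_VS_GROWTH, **TABLE)
        k = 0.27 / (3.1 * 5.4)
        assert B == pytest.approx((0.015 + 0.0024) + 11.388 * k, rel=1e-12)
        assert B == pytest.approx(0.200, abs=2e-3)
        assert C == pytest.approx(1.853 * k - 0.0087**2, rel=1e-12)

    def test_zero_slope_degenerates_to_fixed_release(self):
        law = LinearReleaseLaw(intercept=0.78, slope=0.0)
        assert gcomm_variable_release(law=law, **TABLE) == pytest.approx(
            gcomm_approx(r_L=0.78, **TABLE))

    def test_unsustainable_community_rejected(self):
        law = LinearReleaseLaw(intercept=0.0, slope=-1.0)
        with pytest.raises(ParameterError):
            gcomm_variable_release(0.02, 0.02, 0.3, 3.0, 5.0, law)

    def test_monotonicity_in_parameters(self):
        """Growth increases with intercept and r_A, decreases in deaths and
        consumptions, over a parameter grid."""
        base = dict(TABLE)
        law = LYSINE_RELEASE_VS_GROWTH
        g0 = gcomm_variable_release(law=law, **base)
        for name, sign in (("r_A", +1), ("d_A", -1), ("d_L", -1),
                           ("c_A", -1), ("c_L", -1)):
            for bump in (1.1, 1.5):
                kwargs = dict(base)
                kwargs[name] = base[name] * bump
                g = gcomm_variable_release(law=law, **kwargs)
                assert (g - g0) * sign > 0, name
        g_up = gcomm_variable_release(
            law=LinearReleaseLaw(law.intercept * 1.2, law.slope), **base)
        assert g_up > g0


class TestDoublingTime:
    def test_printed_value(self):
        assert round(doubling_time(0.10), 1) == 6.9

    def test_ln2_rate(self):
        assert doubling_time(math.log(2)) == pytest.approx(1.0)

    def test_8h_convention(self):
        assert doubling_time(0.087) == pytest.approx(7.97, abs=0.01)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ParameterError):
            doubling_time(0.0)


def _table_sems(registry):
    pL, pA = registry["1335"], registry["1340"]
    values = dict(TABLE, r_L=pA.value("release_rate@H=0.65"))
    sems = dict(
        d_A=pA.sem("death_rate"), d_L=pL.sem("death_rate"),
        r_A=pL.sem("release_rate"), r_L=pA.sem("release_rate@H=0.65"),
        c_A=pA.sem("consumption"), c_L=pL.sem("consumption"),
    )
    return values, sems


class TestErrorPropagation:
    def test_release_contribution_term(self, registry):
        values, sems = _table_sems(registry)
        pred = propagate_error(values, sems)
        assert pred.terms["r_A"] == pytest.approx(4.3e-6, abs=0.05e-6)
        assert pred.terms["r_L"] == pytest.approx(8.3e-6, abs=0.1e-6)
        # consumption terms: printed values back-compute to unrounded bounds,
        # so only order-of-magnitude agreement is expected
        assert pred.terms["c_A"] == pytest.approx(1.3e-6, rel=0.40)
        assert pred.terms["c_L"] == pytest.approx(1.8e-6, rel=0.40)

    def test_total_error_and_ci(self, registry):
        values, sems = _table_sems(registry)
        pred = propagate_error(values, sems)
        assert pred.sem == pytest.approx(0.004, abs=5e-4)
        assert pred.ci95_halfwidth == pytest.approx(2 * pred.sem)
        assert sum(pred.terms.values()) == pytest.approx(pred.sem**2)

    def test_zero_sems_give_zero_error(self, registry):
        values, _ = _table_sems(registry)
        pred = propagate_error(values, {k: 0.0 for k in values})
        assert pred.sem == 0.0

    def test_doubling_time_consistency(self, registry):
        values, sems = _table_sems(registry)
        pred = propagate_error(values, sems)
        assert pred.doubling_time == pytest.approx(math.log(2) / pred.g_comm)

    def test_partials_match_finite_differences(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            vals = dict(
                d_A=rng.uniform(0.001, 0.05), d_L=rng.uniform(0.001, 0.05),
                r_A=rng.uniform(0.05, 1.0), r_L=rng.uniform(0.05, 1.0),
                c_A=rng.uniform(1.0, 10.0), c_L=rng.uniform(1.0, 10.0),
            )
            order = ("d_A", "d_L", "r_A", "r_L", "c_A", "c_L")
            parts = gcomm_partials(*(vals[k] for k in order))
            for k in order:
                h = 1e-6 * vals[k]
                hi = dict(vals); hi[k] += h
                lo = dict(vals); lo[k] -= h
                fd = (gcomm_approx(*(hi[kk] for kk in order))
                      - gcomm_approx(*(lo[kk] for kk in order))) / (2 * h)
                assert parts[k] == pytest.approx(fd, rel=1e-4)

    def test_against_monte_carlo_oracle(self, registry):
        """Linearised propagation agrees within 5% with the sample SD of the
        growth rate over 50,000 Gaussian parameter draws."""
        values, sems = _table_sems(registry)
        pred = propagate_error(values, sems)
        rng = np.random.default_rng(2024)
        n = 50_000
        draws = {k: rng.normal(values[k], sems[k], n) for k in values}
        g = (-(draws["d_A"] + draws["d_L"]) / 2
             + np.sqrt(draws["r_A"] * draws["r_L"] / (draws["c_A"] * draws["c_L"])))
        assert pred.sem == pytest.approx(float(np.std(g, ddof=1)), rel=0.05)

    def test_negative_sem_rejected(self, registry):
        values, sems = _table_sems(registry)
        sems["r_A"] = -0.01
        with pytest.raises(ParameterError):
            propagate_error(values, sems)
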