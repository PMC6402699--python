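"""Chemostat simulation and the phenotype estimators built on it."""

import dataclasses
import math

import numpy as np
import pytest

from cosmodyn.chemostat import (
    ChemostatConfig,
    batch_death_rate,
    compare_release_models,
    dead_release_concentration,
    dead_release_required,
    dilution_rate_from_doubling,
    estimate_consumption_exponential,
    estimate_consumption_saturation,
    estimate_consumption_ss,
    estimate_death_regression,
    estimate_death_ss,
    estimate_release_regression,
    estimate_release_ss,
    exp_weighted_integral,
    release_rate_upper_bound,
    simulate_chemostat,
    steady_state_window,
)
from cosmodyn.params import MoserParams, ParameterError, StrainPhenotype
from cosmodyn.synth import generate_starvation_series
from cosmodyn.wellmixed import moser_birth_rate


def _strain(b_max=0.51, K=2.1, n=3.2, d=0.0024, c=5.4, r=0.27):
    return StrainPhenotype(strain="x", birth=MoserParams(b_max, K, n),
                           death_rate=d, consumption=c, release=r)


class TestDilutionRate:
    def test_19ml_8h_vessel(self):
        flow, dil = dilution_rate_from_doubling(19.0, 8.0)
        assert flow == pytest.approx(1.646, abs=5e-4)
        assert dil == pytest.approx(math.log(2) / 8)

    def test_infinite_doubling_limit(self):
        flow, dil = dilution_rate_from_doubling(19.0, 1e12)
        assert flow == pytest.approx(0.0, abs=1e-10)

    def test_55h_doubling(self):
        flow, _ = dilution_rate_from_doubling(19.0, 5.5)
        assert flow == pytest.approx(19 * math.log(2) / 5.5, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ParameterError):
            dilution_rate_from_doubling(0.0, 8.0)


@pytest.fixture(scope="module")
def converged_series(lys_consumer):
    cfg = ChemostatConfig(reservoir_uM=20.0, doubling_h=8.0)
    return simulate_chemostat(lys_consumer, cfg, 250.0, n_points=251), cfg


@pytest.fixture(scope="module")
def regression_series():
    strain = _strain(r=0.30, d=0.0024)
    cfg = ChemostatConfig(reservoir_uM=20.0, doubling_h=8.0, init_live=1e6)
    return simulate_chemostat(strain, cfg, 96.0, n_points=97)


class TestSimulateChemostat:
    @pytest.fixture()
    def series(self, converged_series):
        return converged_series

    def test_steady_state_growth_balance(self, series, lys_consumer):
        """At steady state, b(S_ss) - d = dil."""
        s, cfg = series
        mask = steady_state_window(s)
        b = moser_birth_rate(s.limiting_uM[mask].mean(), lys_consumer.birth)
        assert abs(b - lys_consumer.death_rate - cfg.dil) < 1e-6

    def test_steady_density_near_reservoir_over_consumption(self, series):
        # approximate balance: N_ss ~ S0 / c in package units (2e7 fmole/mL / 5.4)
        s, _ = series
        live_ss = s.live[steady_state_window(s)].mean()
        assert live_ss == pytest.approx(20e6 / 5.4, rel=0.15)

    def test_zero_release_keeps_metabolite_zero(self):
        strain = _strain(r=0.0)
        cfg = ChemostatConfig(reservoir_uM=20.0, doubling_h=8.0)
        s = simulate_chemostat(strain, cfg, 100.0)
        assert np.all(s.released_uM == 0.0)

    def test_live_and_dead_release_equivalent_when_rates_match(self):
        """Release by live cells at rate r and release on death of r/d per
        death produce identical metabolite dynamics (the reason chemostat
        dynamics alone cannot discriminate the two modes)."""
        d = 0.0024
        live = _strain(d=d, r=0.27)
        cfg_live = ChemostatConfig(reservoir_uM=20.0, doubling_h=8.0)
        cfg_dead = ChemostatConfig(reservoir_uM=20.0, doubling_h=8.0,
                                   release_mode="dead",
                                   dead_release_fmole=0.27 / d)
        a = simulate_chemostat(live, cfg_live, 150.0)
        b = simulate_chemostat(live, cfg_dead, 150.0)
        assert a.released_uM == pytest.approx(b.released_uM, rel=1e-6, abs=1e-9)


class TestSteadyStateEstimators:
    def test_consumption_example(self):
        exact, approx = estimate_consumption_ss(20.0, 0.0866, 0.0, 0.0866, 3.7e6)
        assert exact == pytest.approx(20e6 / 3.7e6, rel=1e-9)
        assert approx == pytest.approx(exact)

    def test_consumption_zero_when_no_drawdown(self):
        exact, _ = estimate_consumption_ss(20.0, 0.0866, 20.0, 0.0866, 1e6)
        assert exact == 0.0

    def test_death_from_dead_live_ratio(self):
        assert estimate_death_ss(0.0866, 0.0277 * 3.2e6, 3.2e6) == pytest.approx(
            0.0024, abs=1e-4)
        assert estimate_death_ss(0.0866, 0.0, 1e6) == 0.0

    def test_release_from_steady_metabolite(self):
        assert estimate_release_ss(0.0866, 10.0, 3.2e6) == pytest.approx(0.27, abs=0.002)
        assert estimate_release_ss(0.0866, 0.0, 1e6) == 0.0

    def test_zero_density_rejected(self):
        with pytest.raises(ParameterError):
            estimate_death_ss(0.0866, 1e5, 0.0)

    def test_recovery_from_simulation(self, lys_consumer):
        cfg = ChemostatConfig(reservoir_uM=20.0, doubling_h=8.0)
        s = simulate_chemostat(lys_consumer, cfg, 250.0)
        mask = steady_state_window(s)
        live, dead = s.live[mask].mean(), s.dead[mask].mean()
        L, A = s.limiting_uM[mask].mean(), s.released_uM[mask].mean()
        b = moser_birth_rate(L, lys_consumer.birth)
        exact, _ = estimate_consumption_ss(20.0, cfg.dil, L, b, live)
        assert exact == pytest.approx(5.4, rel=0.01)
        assert estimate_death_ss(cfg.dil, dead, live) == pytest.approx(0.0024, rel=0.02)
        assert estimate_release_ss(cfg.dil, A, live) == pytest.approx(0.27, rel=0.02)


class TestExpWeightedIntegral:
    def test_constant_integrand_zero_dilution(self):
        t = np.linspace(0, 10, 21)
        out = exp_weighted_integral(t, np.full_like(t, 3.0), 0.0)
        assert out[-1] == pytest.approx(30.0)
        assert out[0] == 0.0

    def test_decaying_integrand_cancels_weight(self):
        t = np.linspace(0, 5, 11)
        out = exp_weighted_integral(t, np.exp(-0.3 * t), 0.3)
        assert out == pytest.approx(t)

    def test_hand_trapezoid(self):
        out = exp_weighted_integral([0.0, 1.0, 2.0], [0.0, 1.0, 2.0], 0.0)
        assert out == pytest.approx([0.0, 0.5, 2.0])

    def test_unordered_times_rejected(self):
        with pytest.raises(ParameterError):
            exp_weighted_integral([0.0, 2.0, 1.0], [1.0, 1.0, 1.0], 0.0)


class TestRegressionEstimators:
    @pytest.fixture()
    def series(self, regression_series):
        return regression_series

    def test_release_recovered_noiselessly(self, series):
        est = estimate_release_regression(series)
        assert est.value == pytest.approx(0.30, rel=0.005)

    def test_death_recovered_noiselessly(self, series):
        est = estimate_death_regression(series)
        assert est.value == pytest.approx(0.0024, rel=0.01)

    def test_no_deaths_give_zero_slope(self):
        t = np.linspace(0, 48, 13)
        dil = math.log(2) / 8
        from cosmodyn.chemostat import ChemostatSeries
        s = ChemostatSeries(t=t, live=np.full_like(t, 1e6),
                            dead=1e4 * np.exp(-dil * t),
                            limiting_uM=np.zeros_like(t),
                            released_uM=np.zeros_like(t), dil=dil)
        est = estimate_death_regression(s)
        assert est.value == pytest.approx(0.0, abs=1e-12)
        assert est.intercept == pytest.approx(1e4, rel=1e-9)

    def test_agreement_with_steady_state_estimators(self, series):
        """Regression over the full series and steady-state averaging agree
        within 3% on converged noiseless data."""
        mask = steady_state_window(series)
        r_ss = estimate_release_ss(series.dil, series.released_uM[mask].mean(),
                                   series.live[mask].mean())
        d_ss = estimate_death_ss(series.dil, series.dead[mask].mean(),
                                 series.live[mask].mean())
        assert estimate_release_regression(series).value == pytest.approx(r_ss, rel=0.03)
        assert estimate_death_regression(series).value == pytest.approx(d_ss, rel=0.03)

    def test_full_loop_randomized_recovery(self):
        """Simulation followed by estimation recovers randomized (r, d, c)
        within 2% without noise."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            r = rng.uniform(0.1, 0.8)
            d = rng.uniform(0.002, 0.02)
            c = rng.uniform(2.0, 8.0)
            strain = _strain(d=d, c=c, r=r)
            cfg = ChemostatConfig(reservoir_uM=20.0, doubling_h=8.0, init_live=1e6)
            s = simulate_chemostat(strain, cfg, 250.0)
            assert estimate_release_regression(s).value == pytest.approx(r, rel=0.02)
            assert estimate_death_regression(s).value == pytest.approx(d, rel=0.02)
            mask = steady_state_window(s)
            L = s.limiting_uM[mask].mean()
            b = moser_birth_rate(L, strain.birth)
            exact, _ = estimate_consumption_ss(20.0, cfg.dil, L, b, s.live[mask].mean())
            assert exact == pytest.approx(c, rel=0.02)


class TestReleaseModeComparison:
    def test_live_generated_series_prefers_live(self):
        s = generate_starvation_series("live", release_rate=0.27)
        rep = compare_release_models(s.t, s.live, s.dead, s.released_uM)
        assert rep.preferred == "live"
        assert rep.live_slope == pytest.approx(0.27, rel=0.01)

    def test_dead_generated_series_prefers_dead(self):
        s = generate_starvation_series("dead", release_per_death=20.0)
        rep = compare_release_models(s.t, s.live, s.dead, s.released_uM)
        assert rep.preferred == "dead"
        assert rep.dead_slope == pytest.approx(20.0, rel=0.01)

    def test_collinear_series_flagged_indeterminate(self):
        """Constant death without dilution makes dead density exactly
        proportional to the integrated live density: no discrimination."""
        s = generate_starvation_series("live", release_rate=0.27,
                                       late_death_rate=None, death_rate=0.01)
        rep = compare_release_models(s.t, s.live, s.dead, s.released_uM)
        assert rep.preferred == "indeterminate"

    def test_constant_dead_density_flagged(self):
        t = np.linspace(0, 24, 6)
        live = np.full_like(t, 1e6)
        dead = np.full_like(t, 1e4)
        met = 0.27 * 1e6 * t * 1e-6
        rep = compare_release_models(t, live, dead, met)
        assert rep.preferred == "live"
        assert rep.dead_r2 is None


class TestDeadReleaseArithmetic:
    def test_forward_concentration_check(self):
        assert dead_release_concentration(0.12, 1e5) == pytest.approx(0.012)
        assert dead_release_concentration(0.12, 0.0) == 0.0

    def test_inverse_required_content(self):
        assert dead_release_required(10.0, 1e5) == pytest.approx(100.0)

    def test_inverse_rejects_zero_density(self):
        with pytest.raises(ParameterError):
            dead_release_required(10.0, 0.0)


class TestBatchEstimators:
    def test_exponential_consumption_constructed_slope(self):
        n = np.linspace(1e6, 2e7, 8)
        m = 100.0 - 3.0 * (n - n[0]) * 1e-6
        est = estimate_consumption_exponential(n, m)
        assert est.value == pytest.approx(3.0, rel=1e-9)

    def test_low_metabolite_points_filtered(self):
        n = np.linspace(1e6, 3e7, 10)
        m = 100.0 - 5.4 * (n - n[0]) * 1e-6
        m[m < 10] = 5.0  # corrupt points below the validity floor
        with pytest.warns(UserWarning, match="validity floor"):
            est = estimate_consumption_exponential(n, m)
        assert est.value == pytest.approx(5.4, rel=1e-6)
        assert est.n_points == int((m >= 10).sum())

    def test_exponential_simulation_recovery(self):
        t = np.linspace(0, 6, 7)
        n = 1e6 * np.exp(0.47 * t)
        m = 100.0 - 5.4 * (n - n[0]) * 1e-6
        keep = m >= 10
        est = estimate_consumption_exponential(n[keep], m[keep])
        assert est.value == pytest.approx(5.4, rel=0.005)

    def test_all_points_below_floor_rejected(self):
        with pytest.raises(ParameterError):
            estimate_consumption_exponential([1e6, 2e6], [5.0, 4.0])

    def test_saturation_yield_exact(self):
        conc = np.array([2.0, 5.0, 10.0, 20.0])
        dens = conc * 1e6 / 2.0
        est = estimate_consumption_saturation(conc, dens)
        assert est.value == pytest.approx(2.0, rel=1e-12)

    def test_saturation_yield_noisy(self):
        rng = np.random.default_rng(5)
        conc = np.array([2.0, 5.0, 10.0, 15.0, 20.0, 25.0])
        dens = conc * 1e6 / 2.0 * rng.normal(1.0, 0.05, conc.size)
        est = estimate_consumption_saturation(conc, dens)
        assert est.value == pytest.approx(2.0, rel=0.05)

    def test_saturation_single_level_rejected(self):
        with pytest.raises(ParameterError):
            estimate_consumption_saturation([10.0], [5e6])

    def test_release_upper_bound_detection_limit(self):
        r = release_rate_upper_bound(0.1, 0.47, 1.5e7)
        assert round(r, 3) == 0.003

    def test_release_upper_bound_linearity(self):
        r1 = release_rate_upper_bound(0.1, 0.47, 1.5e7)
        assert release_rate_upper_bound(0.2, 0.47, 1.5e7) == pytest.approx(2 * r1)
        assert release_rate_upper_bound(0.0, 0.47, 1.5e7) == 0.0

    def test_batch_death_rate(self):
        assert batch_death_rate(0.001, 0.47) == pytest.approx(4.7e-4)
        assert batch_death_rate(0.0, 0.47) == 0.0
        with pytest.raises(ParameterError):
            batch_death_rate(0.001, 0.0)

    def test_batch_death_rate_from_birth_death_simulation(self):
        b, d = 0.48, 0.01
        t = 10.0
        live = 1e5 * math.exp((b - d) * t)
        dead = d / (b - d) * live  # balanced-growth ratio
        assert batch_death_rate(dead / live, b - d) == pytest.approx(d, rel=0.02)
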