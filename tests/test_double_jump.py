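"""Mixing arithmetic, three-state relaxation, and interrupted-refolding fits."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from knotfold.double_jump import (
    AmplitudeBuildUp,
    InterruptedRefoldingSeries,
    LinearThreeState,
    MixingScheme,
    MixingStep,
    final_concentration,
    fit_amplitude_buildup,
    fit_linear_three_state,
    global_fit_shared_rates,
    populations,
    three_state_relaxation,
)
from knotfold.exceptions import DataError
from knotfold.synthetic import generate_interrupted_refolding


class TestMixing:
    def test_single_jump_eleven_fold_dilution(self):
        scheme = MixingScheme.single_jump(protein_start=20.0, stock_denaturant=8.0)
        (denat, prot), = final_concentration(scheme)
        assert prot == pytest.approx(20.0 / 11.0)       # 1.8 μM
        assert denat == pytest.approx(8.0 / 11.0)

    def test_interrupted_refolding_two_steps(self):
        scheme = MixingScheme.interrupted_refolding(stock_denaturant=7.7)
        steps = final_concentration(scheme)
        assert steps[0][0] == pytest.approx(7.7 / 6.0)          # ≈ 1.28 M
        assert steps[1][0] == pytest.approx((7.7 / 6.0 + 8.0) / 2.0)  # ≈ 4.64 M

    def test_invalid_ratio_rejected(self):
        with pytest.raises(DataError):
            MixingStep(0.0, -1.0)


class TestThreeStateRelaxation:
    def test_symmetric_rates_analytic_eigenvalues(self):
        rates, _ = three_state_relaxation(LinearThreeState(1, 1, 1, 1))
        assert sorted(rates) == pytest.approx([1.0, 3.0], rel=1e-12)

    def test_detailed_balance_at_equilibrium(self):
        model = LinearThreeState(0.03, 0.003, 0.3, 0.03)
        p_eq = populations(model, np.array([1e6]))[:, 0]
        assert p_eq[0] * model.k_ab == pytest.approx(p_eq[1] * model.k_ba, rel=1e-6)
        assert p_eq[1] * model.k_bc == pytest.approx(p_eq[2] * model.k_cb, rel=1e-6)

    def test_analytic_populations_match_ode(self):
        model = LinearThreeState(0.03, 0.003, 0.3, 0.03)
        t = np.linspace(0.0, 200.0, 100)
        sol = solve_ivp(
            lambda _, p: model.rate_matrix @ p, (0, 200), model.p0,
            t_eval=t, rtol=1e-11, atol=1e-13,
        )
        assert np.abs(populations(model, t) - sol.y).max() < 1e-8

    def test_population_conservation(self):
        model = LinearThreeState(0.5, 0.1, 2.0, 0.2)
        p = populations(model, np.linspace(0, 50, 100))
        assert np.abs(p.sum(axis=0) - 1.0).max() < 1e-12

    def test_relabelling_symmetry(self):
        r1, _ = three_state_relaxation(LinearThreeState(0.1, 0.02, 0.5, 0.04))
        r2, _ = three_state_relaxation(LinearThreeState(0.04, 0.5, 0.02, 0.1))
        assert sorted(r1) == pytest.approx(sorted(r2), rel=1e-10)

    def test_all_zero_rates_rejected(self):
        with pytest.raises(DataError):
            three_state_relaxation(LinearThreeState(0, 0, 0, 0))


class TestSharedRateFit:
    def test_noiseless_rates_equal_generator(self):
        series, truth = generate_interrupted_refolding(noise=0.0, seed=0)
        rates, _ = global_fit_shared_rates(series, 2)
        assert rates[0] == pytest.approx(truth["probe_rates"][0], rel=1e-6)
        assert rates[1] == pytest.approx(truth["probe_rates"][1], rel=1e-6)

    def test_noisy_rates_within_15_percent(self):
        series, truth = generate_interrupted_refolding(
            noise=0.02, seed=11, aging_times=np.geomspace(0.01, 100.0, 8)
        )
        rates, _ = global_fit_shared_rates(series, 2)
        assert rates[0] == pytest.approx(truth["probe_rates"][0], rel=0.15)
        assert rates[1] == pytest.approx(truth["probe_rates"][1], rel=0.15)

    def test_single_aging_time_rejected(self):
        series, _ = generate_interrupted_refolding(
            noise=0.0, aging_times=np.array([1.0])
        )
        with pytest.raises(DataError):
            global_fit_shared_rates(series, 2)

    def test_amplitudes_track_species_populations(self):
        series, truth = generate_interrupted_refolding(noise=0.0, seed=0)
        _, amp = global_fit_shared_rates(series, 2)
        pops = np.array(truth["populations"])
        assert np.allclose(amp[0], pops[1], atol=1e-6)  # fast phase ~ intermediate
        assert np.allclose(amp[1], pops[2], atol=1e-6)  # slow phase ~ native


class TestAmplitudeBuildUp:
    def test_exact_exponential_recovery(self):
        t = np.geomspace(0.05, 30.0, 12)
        amp = 0.7 * (1.0 - np.exp(-0.5 * t))
        fit = fit_amplitude_buildup(amp[None, :], t)
        assert fit.buildup_rates[0] == pytest.approx(0.5, rel=1e-6)
        assert not fit.lag_flags[0]

    def test_sequential_intermediate_shows_lag(self):
        # A -> B -> C with k1=0.03, k2=0.3: C builds up with a delayed onset
        model = LinearThreeState(0.03, 0.0, 0.3, 0.0)
        t = np.geomspace(0.5, 300.0, 15)
        p = populations(model, t)
        fit = fit_amplitude_buildup(p[2][None, :], t)
        assert fit.lag_flags[0]

    def test_constant_amplitude_reports_absent_rate(self):
        t = np.geomspace(0.1, 10.0, 8)
        fit = fit_amplitude_buildup(np.full((1, 8), 0.4), t)
        assert fit.buildup_rates[0] is None

    def test_too_few_aging_times_rejected(self):
        with pytest.raises(DataError):
            fit_amplitude_buildup(np.ones((1, 3)), np.array([0.1, 1.0, 10.0]))


class TestLinearThreeStateFit:
    def test_noiseless_recovery_to_one_percent(self):
        series, truth = generate_interrupted_refolding(noise=0.0, seed=0)
        _, amp = global_fit_shared_rates(series, 2)
        buildup = fit_amplitude_buildup(amp, series.aging_times)
        model = fit_linear_three_state(buildup)
        for name in ("k_ab", "k_ba", "k_bc", "k_cb"):
            assert getattr(model, name) == pytest.approx(truth[name], rel=0.01)
        assert model.preferred == "three-state"

    def test_noisy_recovery_within_factor_two(self):
        """At 10% amplitude noise the identifiable microscopic rates come
        back within a factor of two.  The back-rate k_ba (0.003 s^-1) barely
        perturbs the observable build-ups and is not identifiable at this
        noise level; the observable relaxation rates of the fitted scheme
        are checked instead."""
        series, truth = generate_interrupted_refolding(noise=0.10, seed=5)
        _, amp = global_fit_shared_rates(series, 2)
        buildup = fit_amplitude_buildup(amp, series.aging_times)
        model = fit_linear_three_state(buildup)
        for name in ("k_ab", "k_bc", "k_cb"):
            ratio = getattr(model, name) / truth[name]
            assert 0.5 <= ratio <= 2.0
        true_model = LinearThreeState(truth["k_ab"], truth["k_ba"],
                                      truth["k_bc"], truth["k_cb"])
        lam_fit, _ = three_state_relaxation(model)
        lam_true, _ = three_state_relaxation(true_model)
        for f, t in zip(sorted(lam_fit), sorted(lam_true)):
            assert 0.5 <= f / t <= 2.0

    def test_two_state_data_prefers_simpler_scheme(self):
        # both observables relax with the same single exponential: no
        # evidence for an on-pathway intermediate
        t = np.geomspace(0.05, 50.0, 12)
        rng = np.random.default_rng(3)
        y = 1.0 - np.exp(-0.2 * t)
        rows = np.vstack([y, y]) + rng.normal(0, 0.01, (2, len(t)))
        buildup = AmplitudeBuildUp(t, rows)
        model = fit_linear_three_state(buildup)
        assert model.preferred == "two-state"
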