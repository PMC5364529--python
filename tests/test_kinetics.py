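"""Stopped-flow trace fitting, F-test model choice, and chevron analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from knotfold.conditions import Conditions
from knotfold.exceptions import DataError, UnidentifiableError
from knotfold.kinetics import (
    ChevronDataset,
    ChevronFit,
    KineticTrace,
    chevron_kobs,
    delta_g_from_rates,
    extra_ss_f_test,
    fit_chevron,
    fit_multiexponential,
)
from knotfold.synthetic import generate_chevron, generate_kinetic_trace

# published chevron parameters (kf, mf, ku, mu) per kinetic phase
PHASE1 = (0.14, -1.09, 8.1e-9, 1.88)
PHASE4 = (1120.0, -1.65, 3.1e-2, 0.81)
UCHL1 = (0.3, -1.06, 7.6e-5, 0.74)
UCHL3 = (49.0, -1.28, 2.6e-4, 0.83)


class TestMultiExponential:
    def test_noiseless_two_phase_recovery(self):
        trace, _ = generate_kinetic_trace([10.0, 0.8], [0.8, 0.2], noise=0.0)
        fit = fit_multiexponential(trace)
        assert fit.n_phases == 2
        assert fit.rates[0] == pytest.approx(10.0, rel=1e-6)
        assert fit.rates[1] == pytest.approx(0.8, rel=1e-6)

    def test_noisy_phase2_phase3_rates(self):
        # the two intermediate phases (10.3 and 0.80 s^-1) at 4:1 amplitude
        trace, _ = generate_kinetic_trace(
            [10.3, 0.80], [0.8, 0.2], noise=0.01, seed=7
        )
        fit = fit_multiexponential(trace)
        assert fit.n_phases == 2
        assert fit.rates[0] == pytest.approx(10.3, rel=0.10)
        assert fit.rates[1] == pytest.approx(0.80, rel=0.10)

    def test_pure_offset_trace_flagged_single_phase(self):
        t = np.linspace(2e-3, 5.0, 200)
        trace = KineticTrace(t, np.full_like(t, 3.0))
        fit = fit_multiexponential(trace)
        assert fit.n_phases == 1
        assert abs(fit.amplitudes[0]) < 1e-6
        assert fit.flags

    def test_dead_time_points_discarded(self):
        t = np.linspace(0.0, 5.0, 300)
        trace = KineticTrace(t, 1.0 + 0.5 * np.exp(-2.0 * t), dead_time=0.05)
        fit = fit_multiexponential(trace)
        assert fit.rates[0] == pytest.approx(2.0, rel=1e-6)

    def test_too_short_trace_rejected(self):
        t = np.linspace(2e-3, 1.0, 30)
        with pytest.raises(DataError):
            fit_multiexponential(KineticTrace(t, np.exp(-t)))

    def test_phase_relabelling_slowest_first(self):
        trace, _ = generate_kinetic_trace([10.0, 0.8], [0.8, 0.2], noise=0.0)
        fit = fit_multiexponential(trace)
        labelled = fit.phase_rates()
        assert labelled[1] < labelled[2]  # phase 1 is the slowest


class TestFTest:
    def test_equal_rss_gives_zero_f(self):
        f, p, accept = extra_ss_f_test(1.0, 3, 1.0, 5, 100)
        assert f == 0.0 and not accept

    def test_direct_arithmetic(self):
        f, _, accept = extra_ss_f_test(2.0, 3, 1.0, 5, 105)
        assert f == pytest.approx(50.0)
        assert accept

    def test_below_critical_value_not_accepted(self):
        # F = 1 with (2, 100) dof is far below the 5% critical value
        f, p, accept = extra_ss_f_test(1.02, 3, 1.0, 5, 105)
        assert p > 0.05 and not accept

    def test_worse_complex_model_rejected(self):
        f, _, accept = extra_ss_f_test(1.0, 3, 1.5, 5, 100)
        assert f == 0.0 and not accept

    def test_invalid_nesting_rejected(self):
        with pytest.raises(ValueError):
            extra_ss_f_test(1.0, 5, 0.5, 3, 100)


class TestChevronKobs:
    def test_water_limit(self, cond298):
        fit = ChevronFit(*PHASE1)
        assert chevron_kobs(fit, 0.0) == pytest.approx(0.14 + 8.1e-9)

    def test_unfolding_limb_at_6M(self, cond298):
        # independent evaluation of the closed form at 6 M urea
        assert chevron_kobs(ChevronFit(*PHASE1), 6.0) == pytest.approx(1.517, rel=0.01)

    def test_arm_equality_concentration_is_d50(self, cond298):
        fit = ChevronFit(*PHASE1)
        d_star = cond298.rt * np.log(fit.kf_h2o / fit.ku_h2o) / (fit.mu - fit.mf)
        assert d_star == pytest.approx(fit.d50, rel=1e-12)
        refold = fit.kf_h2o * np.exp(fit.mf * d_star / cond298.rt)
        unfold = fit.ku_h2o * np.exp(fit.mu * d_star / cond298.rt)
        assert refold == pytest.approx(unfold, rel=1e-9)

    def test_single_minimum_on_log_scale(self):
        fit = ChevronFit(*PHASE1)
        d = np.linspace(0, 9, 400)
        logk = np.log10(chevron_kobs(fit, d))
        sign_changes = np.sum(np.abs(np.diff(np.sign(np.diff(logk)))) > 0)
        assert sign_changes == 1


class TestChevronFit:
    def test_noiseless_exact_recovery(self):
        dataset, truth = generate_chevron(*PHASE1, noise_log_sd=0.0)
        fit = fit_chevron(dataset)
        assert fit.kf_h2o == pytest.approx(truth["kf_h2o"], rel=1e-6)
        assert fit.ku_h2o == pytest.approx(truth["ku_h2o"], rel=1e-6)
        assert fit.mf == pytest.approx(truth["mf"], rel=1e-6)
        assert fit.mu == pytest.approx(truth["mu"], rel=1e-6)

    def test_roundtrip_reproduces_kobs(self):
        dataset, _ = generate_chevron(*PHASE1, noise_log_sd=0.0)
        fit = fit_chevron(dataset)
        assert np.allclose(
            chevron_kobs(fit, dataset.denaturant), dataset.k_obs, rtol=1e-8
        )

    def test_noisy_recovery_within_extrapolation_uncertainty(self):
        dataset, truth = generate_chevron(*PHASE1, noise_log_sd=0.05, seed=3)
        fit = fit_chevron(dataset)
        assert np.log10(fit.ku_h2o) == pytest.approx(
            np.log10(truth["ku_h2o"]), abs=0.5
        )
        assert fit.dg == pytest.approx(truth["dg"], abs=0.6)

    def test_derived_identities(self):
        dataset, _ = generate_chevron(*PHASE1, noise_log_sd=0.05, seed=4)
        fit = fit_chevron(dataset)
        assert fit.d50 * fit.m_kin == pytest.approx(fit.dg, rel=1e-12)
        assert fit.m_kin == pytest.approx(abs(fit.mf) + fit.mu, rel=1e-12)

    def test_single_arm_unidentifiable(self):
        d = np.linspace(0.5, 3.0, 10)
        k = 0.14 * np.exp(-1.09 * d / Conditions().rt)
        with pytest.raises(UnidentifiableError, match="unfolding"):
            fit_chevron(ChevronDataset(d, k, ["refolding"] * 10))

    def test_uchl1_parameters_regenerate_published_dg(self):
        # cross-paralog check: UCH-L1 chevron parameters give ΔG = 4.90
        fit = ChevronFit(*UCHL1)
        assert fit.dg == pytest.approx(4.90, abs=0.02)


class TestDeltaG:
    def test_equal_rates_zero(self):
        assert delta_g_from_rates(1.0, 1.0) == 0.0

    @pytest.mark.parametrize(
        "kf, ku, expected",
        [
            (0.14, 8.1e-9, 9.87),   # slowest phase of the UCH-L5 domain
            (49.0, 2.6e-4, 7.19),   # UCH-L3
            (0.3, 7.6e-5, 4.90),    # UCH-L1
        ],
    )
    def test_published_free_energies(self, kf, ku, expected, cond298):
        assert delta_g_from_rates(kf, ku, cond298) == pytest.approx(expected, abs=0.02)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(min_value=1e-9, max_value=1e3),
        st.floats(min_value=1e-9, max_value=1e3),
    )
    def test_antisymmetry(self, kf, ku):
        assert delta_g_from_rates(kf, ku) == pytest.approx(
            -delta_g_from_rates(ku, kf), abs=1e-10
        )


class TestPhase4Inconsistency:
    """The fastest phase's printed m_kin (1.73) conflicts with its own
    chevron parameters: mu − mf = 2.46, and the printed midpoint 2.52 M is
    consistent with 2.46, not 1.73.  The package derives m_kin from the
    chevron parameters; this regression test documents the discrepancy."""

    def test_derived_values_self_consistent(self, cond298):
        fit = ChevronFit(*PHASE4)
        assert fit.m_kin == pytest.approx(2.46, abs=1e-12)
        assert fit.m_kin != pytest.approx(1.73, abs=0.1)  # printed value
        # the printed [D]50% of 2.52 M follows from the derived m_kin
        assert fit.d50 == pytest.approx(2.52, rel=0.005)
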