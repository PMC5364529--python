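"""Equilibrium unfolding: populations, SVD diagnostics, and global fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from knotfold.conditions import Conditions
from knotfold.equilibrium import (
    TitrationSeries,
    count_significant_components,
    fit_lambda_max,
    fit_two_state_equilibrium,
    fraction_denatured,
    svd_decompose,
)
from knotfold.exceptions import DataError, FitError
from knotfold.synthetic import generate_equilibrium_titration


class TestFractionDenatured:
    def test_midpoint_is_half(self, cond298):
        dg, m = 9.0, 2.5
        assert fraction_denatured(dg, m, dg / m, cond298) == pytest.approx(0.5)

    def test_published_midpoint(self, cond298):
        # global-fit parameters put the transition midpoint at 3.53 M urea
        assert fraction_denatured(9.21, 2.61, 3.53, cond298) == pytest.approx(
            0.500, abs=0.003
        )

    def test_native_limit_in_water(self, cond298):
        assert fraction_denatured(9.21, 2.61, 0.0, cond298) < 2e-7

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(min_value=2.0, max_value=15.0),
        st.floats(min_value=0.5, max_value=5.0),
    )
    def test_monotone_in_denaturant(self, dg, m):
        d = np.linspace(0.0, 10.0, 50)
        f = fraction_denatured(dg, m, d)
        assert np.all(np.diff(f) >= 0)
        assert np.all((f >= 0) & (f <= 1))
        core = (f > 1e-12) & (f < 1 - 1e-12)  # strictly away from saturation
        assert np.all(np.diff(f[core]) > 0)

    def test_decreasing_in_stability(self):
        d = 3.0
        f = [fraction_denatured(dg, 2.6, d) for dg in (6.0, 8.0, 10.0)]
        assert f[0] > f[1] > f[2]


class TestSVD:
    def test_rank1_outer_product(self):
        d = np.linspace(0, 6, 20)
        spec = np.exp(-0.5 * ((np.linspace(300, 450, 30) - 330) / 20) ** 2)
        mat = np.outer(spec, 1.0 + 0.5 * d)
        series = TitrationSeries(d, [str(i) for i in range(30)], mat)
        res = svd_decompose(series)
        assert np.sum(res.singular_values > 1e-10 * res.singular_values[0]) == 1
        assert res.n_significant == 1

    def test_two_state_noiseless_has_two_components(self):
        series, _ = generate_equilibrium_titration(noise=0.0, seed=0)
        res = svd_decompose(series)
        nonzero = np.sum(res.singular_values > 1e-10 * res.singular_values[0])
        assert nonzero == 2
        assert res.n_significant == 2

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(3)
        d = np.linspace(0, 6, 10)
        mat = rng.normal(size=(12, 10))
        series = TitrationSeries(d, [str(i) for i in range(12)], mat)
        res = svd_decompose(series)
        recon = (res.basis_spectra * res.singular_values) @ res.coefficients.T
        assert np.linalg.norm(recon - mat) / np.linalg.norm(mat) < 1e-12

    def test_singular_values_descending(self):
        series, _ = generate_equilibrium_titration(noise=0.01, seed=5)
        res = svd_decompose(series)
        assert np.all(np.diff(res.singular_values) <= 0)
        assert np.all(res.singular_values >= 0)

    def test_noisy_titration_counts_two(self):
        series, _ = generate_equilibrium_titration(noise=0.01, seed=11)
        assert svd_decompose(series).n_significant == 2

    def test_pure_noise_counts_zero(self):
        rng = np.random.default_rng(7)
        series = TitrationSeries(
            np.linspace(0, 6, 41),
            [str(i) for i in range(121)],
            rng.normal(size=(121, 41)),
        )
        assert svd_decompose(series).n_significant == 0

    def test_count_invariant_to_positive_scaling(self):
        series, _ = generate_equilibrium_titration(noise=0.01, seed=13)
        res1 = svd_decompose(series)
        series.signal_matrix = series.signal_matrix * 37.5
        res2 = svd_decompose(series)
        assert res1.n_significant == res2.n_significant

    def test_threshold_validation(self):
        series, _ = generate_equilibrium_titration(noise=0.0, seed=0)
        res = svd_decompose(series)
        with pytest.raises(ValueError):
            count_significant_components(res, threshold=1.5)


class TestTwoStateFit:
    def test_noiseless_exact_recovery(self):
        series, truth = generate_equilibrium_titration(noise=0.0, seed=1)
        fit = fit_two_state_equilibrium(series)
        assert fit.dg_h2o == pytest.approx(truth["dg"], rel=1e-6)
        assert fit.m_value == pytest.approx(truth["m"], rel=1e-6)
        assert fit.d50 * fit.m_value == pytest.approx(fit.dg_h2o, rel=1e-9)

    def test_global_fit_recovers_study_parameters(self):
        series, _ = generate_equilibrium_titration(
            dg=9.21, m=2.61, noise=0.005, seed=1
        )
        fit = fit_two_state_equilibrium(series)
        assert fit.dg_h2o == pytest.approx(9.21, abs=0.3)
        assert fit.m_value == pytest.approx(2.61, abs=0.1)

    def test_fluorescence_style_d50(self):
        # the fluorescence-only parameter set puts the midpoint near 3.50 M
        series, _ = generate_equilibrium_titration(
            dg=9.56, m=2.73, noise=0.003, seed=2
        )
        fit = fit_two_state_equilibrium(series)
        assert fit.d50 == pytest.approx(3.50, abs=0.05)

    def test_shared_fit_matches_single_series_on_noiseless_data(self):
        fl, _ = generate_equilibrium_titration(noise=0.0, seed=0, probe="fluorescence")
        cd, _ = generate_equilibrium_titration(
            noise=0.0, seed=0, probe="far-UV CD",
            wavelengths=np.linspace(200, 260, 25), native_peak=222.0,
            denatured_peak=205.0,
        )
        cd.label = "cd"
        joint = fit_two_state_equilibrium([fl, cd])
        single = fit_two_state_equilibrium(fl)
        assert joint.dg_h2o == pytest.approx(single.dg_h2o, rel=1e-6)
        assert joint.m_value == pytest.approx(single.m_value, rel=1e-6)

    def test_unbracketed_transition_raises(self):
        series, _ = generate_equilibrium_titration(
            dg=9.21, m=2.61, d_max=1.5, noise=0.0, seed=0
        )
        with pytest.raises(FitError):
            fit_two_state_equilibrium(series)

    def test_too_few_points_rejected(self):
        series, _ = generate_equilibrium_titration(n_points=6, noise=0.0, seed=0)
        with pytest.raises(DataError):
            fit_two_state_equilibrium(series)


class TestLambdaMax:
    @staticmethod
    def _lambda_max_curve(dg=9.21, m=2.61, noise=0.0, seed=0):
        # equal band amplitudes so the peak-position midpoint coincides with
        # the population midpoint
        series, truth = generate_equilibrium_titration(
            dg=dg, m=m, noise=noise, seed=seed, denatured_amp=1.0,
            wavelengths=np.linspace(300.0, 450.0, 601),
        )
        w = np.array([float(c) for c in series.channels])
        lam = w[np.argmax(series.signal_matrix, axis=0)]
        return series.denaturant_concs, lam, truth

    def test_sigmoid_recovery_noiseless(self):
        d = np.linspace(0, 6, 41)
        f = fraction_denatured(9.0, 2.5, d)
        lam = 330.0 * (1 - f) + 350.0 * f
        fit = fit_lambda_max(d, lam)
        assert fit.dg_h2o == pytest.approx(9.0, rel=1e-6)
        assert fit.m_value == pytest.approx(2.5, rel=1e-6)

    def test_midpoint_from_spectral_peak_shift(self):
        d, lam, truth = self._lambda_max_curve(noise=0.002, seed=9)
        fit = fit_lambda_max(d, lam)
        assert fit.d50 == pytest.approx(truth["d50"], abs=0.05)

    def test_flat_curve_raises(self):
        d = np.linspace(0, 6, 41)
        with pytest.raises(FitError):
            fit_lambda_max(d, np.full_like(d, 340.0))
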