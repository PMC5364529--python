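"""Seeded synthetic-data generators for every analysis in the package.

Each generator emits a dataset in the native type of the module it feeds,
together with a ground-truth record, so every fitting stage can be
validated by parameter recovery.  Defaults reproduce the published study
conditions: 41-point urea titrations from 0–6 M (2.5% increments) with
spectra built from two Gaussian emission bands whose weights follow the
two-state populations; stopped-flow traces as exponential sums behind a
2 ms dead time; interrupted-refolding series by exact three-state
propagation; HDX decays from a per-residue log-PF field with intrinsic
rates; Gibbs–Helmholtz melting curves; and one-site ITC isotherms with
perfusion-displacement bookkeeping.  Noise is Gaussian, proportional to the
signal span (coefficient of variation), with a fixed seed making every
dataset byte-reproducible.

The preset registry keys the published parameter sets by protein and
kinetic phase (the equilibrium parameter sets, the four chevron phases, the
cross-paralog kinetics, and the two ITC global fits).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .binding import ITCIsotherm, T0_STANDARD, one_site_expected_heats
from .conditions import Conditions, R_KCAL
from .double_jump import InterruptedRefoldingSeries, LinearThreeState, populations
from .equilibrium import TitrationSeries, fraction_denatured
from .exceptions import DataError
from .hdx import IntrinsicRateContext, ResidueExchangeSeries, intrinsic_exchange_rate
from .kinetics import ChevronDataset, ChevronFit, KineticTrace, chevron_kobs
from .thermal import MeltCurve, gibbs_helmholtz

__all__ = [
    "GeneratorSpec",
    "PRESETS",
    "generate",
    "generate_equilibrium_titration",
    "generate_kinetic_trace",
    "generate_chevron",
    "generate_interrupted_refolding",
    "generate_hdx_series",
    "generate_melt_curve",
    "generate_itc_isotherm",
]


@dataclass
class GeneratorSpec:
    """Declarative request for one synthetic dataset."""

    kind: str
    parameters: dict = field(default_factory=dict)
    noise: float = 0.01
    noise_model: str = "proportional_cv"
    seed: int = 0


# Published parameter sets, keyed by protein / phase / probe: the reported
# equilibrium, chevron, and binding thermodynamics of the three UCH paralogs.
PRESETS = {
    # equilibrium unfolding (ΔG kcal/mol, m kcal/mol/M)
    "uchl5_eq_global": {"kind": "equilibrium_titration", "dg": 9.21, "m": 2.61},
    "uchl5_eq_fluorescence": {"kind": "equilibrium_titration", "dg": 9.56, "m": 2.73},
    "uchl5_eq_cd": {"kind": "equilibrium_titration", "dg": 9.05, "m": 2.60},
    "uchl1_eq": {"kind": "equilibrium_titration", "dg": 8.83, "m": 2.95},
    "uchl3_eq": {"kind": "equilibrium_titration", "dg": 7.11, "m": 2.28},
    # chevron phases of the UCH-L5 catalytic domain
    "uchl5_phase1": {"kind": "chevron", "kf": 0.14, "mf": -1.09, "ku": 8.1e-9, "mu": 1.88},
    "uchl5_phase2": {"kind": "chevron", "kf": 0.80, "mf": -0.82, "ku": 1.9e-6, "mu": 1.41},
    "uchl5_phase3": {"kind": "chevron", "kf": 10.3, "mf": -0.96, "ku": 3.1e-4, "mu": 1.07},
    "uchl5_phase4": {"kind": "chevron", "kf": 1120.0, "mf": -1.65, "ku": 3.1e-2, "mu": 0.81},
    # cross-paralog slowest phases
    "uchl1_kin": {"kind": "chevron", "kf": 0.3, "mf": -1.06, "ku": 7.6e-5, "mu": 0.74},
    "uchl3_kin": {"kind": "chevron", "kf": 49.0, "mf": -1.28, "ku": 2.6e-4, "mu": 0.83},
    # variable-temperature ITC global parameters (ΔH kcal/mol at 25 degC,
    # ΔS cal/mol/K, ΔCp kcal/mol/K)
    "uchl1_itc": {"kind": "itc_series", "dh0": -5.63, "ds0": 11.28, "dcp": -0.53},
    "uchl3_itc": {"kind": "itc_series", "dh0": -12.26, "ds0": -13.33, "dcp": -0.72},
}


def _noise_sd(signal: np.ndarray, spec_noise: float, model: str) -> float:
    if model == "gaussian_sd":
        return spec_noise
    if model == "proportional_cv":
        span = np.ptp(signal)
        return spec_noise * (span if span > 0 else 1.0)
    raise DataError(f"unknown noise model '{model}'")


def generate_equilibrium_titration(
    dg: float = 9.21,
    m: float = 2.61,
    n_points: int = 41,
    d_max: float = 6.0,
    wavelengths: np.ndarray | None = None,
    native_peak: float = 330.0,
    denatured_peak: float = 350.0,
    band_width: float = 18.0,
    denatured_amp: float = 0.55,
    baseline_slope: float = 0.01,
    noise: float = 0.01,
    noise_model: str = "proportional_cv",
    seed: int = 0,
    conditions: Conditions = Conditions(),
    probe: str = "fluorescence",
):
    """Two-state titration spectra from two Gaussian emission bands.

    The native band (330 nm) is replaced by a red-shifted, weaker denatured
    band (350 nm) as the denatured population grows; band amplitudes drift
    linearly with denaturant to emulate instrument baselines.  Defaults
    follow the study conditions: 41 titration points in 2.5% increments of
    the 0–6 M urea range, 1% proportional noise.
    """
    rng = np.random.default_rng(seed)
    d = np.linspace(0.0, d_max, n_points)
    if wavelengths is None:
        wavelengths = np.linspace(300.0, 450.0, 121)
    w = np.asarray(wavelengths, dtype=float)
    f_d = fraction_denatured(dg, m, d, conditions)
    band_n = np.exp(-0.5 * ((w - native_peak) / band_width) ** 2)
    band_d = denatured_amp * np.exp(-0.5 * ((w - denatured_peak) / band_width) ** 2)
    amp_n = 1.0 + baseline_slope * d
    amp_d = 1.0 - baseline_slope * d
    clean = np.outer(band_n, amp_n * (1.0 - f_d)) + np.outer(band_d, amp_d * f_d)
    sd = _noise_sd(clean, noise, noise_model)
    signal = clean + rng.normal(0.0, sd, clean.shape) if noise > 0 else clean
    series = TitrationSeries(
        denaturant_concs=d,
        channels=[f"{x:.2f}" for x in w],
        signal_matrix=signal,
        probe=probe,
        label=f"synthetic-{probe}",
    )
    truth = {"dg": dg, "m": m, "d50": dg / m, "noise_sd": sd, "seed": seed}
    return series, truth


def generate_kinetic_trace(
    rates: Sequence[float],
    amplitudes: Sequence[float],
    offset: float = 1.0,
    final_denaturant: float = 0.73,
    dead_time: float = 2e-3,
    t_max: float | None = None,
    n_points: int = 1000,
    noise: float = 0.01,
    noise_model: str = "proportional_cv",
    seed: int = 0,
):
    """Multi-exponential stopped-flow trace sampled behind the dead time."""
    rng = np.random.default_rng(seed)
    rates = np.asarray(rates, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if t_max is None:
        t_max = 5.0 / rates.min()
    t = np.geomspace(max(dead_time, 1e-5), t_max, n_points)
    clean = offset + sum(a * np.exp(-k * t) for a, k in zip(amplitudes, rates))
    sd = _noise_sd(clean, noise, noise_model)
    signal = clean + rng.normal(0.0, sd, clean.shape) if noise > 0 else clean
    trace = KineticTrace(t, signal, final_denaturant, dead_time)
    truth = {
        "rates": rates.tolist(), "amplitudes": amplitudes.tolist(),
        "offset": offset, "noise_sd": sd, "seed": seed,
    }
    return trace, truth


def generate_chevron(
    kf: float,
    mf: float,
    ku: float,
    mu: float,
    refold_concs: np.ndarray | None = None,
    unfold_concs: np.ndarray | None = None,
    noise_log_sd: float = 0.05,
    seed: int = 0,
    conditions: Conditions = Conditions(),
    phase_label: int = 1,
):
    """Chevron dataset with log-normal rate noise (5% default).

    Refolding points cover 0.7–3 M and unfolding points 4–8 M final urea,
    fifteen per arm, matching a single-jump series around a ~3.3 M midpoint.
    """
    rng = np.random.default_rng(seed)
    if refold_concs is None:
        refold_concs = np.linspace(0.7, 3.0, 15)
    if unfold_concs is None:
        unfold_concs = np.linspace(4.0, 8.0, 15)
    d = np.concatenate([refold_concs, unfold_concs])
    branch = ["refolding"] * len(refold_concs) + ["unfolding"] * len(unfold_concs)
    k_clean = chevron_kobs((kf, mf, ku, mu), d, conditions)
    k_obs = k_clean * np.exp(rng.normal(0.0, noise_log_sd, k_clean.shape)) \
        if noise_log_sd > 0 else k_clean
    dataset = ChevronDataset(d, k_obs, branch, phase_label=phase_label)
    fit_truth = ChevronFit(kf, mf, ku, mu, conditions=conditions)
    truth = {
        "kf_h2o": kf, "mf": mf, "ku_h2o": ku, "mu": mu,
        "dg": fit_truth.dg, "m_kin": fit_truth.m_kin, "d50": fit_truth.d50,
        "seed": seed,
    }
    return dataset, truth


def generate_interrupted_refolding(
    model: LinearThreeState | None = None,
    aging_times: np.ndarray | None = None,
    probe_rates: Sequence[float] = (30.0, 3.0),
    final_denaturant: float = 4.64,
    t_max: float = 2.0,
    n_points: int = 400,
    noise: float = 0.02,
    noise_model: str = "proportional_cv",
    seed: int = 0,
):
    """Interrupted-refolding series from exact three-state propagation.

    During aging the populations evolve under the A ⇌ B ⇌ C scheme
    (A = denatured); the post-jump unfolding trace then shows one
    exponential per observable species, with amplitudes proportional to the
    populations of B and C at the end of the aging period.  ``probe_rates``
    are the post-jump unfolding rates of the two phases.
    """
    rng = np.random.default_rng(seed)
    if model is None:
        model = LinearThreeState(0.03, 0.003, 0.3, 0.03)
    if aging_times is None:
        aging_times = np.geomspace(0.01, 100.0, 10)
    aging_times = np.asarray(aging_times, dtype=float)
    pops = populations(model, aging_times)  # 3 x n_age
    t = np.geomspace(2e-3, t_max, n_points)
    traces = []
    for j in range(len(aging_times)):
        amp_c = pops[2, j]  # native -> slower unfolding phase
        amp_b = pops[1, j]  # intermediate -> faster unfolding phase
        clean = 1.0 + amp_b * np.exp(-probe_rates[0] * t) \
            + amp_c * np.exp(-probe_rates[1] * t)
        sd = _noise_sd(clean, noise, noise_model) if noise > 0 else 0.0
        sub = rng.normal(0.0, sd, clean.shape) if noise > 0 else 0.0
        traces.append(KineticTrace(t, clean + sub, final_denaturant, 2e-3))
    series = InterruptedRefoldingSeries(aging_times, traces)
    truth = {
        "k_ab": model.k_ab, "k_ba": model.k_ba,
        "k_bc": model.k_bc, "k_cb": model.k_cb,
        "probe_rates": list(probe_rates),
        "populations": pops.tolist(), "seed": seed,
    }
    return series, truth


def generate_hdx_series(
    sequence: str,
    log_pf: np.ndarray,
    context: IntrinsicRateContext | None = None,
    times: np.ndarray | None = None,
    noise: float = 0.05,
    noise_model: str = "proportional_cv",
    seed: int = 0,
):
    """Per-residue exponential intensity decays from a log-PF field.

    ``log_pf[i]`` is the log10 protection factor of residue ``i + 2`` (the
    first amide with an exchangeable proton).  Observed rates are
    k_int / PF; sampling times default to 12 log-spaced points covering
    5 / k_obs for each residue.  Prolines are skipped.
    """
    rng = np.random.default_rng(seed)
    if context is None:
        context = IntrinsicRateContext(sequence=sequence)
    log_pf = np.asarray(log_pf, dtype=float)
    series_list = []
    truth_rows = []
    for offset, lp in enumerate(log_pf):
        idx = offset + 2
        if idx > len(sequence):
            break
        if sequence[idx - 1] == "P":
            continue
        k_int = intrinsic_exchange_rate(context, idx)
        k_obs = k_int / 10.0**lp
        if times is None:
            t = np.geomspace(0.05 / k_obs, 5.0 / k_obs, 12)
        else:
            t = np.asarray(times, dtype=float)
        clean = np.exp(-k_obs * t)
        sd = _noise_sd(clean, noise, noise_model) if noise > 0 else 0.0
        noisy = np.clip(clean + rng.normal(0.0, sd, clean.shape), 0.0, None) \
            if noise > 0 else clean
        series_list.append(
            ResidueExchangeSeries(idx, sequence[idx - 1], t, noisy)
        )
        truth_rows.append({"residue": idx, "k_int": k_int,
                           "k_obs": k_obs, "log10_pf": lp})
    truth = {"records": truth_rows, "seed": seed}
    return series_list, truth


def generate_melt_curve(
    tm: float = 328.0,
    dh_m: float = 100.0,
    dcp: float = 0.0,
    baselines: tuple = (-20.0, 0.01, -2.0, 0.005),
    t_min: float = 298.0,
    t_max: float = 353.0,
    n_points: int = 111,
    noise: float = 0.01,
    noise_model: str = "proportional_cv",
    seed: int = 0,
    ligand_label: str | None = None,
):
    """Gibbs–Helmholtz melting curve in CD units with linear baselines.

    The 298–353 K default span mirrors a 25–80 °C scan.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(t_min, t_max, n_points)
    dg = gibbs_helmholtz(dh_m, tm, dcp, t)
    ff = 1.0 / (1.0 + np.exp(-dg / (R_KCAL * t)))
    a_n, b_n, a_d, b_d = baselines
    clean = (a_n + b_n * t) * ff + (a_d + b_d * t) * (1.0 - ff)
    sd = _noise_sd(clean, noise, noise_model) if noise > 0 else 0.0
    signal = clean + rng.normal(0.0, sd, clean.shape) if noise > 0 else clean
    curve = MeltCurve(t, signal, ligand_label=ligand_label)
    truth = {"tm": tm, "dh_m": dh_m, "dcp": dcp, "seed": seed}
    return curve, truth


def generate_itc_isotherm(
    ka: float,
    dh: float,
    n_sites: float = 1.0,
    cell_concentration: float = 27.5,
    syringe_concentration: float = 275.0,
    cell_volume: float = 200.0,
    n_injections: int = 20,
    injection_volume: float = 2.0,
    offset_heat: float = 0.0,
    temperature: float = T0_STANDARD,
    noise: float = 0.02,
    noise_model: str = "proportional_cv",
    seed: int = 0,
):
    """One-site ITC isotherm under the study's concentration scheme
    (27.5 μM cell, 275 μM syringe), 2% proportional heat noise."""
    rng = np.random.default_rng(seed)
    volumes = np.full(n_injections, injection_volume)
    iso = ITCIsotherm(
        cell_concentration, syringe_concentration, cell_volume,
        volumes, np.zeros(n_injections), temperature,
    )
    clean = one_site_expected_heats(n_sites, ka, dh, iso, offset_heat)
    sd = _noise_sd(clean, noise, noise_model) if noise > 0 else 0.0
    heats = clean + rng.normal(0.0, sd, clean.shape) if noise > 0 else clean
    iso.heats = heats
    truth = {"ka": ka, "dh": dh, "n_sites": n_sites,
             "offset_heat": offset_heat, "seed": seed}
    return iso, truth


def itc_series_from_thermo(
    dh0: float,
    ds0: float,
    dcp: float,
    temperatures: Sequence[float] = (293.15, 298.15, 303.15, 310.15),
    noise: float = 0.03,
    seed: int = 0,
    **isotherm_kwargs,
):
    """Isotherms at several temperatures from a (ΔH₀, ΔS₀, ΔCp) model.

    ΔH(T) = ΔH₀ + ΔCp(T−T₀) and ΔS(T) = ΔS₀ + ΔCp·ln(T/T₀) set the
    per-temperature one-site parameters; each isotherm gets its own noise
    substream derived from *seed*.
    """
    out = []
    for j, temp in enumerate(temperatures):
        dh_t = dh0 + dcp * (temp - T0_STANDARD)
        ds_t = ds0 / 1000.0 + dcp * np.log(temp / T0_STANDARD)  # kcal/mol/K
        dg_t = dh_t - temp * ds_t
        ka_t = float(np.exp(-dg_t / (R_KCAL * temp)))
        iso, truth = generate_itc_isotherm(
            ka_t, dh_t, temperature=temp, noise=noise,
            seed=seed * 1000 + j, **isotherm_kwargs,
        )
        truth.update({"dh0": dh0, "ds0": ds0, "dcp": dcp})
        out.append((iso, truth))
    return out


_KIND_DISPATCH = {
    "equilibrium_titration": generate_equilibrium_titration,
    "kinetic_trace": generate_kinetic_trace,
    "chevron": generate_chevron,
    "interrupted_refolding": generate_interrupted_refolding,
    "hdx_series": generate_hdx_series,
    "melt_curve": generate_melt_curve,
    "itc_isotherm": generate_itc_isotherm,
}

_PRESET_PARAM_MAP = {
    "equilibrium_titration": {"dg": "dg", "m": "m"},
    "chevron": {"kf": "kf", "mf": "mf", "ku": "ku", "mu": "mu"},
}


def generate(spec: GeneratorSpec):
    """Dispatch a :class:`GeneratorSpec` to the matching generator."""
    if spec.kind == "itc_series":
        return itc_series_from_thermo(seed=spec.seed, noise=spec.noise,
                                      **spec.parameters)
    if spec.kind not in _KIND_DISPATCH:
        raise DataError(f"unknown generator kind '{spec.kind}'")
    fn = _KIND_DISPATCH[spec.kind]
    kwargs = dict(spec.parameters)
    if spec.kind == "chevron":
        kwargs.setdefault("noise_log_sd", spec.noise)
        return fn(seed=spec.seed, **kwargs)
    return fn(seed=spec.seed, noise=spec.noise,
              noise_model=spec.noise_model, **kwargs)


def spec_from_preset(preset: str, seed: int = 0, noise: float | None = None) -> GeneratorSpec:
    """Build a GeneratorSpec from the published-parameter preset registry."""
    if preset not in PRESETS:
        raise DataError(f"unknown preset '{preset}'; available: {sorted(PRESETS)}")
    entry = dict(PRESETS[preset])
    kind = entry.pop("kind")
    spec = GeneratorSpec(kind=kind, parameters=entry, seed=seed)
    if noise is not None:
        spec.noise = noise
    return spec
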