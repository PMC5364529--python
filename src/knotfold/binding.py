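"""ITC binding thermodynamics: one-site isotherms and variable-temperature
global analysis.

A titration in a perfusion cell displaces cell contents with every
injection; the standard displacement bookkeeping dilutes the cell species
and accounts for the heat carried out with the displaced volume.  Per
injection the heat is V0·ΔH·Δ[bound], with the bound concentration from the
closed-form one-site quadratic

    [PL] = ½[(n·P + L + Kd) − sqrt((n·P + L + Kd)² − 4·n·P·L)].

The temperature dependence of the per-temperature fits yields the binding
heat-capacity change through

    ΔH(T) = ΔH₀ + ΔCp·(T − T₀),   ΔS(T) = ΔS₀ + ΔCp·ln(T/T₀),

fit jointly to the observed (Ka, ΔH) at each temperature.  Derived
quantities use ΔG = ΔH − T·ΔS and K_D = exp(ΔG/RT); the reference
temperature is 298.15 K (standard conditions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .conditions import Conditions, R_KCAL
from .exceptions import DataError, FitError, UnidentifiableError

__all__ = [
    "ITCIsotherm",
    "OneSiteFit",
    "BindingThermo",
    "one_site_expected_heats",
    "fit_one_site",
    "global_fit_temperature_series",
    "binding_free_energy",
    "kd_from_dg",
]

T0_STANDARD = 298.15


@dataclass
class ITCIsotherm:
    """Integrated injection heats of one titration."""

    cell_concentration: float      # μM, titrand (protein in the cell)
    syringe_concentration: float   # μM, titrant (ubiquitin)
    cell_volume: float             # μL
    injection_volumes: np.ndarray  # μL
    heats: np.ndarray              # μcal per injection
    temperature: float = T0_STANDARD

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        self.heats = np.asarray(self.heats, dtype=float)
        if self.cell_concentration <= 0 or self.syringe_concentration <= 0:
            raise DataError("concentrations must be positive")
        if np.any(self.injection_volumes <= 0):
            raise DataError("injection volumes must be positive")
        if len(self.heats) != len(self.injection_volumes):
            raise DataError("one heat per injection required")
        if not np.all(np.isfinite(self.heats)):
            raise DataError("heats must be finite")


@dataclass
class OneSiteFit:
    """Single-site fit of one isotherm."""

    n_sites: float
    ka: float                      # M^-1
    dh: float                      # kcal/mol
    offset_heat: float             # μcal per injection (dilution heat)
    stderr: dict = field(default_factory=dict)
    rss: float = float("nan")
    temperature: float = T0_STANDARD
    c_value: float = float("nan")
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ka <= 0:
            raise DataError("ka must be positive")


@dataclass
class BindingThermo:
    """Temperature-dependent binding thermodynamics at T0 = 298.15 K."""

    dh0: float                     # kcal/mol at T0
    ds0: float                     # cal/mol/K at T0
    dcp: float                     # kcal/mol/K
    reference_temperature: float = T0_STANDARD
    stderr: dict = field(default_factory=dict)

    @property
    def dg(self) -> float:
        """ΔG = ΔH − T·ΔS at the reference temperature, kcal/mol."""
        return binding_free_energy(self.dh0, self.ds0, self.reference_temperature)

    @property
    def tds(self) -> float:
        """T·ΔS at the reference temperature, kcal/mol."""
        return self.reference_temperature * self.ds0 / 1000.0

    @property
    def kd(self) -> float:
        """Dissociation constant at the reference temperature, μM."""
        return kd_from_dg(self.dg, Conditions(temperature=self.reference_temperature))


def _cell_factors(cell_volume: float, injection_volumes: np.ndarray):
    """Perfusion displacement factors after each injection.

    Returns (titrand dilution factor, titrant concentration factor) per
    injection, for cumulative injected volume v against cell volume V0.
    """
    v_cum = np.cumsum(injection_volumes)
    v0 = cell_volume
    dil = (1.0 - v_cum / (2.0 * v0)) / (1.0 + v_cum / (2.0 * v0))
    titr = (v_cum / v0) / (1.0 + v_cum / (2.0 * v0))
    return dil, titr


def _bound_quadratic(n, p_tot, l_tot, kd):
    b = n * p_tot + l_tot + kd
    disc = np.clip(b * b - 4.0 * n * p_tot * l_tot, 0.0, None)
    return 0.5 * (b - np.sqrt(disc))


def one_site_expected_heats(
    n_sites: float,
    ka: float,
    dh: float,
    isotherm: ITCIsotherm,
    offset_heat: float = 0.0,
) -> np.ndarray:
    """Expected heat per injection (μcal) for the one-site model.

    Uses the displaced-volume bookkeeping for both species, the closed-form
    one-site quadratic for the bound concentration after every injection,
    and the mid-injection correction for heat carried out of the cell.
    """
    dil, titr = _cell_factors(isotherm.cell_volume, isotherm.injection_volumes)
    p_tot = isotherm.cell_concentration * 1e-6 * dil        # M
    l_tot = isotherm.syringe_concentration * 1e-6 * titr    # M
    kd = 1.0 / ka
    bound = _bound_quadratic(n_sites, p_tot, l_tot, kd)     # M
    v0_l = isotherm.cell_volume * 1e-6                      # L
    q_total = bound * v0_l * dh * 1e9                       # mol x kcal/mol -> μcal
    dv = isotherm.injection_volumes * 1e-6                  # L
    q_prev = np.concatenate([[0.0], q_total[:-1]])
    heats = q_total - q_prev + (dv / v0_l) * 0.5 * (q_total + q_prev)
    return heats + offset_heat


def fit_one_site(isotherm: ITCIsotherm) -> OneSiteFit:
    """Least-squares one-site fit of an isotherm (n, Ka, ΔH, offset).

    The Wiseman c-value n·Ka·[cell] must fall in the fittable 0.5–1000
    range; outside it the fit proceeds but is flagged.  A flat isotherm
    raises an unidentifiable-Ka error.
    """
    heats = isotherm.heats
    if np.ptp(heats) < 1e-9 * max(1.0, np.abs(heats).max()):
        raise UnidentifiableError("flat isotherm: Ka is unidentifiable")

    total_titrant = (
        isotherm.syringe_concentration * isotherm.injection_volumes.sum()
        / isotherm.cell_volume
    )
    dh0 = np.sum(heats) / (isotherm.cell_concentration * 1e-6
                           * isotherm.cell_volume * 1e-6 * 1e9)

    def resid(x):
        n, log_ka, dh, off = x
        return one_site_expected_heats(n, np.exp(log_ka), dh, isotherm, off) - heats

    best = None
    for log_ka0 in np.log(10.0 ** np.array([4.0, 5.5, 7.0, 8.5])):
        sol = least_squares(
            resid,
            [1.0, log_ka0, dh0 if abs(dh0) > 1e-3 else -5.0, 0.0],
            bounds=([0.1, np.log(1e2), -1e3, -1e6], [10.0, np.log(1e12), 1e3, 1e6]),
            xtol=1e-14, ftol=1e-15,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise FitError("one-site fit did not converge")
    n_fit, log_ka, dh_fit, off = best.x
    ka_fit = float(np.exp(log_ka))
    rss = float(2 * best.cost)
    c_value = n_fit * ka_fit * isotherm.cell_concentration * 1e-6
    flags = []
    if not 0.5 <= c_value <= 1000.0:
        flags.append(
            f"c-value {c_value:.3g} outside the fittable range 0.5-1000; "
            "Ka is poorly constrained"
        )
    dof = max(len(heats) - 4, 1)
    stderr = {}
    try:
        cov = np.linalg.inv(best.jac.T @ best.jac) * (rss / dof)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        stderr = {
            "n_sites": float(se[0]),
            "ka": float(se[1]) * ka_fit,
            "dh": float(se[2]),
            "offset_heat": float(se[3]),
        }
    except np.linalg.LinAlgError:
        pass
    return OneSiteFit(
        n_sites=float(n_fit), ka=ka_fit, dh=float(dh_fit), offset_heat=float(off),
        stderr=stderr, rss=rss, temperature=isotherm.temperature,
        c_value=float(c_value), flags=flags,
    )


def global_fit_temperature_series(
    fits: Sequence[OneSiteFit],
    reference_temperature: float = T0_STANDARD,
) -> BindingThermo:
    """Global ΔCp model over per-temperature one-site fits.

    Fits (ΔH₀, ΔS₀, ΔCp) to the observed ΔH(T) and ln Ka(T) jointly.  At
    least three distinct temperatures are required, otherwise ΔCp cannot be
    separated from ΔH₀.
    """
    temps = np.array([f.temperature for f in fits])
    if len(np.unique(np.round(temps, 6))) < 3:
        raise UnidentifiableError(
            "need at least three temperatures: dcp is unidentifiable from two"
        )
    dh_obs = np.array([f.dh for f in fits])
    lnka_obs = np.array([np.log(f.ka) for f in fits])
    t0 = reference_temperature

    def model(x):
        dh0, ds0_cal, dcp = x
        dh_t = dh0 + dcp * (temps - t0)
        ds_t = ds0_cal / 1000.0 + dcp * np.log(temps / t0)  # kcal/mol/K
        dg_t = dh_t - temps * ds_t
        lnka = -dg_t / (R_KCAL * temps)
        return dh_t, lnka

    # scale residuals so enthalpy (kcal) and ln Ka contribute comparably
    def resid(x):
        dh_t, lnka = model(x)
        return np.concatenate([(dh_t - dh_obs), (lnka - lnka_obs) * R_KCAL * temps])

    sol = least_squares(resid, [dh_obs.mean(), 0.0, -0.5], xtol=1e-14, ftol=1e-15)
    if not sol.success:
        raise FitError("temperature-series global fit did not converge")
    dh0, ds0_cal, dcp = sol.x
    rss = float(2 * sol.cost)
    dof = max(2 * len(temps) - 3, 1)
    stderr = {}
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * (rss / dof)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        stderr = {"dh0": float(se[0]), "ds0": float(se[1]), "dcp": float(se[2])}
    except np.linalg.LinAlgError:
        pass
    return BindingThermo(
        dh0=float(dh0), ds0=float(ds0_cal), dcp=float(dcp),
        reference_temperature=t0, stderr=stderr,
    )


def binding_free_energy(dh: float, ds: float, temperature: float) -> float:
    """ΔG = ΔH − T·ΔS in kcal·mol⁻¹ (ΔH in kcal/mol, ΔS in cal/mol/K)."""
    return dh - temperature * ds / 1000.0


def kd_from_dg(dg: float, conditions: Conditions = Conditions(temperature=T0_STANDARD)) -> float:
    """Dissociation constant K_D = exp(ΔG/RT), reported in μM."""
    import warnings

    if dg >= 0:
        warnings.warn("non-negative binding free energy: K_D is >= 1 M")
    return float(np.exp(dg / conditions.rt) * 1e6)
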