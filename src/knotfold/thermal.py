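"""Thermal denaturation: two-state melting-curve fits and Tm shifts.

The unfolding free energy follows the Gibbs–Helmholtz relation

    ΔG(T) = ΔH_m·(1 − T/Tm) − ΔCp·[(Tm − T) + T·ln(T/Tm)],

which is zero at the melting temperature Tm by construction.  A CD melting
curve is fit to the two-state population weighted sum of linear native and
denatured baselines; fraction folded is recovered from the fitted baselines
(this is the normalisation step).  ΔCp is held fixed (default 0) unless
explicitly freed: a melting curve spanning ~55 K constrains it poorly.

Ligand-induced stabilisation is quantified as ΔTm between a ligand-bound
and an apo melt; for UCH enzymes saturated with ubiquitin these shifts are
of order 1–2 K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .conditions import R_KCAL
from .exceptions import DataError, FitError

__all__ = [
    "MeltCurve",
    "ThermalFit",
    "gibbs_helmholtz",
    "fit_thermal_two_state",
    "tm_shift",
]


@dataclass
class MeltCurve:
    """CD signal at a fixed wavelength versus temperature."""

    temperatures: np.ndarray  # kelvin, increasing
    signal: np.ndarray
    wavelength_nm: float = 215.0
    ligand_label: str | None = None

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if len(self.temperatures) < 20:
            raise DataError("need at least 20 temperature points")
        if np.any(np.diff(self.temperatures) <= 0):
            raise DataError("temperatures must be strictly increasing")
        if len(self.signal) != len(self.temperatures):
            raise DataError("signal and temperature lengths differ")


@dataclass
class ThermalFit:
    """Two-state thermal-denaturation parameters."""

    tm: float                 # kelvin
    dh_m: float               # van't Hoff enthalpy at Tm, kcal/mol
    dcp: float                # kcal/mol/K (fixed unless fitted)
    baselines: tuple          # (aN, bN, aD, bD)
    stderr: dict = field(default_factory=dict)
    rss: float = float("nan")
    n_points: int = 0

    def fraction_folded(self, temperature: np.ndarray) -> np.ndarray:
        dg = gibbs_helmholtz(self.dh_m, self.tm, self.dcp, temperature)
        return expit(np.asarray(dg) / (R_KCAL * np.asarray(temperature)))


def gibbs_helmholtz(
    dh_m: float, tm: float, dcp: float, temperature: float | np.ndarray
) -> float | np.ndarray:
    """Unfolding free energy ΔG(T), kcal·mol⁻¹, zero at Tm by construction."""
    if tm <= 0:
        raise ValueError("tm must be positive")
    t = np.asarray(temperature, dtype=float)
    dg = dh_m * (1.0 - t / tm) - dcp * ((tm - t) + t * np.log(t / tm))
    return float(dg) if np.isscalar(temperature) else dg


def _melt_design(frac_folded: np.ndarray, t: np.ndarray) -> np.ndarray:
    ff = frac_folded
    return np.column_stack([ff, t * ff, 1.0 - ff, t * (1.0 - ff)])


def fit_thermal_two_state(
    curve: MeltCurve,
    fix_dcp: float | None = 0.0,
) -> ThermalFit:
    """Fit a melting curve to the two-state Gibbs–Helmholtz model.

    Baselines are solved linearly inside the nonlinear search over
    (Tm, ΔH_m) — and ΔCp when ``fix_dcp`` is None.  Raises when no
    transition lies within the temperature range.
    """
    t, y = curve.temperatures, curve.signal
    t_lo, t_hi = t[0], t[-1]
    free_dcp = fix_dcp is None

    def frac_folded(tm, dh, dcp):
        dg = gibbs_helmholtz(dh, tm, dcp, t)
        return expit(dg / (R_KCAL * t))

    def resid(x):
        tm, dh = x[0], np.exp(x[1])
        dcp = x[2] if free_dcp else fix_dcp
        design = _melt_design(frac_folded(tm, dh, dcp), t)
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        return design @ coef - y

    # midpoint guess: steepest signal change
    slopes = np.abs(np.diff(y) / np.diff(t))
    tm0 = float(0.5 * (t[np.argmax(slopes)] + t[np.argmax(slopes) + 1]))
    best = None
    for dh0 in (50.0, 100.0, 200.0):
        x0 = [tm0, np.log(dh0)] + ([0.0] if free_dcp else [])
        sol = least_squares(
            resid, x0,
            bounds=([t_lo - 20, np.log(1.0)] + ([-5.0] if free_dcp else []),
                    [t_hi + 20, np.log(2000.0)] + ([5.0] if free_dcp else [])),
            xtol=1e-13, ftol=1e-14,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise FitError("thermal two-state fit did not converge")
    tm_fit, dh_fit = best.x[0], float(np.exp(best.x[1]))
    dcp_fit = best.x[2] if free_dcp else fix_dcp
    if not (t_lo < tm_fit < t_hi):
        raise FitError(
            f"melting transition (Tm = {tm_fit:.1f} K) is not inside the "
            f"measured range [{t_lo:.1f}, {t_hi:.1f}] K"
        )
    design = _melt_design(
        expit(gibbs_helmholtz(dh_fit, tm_fit, dcp_fit, t) / (R_KCAL * t)), t
    )
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    r = design @ coef - y
    rss = float(r @ r)
    # amplitude sanity: transition must dominate the baselines
    native = coef[0] + coef[1] * tm_fit
    denat = coef[2] + coef[3] * tm_fit
    span = np.ptp(y) if np.ptp(y) > 0 else 1.0
    if abs(native - denat) < max(3.0 * np.std(r), 1e-6 * span):
        raise FitError("no resolvable transition: baseline-only curve")
    stderr = _thermal_stderr(best, tm_fit, dh_fit, len(t), free_dcp)
    return ThermalFit(
        tm=float(tm_fit), dh_m=dh_fit, dcp=float(dcp_fit),
        baselines=tuple(coef), stderr=stderr, rss=rss, n_points=len(t),
    )


def _thermal_stderr(sol, tm, dh, n, free_dcp):
    p = 2 + (1 if free_dcp else 0) + 4
    dof = max(n - p, 1)
    rss = 2 * sol.cost
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * (rss / dof)
    except np.linalg.LinAlgError:
        return {}
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    out = {"tm": float(se[0]), "dh_m": float(se[1]) * dh}
    if free_dcp:
        out["dcp"] = float(se[2])
    return out


def tm_shift(curve_apo: MeltCurve, curve_ligand: MeltCurve, **fit_kwargs):
    """Melting-temperature shift Tm(ligand) − Tm(apo) with propagated error.

    Returns ``(delta_tm, stderr)`` in kelvin.
    """
    fit_apo = fit_thermal_two_state(curve_apo, **fit_kwargs)
    fit_lig = fit_thermal_two_state(curve_ligand, **fit_kwargs)
    delta = fit_lig.tm - fit_apo.tm
    se = float(
        np.hypot(fit_apo.stderr.get("tm", np.nan), fit_lig.stderr.get("tm", np.nan))
    )
    return delta, se
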