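"""Equilibrium chemical-denaturation analysis.

Denaturant titrations recorded as full spectra (fluorescence emission or
far-UV CD) are treated as an m × n matrix (wavelengths × titration points).
Singular value decomposition separates the spectral basis from the
denaturant dependence; the number of significant components (judged by the
first-order autocorrelation of the singular vectors, the Henry–Hofrichter
diagnostic) decides whether a two-state description suffices.  The two-state
model itself is the linear-extrapolation model,

    ΔG(D) = ΔG_H2O − m·D,
    f_D(D) = exp(−ΔG(D)/RT) / (1 + exp(−ΔG(D)/RT)),

with linear native and denatured baselines per channel; the global fit
shares ΔG_H2O and m across every channel of every probe while leaving the
four baseline parameters per channel free.  Baselines are solved by linear
least squares inside the nonlinear search (variable projection), which makes
the global fit fast and insensitive to starting values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .conditions import Conditions
from .exceptions import DataError, FitError, UnidentifiableError

logger = logging.getLogger(__name__)

__all__ = [
    "TitrationSeries",
    "SVDResult",
    "TwoStateEqParams",
    "fraction_denatured",
    "svd_decompose",
    "count_significant_components",
    "fit_two_state_equilibrium",
    "fit_lambda_max",
]


@dataclass
class TitrationSeries:
    """A denaturant titration recorded over one or more spectral channels.

    ``signal_matrix`` is m × n: one row per wavelength channel, one column
    per denaturant concentration.
    """

    denaturant_concs: np.ndarray
    channels: Sequence[str]
    signal_matrix: np.ndarray
    probe: str = "fluorescence"
    label: str = ""

    def __post_init__(self) -> None:
        self.denaturant_concs = np.asarray(self.denaturant_concs, dtype=float)
        self.signal_matrix = np.atleast_2d(np.asarray(self.signal_matrix, dtype=float))
        d = self.denaturant_concs
        if d.ndim != 1 or len(d) < 2:
            raise DataError("need at least two denaturant concentrations")
        if np.any(d < 0):
            raise DataError("denaturant concentrations must be non-negative")
        if np.any(np.diff(d) <= 0):
            raise DataError("denaturant concentrations must be strictly increasing")
        m, n = self.signal_matrix.shape
        if n != len(d):
            raise DataError(
                f"signal matrix has {n} columns but {len(d)} denaturant points"
            )
        if len(self.channels) != m:
            raise DataError(
                f"signal matrix has {m} rows but {len(self.channels)} channel labels"
            )
        if not np.all(np.isfinite(self.signal_matrix)):
            raise DataError("signal matrix contains non-finite values")

    @property
    def n_points(self) -> int:
        return len(self.denaturant_concs)


@dataclass
class SVDResult:
    """SVD of a titration matrix plus the component-significance diagnostics."""

    basis_spectra: np.ndarray          # m × r  (left singular vectors, U)
    coefficients: np.ndarray           # n × r  (right singular vectors, V)
    singular_values: np.ndarray        # r, descending
    autocorrelations_u: np.ndarray
    autocorrelations_v: np.ndarray
    n_significant: int


@dataclass
class TwoStateEqParams:
    """Two-state linear-extrapolation parameters with per-channel baselines.

    ``baselines`` maps a channel key to ``(yN, sN, yD, sD)``: native and
    denatured intercepts and slopes in signal units and signal·M⁻¹.
    """

    dg_h2o: float
    m_value: float
    baselines: dict = field(default_factory=dict)
    stderr: dict = field(default_factory=dict)
    rss: float = float("nan")
    n_points: int = 0
    residuals: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.m_value > 0:
            raise FitError(f"m_value must be positive, got {self.m_value}")

    @property
    def d50(self) -> float:
        """Transition midpoint ΔG_H2O / m, in mol·L⁻¹ (identically dg/m)."""
        return self.dg_h2o / self.m_value


def fraction_denatured(
    dg_h2o: float,
    m_value: float,
    denaturant: float | np.ndarray,
    conditions: Conditions = Conditions(),
) -> float | np.ndarray:
    """Equilibrium denatured-state population under the linear-extrapolation model.

    Returns exp(−(ΔG − m·D)/RT) / (1 + exp(−(ΔG − m·D)/RT)); monotonically
    increasing in the denaturant concentration ``D`` and equal to one half at
    D = ΔG/m.
    """
    if not m_value > 0:
        raise ValueError("m_value must be positive")
    d = np.asarray(denaturant, dtype=float)
    out = expit(-(dg_h2o - m_value * d) / conditions.rt)
    return float(out) if np.isscalar(denaturant) else out


def _vector_autocorr(w: np.ndarray) -> float:
    """First-order autocorrelation Σ wᵢ wᵢ₊₁ of a unit-normalised vector."""
    w = w / np.linalg.norm(w)
    return float(np.dot(w[:-1], w[1:]))


def svd_decompose(series: TitrationSeries) -> SVDResult:
    """Singular value decomposition of the titration matrix.

    Autocorrelations of both the spectral (U) and denaturant-coefficient (V)
    singular vectors are attached, and ``n_significant`` counts the leading
    components passing the default 0.8 threshold on both.
    """
    m_mat = series.signal_matrix
    if m_mat.shape[0] < 2 or m_mat.shape[1] < 2:
        raise DataError("titration matrix must be at least 2 x 2")
    if np.allclose(m_mat, m_mat.flat[0]):
        logger.warning("titration matrix is constant; SVD is a degenerate rank-1 result")
    u, s, vt = np.linalg.svd(m_mat, full_matrices=False)
    v = vt.T
    ac_u = np.array([_vector_autocorr(u[:, k]) for k in range(len(s))])
    ac_v = np.array([_vector_autocorr(v[:, k]) for k in range(len(s))])
    result = SVDResult(
        basis_spectra=u,
        coefficients=v,
        singular_values=s,
        autocorrelations_u=ac_u,
        autocorrelations_v=ac_v,
        n_significant=0,
    )
    result.n_significant = count_significant_components(result)
    return result


def count_significant_components(svd_result: SVDResult, threshold: float = 0.8) -> int:
    """Number of leading SVD components whose U and V autocorrelations both
    exceed *threshold*, counted contiguously from the first component."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    count = 0
    for cu, cv in zip(svd_result.autocorrelations_u, svd_result.autocorrelations_v):
        if cu > threshold and cv > threshold:
            count += 1
        else:
            break
    return count


# ---------------------------------------------------------------------------
# Two-state global fitting (variable projection)
# ---------------------------------------------------------------------------


def _channel_design(f: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Design matrix mapping (yN, sN, yD, sD) to the observed channel signal."""
    fn = 1.0 - f
    return np.column_stack([fn, d * fn, f, d * f])


def _vp_residuals(d50: float, m_value: float, series_list, conditions):
    """Concatenated residuals with baselines solved per channel by lstsq."""
    res_blocks = []
    baselines = {}
    for series in series_list:
        d = series.denaturant_concs
        f = fraction_denatured(m_value * d50, m_value, d, conditions)
        design = _channel_design(f, d)
        for i, ch in enumerate(series.channels):
            y = series.signal_matrix[i]
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            res_blocks.append(design @ coef - y)
            baselines[(series.label, str(ch))] = tuple(coef)
    return np.concatenate(res_blocks), baselines


def _steepest_change_conc(series: TitrationSeries) -> float:
    """Concentration of steepest mean-signal change, as a midpoint guess."""
    d = series.denaturant_concs
    y = series.signal_matrix.mean(axis=0)
    slopes = np.abs(np.diff(y) / np.diff(d))
    i = int(np.argmax(slopes))
    return float(0.5 * (d[i] + d[i + 1]))


def fit_two_state_equilibrium(
    series_list: TitrationSeries | Sequence[TitrationSeries],
    conditions: Conditions = Conditions(),
    share_thermo: bool = True,
):
    """Global two-state fit of one or more titration series.

    With ``share_thermo`` (the default) a single (ΔG_H2O, m) pair is shared
    across every channel of every series while each channel keeps its own
    linear native and denatured baselines; this is the fluorescence + CD
    global fit.  With ``share_thermo=False`` each series is fit separately
    and a list of results is returned.

    Returns a :class:`TwoStateEqParams` with baselines, standard errors (from
    the Jacobian-based covariance of the full parameter set), the residual
    vector, and the RSS.
    """
    if isinstance(series_list, TitrationSeries):
        series_list = [series_list]
    series_list = list(series_list)
    if not series_list:
        raise DataError("no titration series supplied")
    if not share_thermo and len(series_list) > 1:
        return [
            fit_two_state_equilibrium(s, conditions, share_thermo=True)
            for s in series_list
        ]

    n_total = sum(s.n_points for s in series_list)
    if min(s.n_points for s in series_list) < 8:
        raise DataError("need at least 8 denaturant points per series")

    d_all = np.concatenate([s.denaturant_concs for s in series_list])
    d_lo, d_hi = float(d_all.min()), float(d_all.max())

    def resid(x):
        d50, m_val = x
        r, _ = _vp_residuals(d50, m_val, series_list, conditions)
        return r

    d50_guess = _steepest_change_conc(series_list[0])
    best = None
    for m0 in (1.0, 2.0, 4.0):
        for d0 in (d50_guess, 0.5 * (d_lo + d_hi)):
            try:
                sol = least_squares(
                    resid,
                    x0=[d0, m0],
                    bounds=([d_lo * 0.0 + 1e-6, 1e-3], [2 * d_hi + 1.0, 50.0]),
                    xtol=1e-12,
                    ftol=1e-14,
                    gtol=1e-10,
                )
            except Exception:  # pragma: no cover - defensive
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None or not best.success:
        raise FitError("two-state equilibrium fit did not converge")

    d50_fit, m_fit = best.x
    if not (d_lo < d50_fit < d_hi):
        raise FitError(
            f"transition midpoint {d50_fit:.2f} M is not bracketed by the data "
            f"range [{d_lo:.2f}, {d_hi:.2f}] M"
        )

    residuals, baselines = _vp_residuals(d50_fit, m_fit, series_list, conditions)
    dg_fit = m_fit * d50_fit

    # Full-parameter refinement for the covariance: (dg, m) + 4 per channel.
    keys = list(baselines)
    x_full0 = np.concatenate(
        [[dg_fit, m_fit]] + [np.asarray(baselines[k]) for k in keys]
    )

    total_len = sum(s.n_points * len(s.channels) for s in series_list)

    def resid_full(x):
        dg, m_val = x[0], x[1]
        if m_val <= 0:
            return np.full(total_len, 1e6)
        blocks = []
        j = 2
        for series in series_list:
            d = series.denaturant_concs
            f = fraction_denatured(dg, m_val, d, conditions)
            design = _channel_design(f, d)
            for i, _ch in enumerate(series.channels):
                coef = x[j : j + 4]
                j += 4
                blocks.append(design @ coef - series.signal_matrix[i])
        return np.concatenate(blocks)

    sol_full = least_squares(resid_full, x_full0, xtol=1e-14, ftol=1e-15, gtol=1e-12)
    dg_fit, m_fit = sol_full.x[0], sol_full.x[1]
    residuals = sol_full.fun
    rss = float(residuals @ residuals)
    stderr = _jacobian_stderr(
        sol_full.jac,
        rss,
        names=["dg_h2o", "m_value"]
        + [f"baseline[{k}]" for k in keys for _ in range(4)],
    )

    # repackage refined baselines
    j = 2
    for k in keys:
        baselines[k] = tuple(sol_full.x[j : j + 4])
        j += 4

    dg_se, m_se = stderr[0], stderr[1]
    d50_fit = dg_fit / m_fit
    d50_se = d50_fit * np.hypot(dg_se / dg_fit, m_se / m_fit)
    return TwoStateEqParams(
        dg_h2o=float(dg_fit),
        m_value=float(m_fit),
        baselines=baselines,
        stderr={"dg_h2o": dg_se, "m_value": m_se, "d50": float(d50_se)},
        rss=rss,
        n_points=len(residuals),
        residuals=residuals,
    )


def _jacobian_stderr(jac, rss, names):
    """Standard errors from the Jacobian; flags unidentifiable parameters."""
    n, p = jac.shape
    dof = max(n - p, 1)
    s2 = rss / dof
    u, s, vt = np.linalg.svd(jac, full_matrices=False)
    if s[0] <= 0 or s[-1] / s[0] < 1e-12:
        null = vt[-1]
        worst = names[int(np.argmax(np.abs(null)))]
        raise UnidentifiableError(
            f"singular Jacobian: parameter '{worst}' is not identifiable"
        )
    cov = (vt.T / s**2) @ vt * s2
    return np.sqrt(np.diag(cov))


def fit_lambda_max(
    denaturant_concs: np.ndarray,
    lambda_max_nm: np.ndarray,
    conditions: Conditions = Conditions(),
) -> TwoStateEqParams:
    """Fit the wavelength of maximum emission versus denaturant to the same
    two-state model with scalar (per-curve) linear baselines."""
    d = np.asarray(denaturant_concs, dtype=float)
    lam = np.asarray(lambda_max_nm, dtype=float)
    if np.ptp(lam) < 1e-9:
        raise FitError("lambda-max curve is flat: no unfolding transition to fit")
    series = TitrationSeries(
        denaturant_concs=d,
        channels=["lambda_max"],
        signal_matrix=lam[None, :],
        probe="lambda-max",
        label="lambda_max",
    )
    return fit_two_state_equilibrium(series, conditions)
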