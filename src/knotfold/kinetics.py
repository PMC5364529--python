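"""Stopped-flow kinetics: multi-exponential traces and chevron plots.

Observed kinetic traces are fit to a sum of one to three exponentials plus
an offset,

    y(t) = y∞ + Σᵢ Aᵢ exp(−kᵢ t),

with the number of phases chosen by the extra-sum-of-squares F test: a phase
is added only when the reduction in residual sum of squares justifies the
extra parameters at the chosen significance level.  Amplitudes and the
offset are linear parameters and are solved by least squares inside the
nonlinear search over rates (variable projection).

Observed rates as a function of final denaturant concentration (the chevron
plot) follow the two-state form

    k_obs(D) = k_f^H2O · exp(m_f·D/RT) + k_u^H2O · exp(m_u·D/RT),

with m_f < 0 (refolding arm) and m_u > 0 (unfolding arm).  The chevron fit
is performed on log10(k_obs): the rates of the four phases span six orders
of magnitude, and homoscedastic errors on the log-rate are the realistic
noise model for stopped-flow data.  The fit yields the unfolding free
energy ΔG = RT·ln(k_f/k_u), the kinetic m-value m_kin = m_u − m_f, and the
midpoint [D]50% = ΔG/m_kin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .conditions import Conditions
from .exceptions import DataError, FitError, UnidentifiableError

logger = logging.getLogger(__name__)

__all__ = [
    "KineticTrace",
    "MultiExpFit",
    "ChevronDataset",
    "ChevronFit",
    "fit_multiexponential",
    "extra_ss_f_test",
    "chevron_kobs",
    "fit_chevron",
    "delta_g_from_rates",
]

#: Default stopped-flow dead time in seconds; configurable per trace.
DEFAULT_DEAD_TIME = 2e-3


@dataclass
class KineticTrace:
    """A single stopped-flow or manual-mixing kinetic trace."""

    times: np.ndarray
    signal: np.ndarray
    final_denaturant: float = 0.0
    dead_time: float = DEFAULT_DEAD_TIME
    source: str = "stopped-flow"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape:
            raise DataError("times and signal must have the same length")
        if np.any(np.diff(self.times) <= 0):
            raise DataError("times must be strictly increasing")
        if self.dead_time < 0:
            raise DataError("dead_time must be non-negative")

    def truncated(self) -> "KineticTrace":
        """Trace restricted to t >= dead_time."""
        keep = self.times >= self.dead_time
        if keep.all():
            return self
        return KineticTrace(
            self.times[keep], self.signal[keep], self.final_denaturant,
            self.dead_time, self.source,
        )


@dataclass
class MultiExpFit:
    """Multi-exponential fit result; rates stored fastest-first (descending).

    The slowest-to-fastest phase labelling used in reports (phase 1 = slowest)
    is provided by :meth:`phase_rates`.
    """

    n_phases: int
    rates: np.ndarray
    amplitudes: np.ndarray
    offset: float
    rss: float
    n_points: int
    stderr_rates: np.ndarray | None = None
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if len(self.rates) != self.n_phases or len(self.amplitudes) != self.n_phases:
            raise DataError("n_phases must match the number of rates and amplitudes")
        if np.any(self.rates <= 0):
            raise DataError("rates must be positive")
        if np.any(np.diff(self.rates) >= 0):
            raise DataError("rates must be strictly descending")

    def phase_rates(self) -> dict:
        """Rates keyed by phase number, phase 1 = slowest (report convention)."""
        asc = np.sort(self.rates)
        return {i + 1: float(k) for i, k in enumerate(asc)}

    def predict(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        return self.offset + sum(
            a * np.exp(-k * t) for a, k in zip(self.amplitudes, self.rates)
        )


@dataclass
class ChevronDataset:
    """Observed rates for one kinetic phase across denaturant concentrations."""

    denaturant: np.ndarray
    k_obs: np.ndarray
    branch: Sequence[str]  # "refolding" | "unfolding" per point
    phase_label: int = 1
    source: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.denaturant = np.asarray(self.denaturant, dtype=float)
        self.k_obs = np.asarray(self.k_obs, dtype=float)
        if np.any(self.k_obs <= 0):
            raise DataError("all observed rates must be positive")
        if len(self.branch) != len(self.k_obs):
            raise DataError("branch labels must match the number of points")


@dataclass
class ChevronFit:
    """Two-state chevron parameters and the thermodynamics derived from them."""

    kf_h2o: float
    mf: float
    ku_h2o: float
    mu: float
    conditions: Conditions = field(default_factory=Conditions)
    stderr: dict = field(default_factory=dict)
    rss: float = float("nan")
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.kf_h2o <= 0 or self.ku_h2o <= 0:
            raise DataError("rates in water must be positive")
        if not (self.mf < 0 < self.mu):
            raise DataError("need mf < 0 < mu for a chevron")

    @property
    def dg(self) -> float:
        """Unfolding free energy RT·ln(kf/ku), kcal·mol⁻¹."""
        return delta_g_from_rates(self.kf_h2o, self.ku_h2o, self.conditions)

    @property
    def m_kin(self) -> float:
        """Kinetic m-value m_u − m_f = |m_f| + m_u, kcal·mol⁻¹·M⁻¹."""
        return self.mu - self.mf

    @property
    def d50(self) -> float:
        """Midpoint ΔG/m_kin, the concentration where both arms are equal."""
        return self.dg / self.m_kin


def extra_ss_f_test(
    rss_simple: float,
    p_simple: int,
    rss_complex: float,
    p_complex: int,
    n: int,
    alpha: float = 0.05,
):
    """Extra-sum-of-squares F test between two nested least-squares models.

    Returns ``(F, p_value, accept_complex)``.  The more complex model is
    accepted when p < alpha.  If the complex model fails to reduce the RSS,
    F is reported as 0 and the simple model is kept.
    """
    if p_complex <= p_simple:
        raise ValueError("complex model must have more parameters")
    if n <= p_complex:
        raise ValueError("need more data points than complex-model parameters")
    if rss_complex > rss_simple:
        return 0.0, 1.0, False
    df1 = p_complex - p_simple
    df2 = n - p_complex
    if rss_complex == 0:
        return float("inf"), 0.0, True
    f_stat = ((rss_simple - rss_complex) / df1) / (rss_complex / df2)
    p_value = float(stats.f.sf(f_stat, df1, df2))
    return float(f_stat), p_value, p_value < alpha


def _exp_design(t: np.ndarray, rates: np.ndarray) -> np.ndarray:
    cols = [np.exp(-k * t) for k in rates] + [np.ones_like(t)]
    return np.column_stack(cols)


def _fit_fixed_n(t, y, n_phases, n_starts=8):
    """Best n-exponential fit via variable projection over log-rates."""
    t_span = t[-1] - t[0] if t[-1] > t[0] else 1.0
    dt_min = np.min(np.diff(t))
    k_lo, k_hi = 1.0 / (5.0 * t_span), 1.0 / (2.0 * dt_min)

    def resid(log_k):
        design = _exp_design(t, np.exp(log_k))
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        return design @ coef - y

    rng_grid = np.log(np.geomspace(k_lo, k_hi, n_starts + n_phases))
    best = None
    for s in range(n_starts):
        x0 = rng_grid[s : s + n_phases]
        try:
            sol = least_squares(
                resid, x0,
                bounds=(np.log(k_lo / 10), np.log(k_hi * 2)),
                xtol=1e-13, ftol=1e-14,
            )
        except Exception:  # pragma: no cover
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("exponential fit failed for all starting points")
    rates = np.sort(np.exp(best.x))[::-1]
    design = _exp_design(t, rates)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    amps, offset = coef[:n_phases], float(coef[-1])
    r = design @ coef - y
    return rates, amps, offset, float(r @ r)


def fit_multiexponential(
    trace: KineticTrace,
    max_phases: int = 3,
    alpha: float = 0.05,
) -> MultiExpFit:
    """Fit a trace to 1–``max_phases`` exponentials plus offset.

    The number of phases is the smallest for which adding another phase is
    not justified by the extra-sum-of-squares F test at *alpha*.  Fitted
    rates closer than a factor of 1.5 are considered unresolved and the
    simpler model is kept.
    """
    trace = trace.truncated()
    t, y = trace.times, trace.signal
    n = len(t)
    if n < 10 * (2 * max_phases + 1):
        raise DataError(
            f"need at least {10 * (2 * max_phases + 1)} points for up to "
            f"{max_phases} phases, got {n}"
        )
    dt_min = np.min(np.diff(t))
    nyquist = 1.0 / (2.0 * dt_min)

    flags = []
    if np.ptp(y) < 1e-12 or np.ptp(y) < 1e-9 * max(1.0, np.abs(y).max()):
        flags.append("flat trace: single-phase fit forced, amplitude ~ 0")
        rates = np.array([1.0 / (t[-1] - t[0] + dt_min)])
        design = _exp_design(t, rates)
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        r = design @ coef - y
        return MultiExpFit(1, rates, coef[:1], float(coef[-1]), float(r @ r), n,
                           flags=flags)

    span = np.ptp(y)
    rss_floor = (1e-8 * span) ** 2 * n  # numerical noise floor
    fits = {}
    chosen = 1
    fits[1] = _fit_fixed_n(t, y, 1)
    for n_ph in range(2, max_phases + 1):
        if fits[chosen][3] < rss_floor:
            break  # already at machine precision; extra phases fit nothing
        cand = _fit_fixed_n(t, y, n_ph)
        rates_c, amps_c = cand[0], cand[1]
        ratios = rates_c[:-1] / rates_c[1:]
        if np.any(ratios < 1.5):
            flags.append(
                f"{n_ph}-phase fit rejected: rates within 1.5x are unresolved"
            )
            break
        if np.any(np.abs(amps_c) < 0.02 * span):
            flags.append(
                f"{n_ph}-phase fit rejected: a phase amplitude is below 2% "
                "of the signal span"
            )
            break
        p_simple = 2 * chosen + 1
        p_complex = 2 * n_ph + 1
        _, _, accept = extra_ss_f_test(
            fits[chosen][3], p_simple, cand[3], p_complex, n, alpha
        )
        if not accept:
            break
        fits[n_ph] = cand
        chosen = n_ph

    rates, amps, offset, rss = fits[chosen]
    if np.any(rates > nyquist):
        raise FitError(
            "fitted rate exceeds the sampling Nyquist bound; trace cannot "
            "resolve this phase"
        )
    # rate standard errors from the full nonlinear Jacobian
    stderr = _multiexp_rate_stderr(t, y, rates, amps, offset, rss)
    return MultiExpFit(chosen, rates, amps, offset, rss, n,
                       stderr_rates=stderr, flags=flags)


def _multiexp_rate_stderr(t, y, rates, amps, offset, rss):
    n_ph = len(rates)
    dof = max(len(t) - (2 * n_ph + 1), 1)
    s2 = rss / dof
    cols = []
    for a, k in zip(amps, rates):
        cols.append(np.exp(-k * t))            # d/dA
        cols.append(-a * t * np.exp(-k * t))   # d/dk
    cols.append(np.ones_like(t))
    jac = np.column_stack(cols)
    try:
        cov = np.linalg.inv(jac.T @ jac) * s2
    except np.linalg.LinAlgError:
        return None
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return se[1::2][:n_ph]


def chevron_kobs(
    fit: "ChevronFit | tuple",
    denaturant: float | np.ndarray,
    conditions: Conditions | None = None,
) -> float | np.ndarray:
    """Observed relaxation rate of the two-state chevron at concentration D."""
    if isinstance(fit, ChevronFit):
        kf, mf, ku, mu = fit.kf_h2o, fit.mf, fit.ku_h2o, fit.mu
        cond = conditions or fit.conditions
    else:
        kf, mf, ku, mu = fit
        cond = conditions or Conditions()
    d = np.asarray(denaturant, dtype=float)
    if np.any(d < 0):
        raise ValueError("denaturant must be non-negative")
    out = kf * np.exp(mf * d / cond.rt) + ku * np.exp(mu * d / cond.rt)
    return float(out) if np.isscalar(denaturant) else out


def fit_chevron(
    dataset: ChevronDataset,
    conditions: Conditions = Conditions(),
) -> ChevronFit:
    """Fit a chevron dataset in log10(k_obs) space.

    Requires points on both the refolding and the unfolding arm; a
    single-arm dataset leaves the opposite rate unidentifiable and raises
    an error naming the missing arm.
    """
    branch = np.asarray([b[:1].lower() for b in dataset.branch])
    n_ref = int(np.sum(branch == "r"))
    n_unf = int(np.sum(branch == "u"))
    if n_ref < 4:
        raise UnidentifiableError(
            "refolding arm has fewer than 4 points: kf_h2o and mf are "
            "unidentifiable"
        )
    if n_unf < 4:
        raise UnidentifiableError(
            "unfolding arm has fewer than 4 points: ku_h2o and mu are "
            "unidentifiable"
        )
    d = dataset.denaturant
    logk = np.log10(dataset.k_obs)
    rt_val = conditions.rt
    ln10 = np.log(10.0)

    # initial estimates from straight-line fits of each arm in log space
    ref = branch == "r"
    slope_f, inter_f = np.polyfit(d[ref], logk[ref], 1)
    slope_u, inter_u = np.polyfit(d[~ref], logk[~ref], 1)
    x0 = np.array([
        inter_f,                      # log10 kf_h2o
        min(slope_f * ln10 * rt_val, -1e-3),  # mf
        min(inter_u, inter_f - 1.0),  # log10 ku_h2o
        max(slope_u * ln10 * rt_val, 1e-3),   # mu
    ])

    def resid(x):
        log_kf, mf, log_ku, mu = x
        k = 10.0**log_kf * np.exp(mf * d / rt_val) + 10.0**log_ku * np.exp(
            mu * d / rt_val
        )
        return np.log10(k) - logk

    sol = least_squares(
        resid, x0,
        bounds=([-30, -20, -30, 1e-6], [30, -1e-6, 30, 20]),
        xtol=1e-15, ftol=1e-15, gtol=1e-12,
    )
    if not sol.success:
        raise FitError("chevron fit did not converge")
    log_kf, mf, log_ku, mu = sol.x
    rss = float(2 * sol.cost)
    stderr_x = _chevron_stderr(sol.jac, rss, len(d))
    kf, ku = 10.0**log_kf, 10.0**log_ku

    stderr = {}
    if stderr_x is not None:
        se_lkf, se_mf, se_lku, se_mu = stderr_x
        stderr = {
            "log10_kf_h2o": se_lkf,
            "kf_h2o": kf * ln10 * se_lkf,
            "mf": se_mf,
            "log10_ku_h2o": se_lku,
            "ku_h2o": ku * ln10 * se_lku,
            "mu": se_mu,
            "dg": rt_val * ln10 * float(np.hypot(se_lkf, se_lku)),
            "m_kin": float(np.hypot(se_mf, se_mu)),
        }
    return ChevronFit(
        kf_h2o=kf, mf=float(mf), ku_h2o=ku, mu=float(mu),
        conditions=conditions, stderr=stderr, rss=rss, n_points=len(d),
    )


def _chevron_stderr(jac, rss, n):
    dof = max(n - 4, 1)
    s2 = rss / dof
    try:
        cov = np.linalg.inv(jac.T @ jac) * s2
    except np.linalg.LinAlgError:
        return None
    return np.sqrt(np.clip(np.diag(cov), 0, None))


def delta_g_from_rates(
    kf: float, ku: float, conditions: Conditions = Conditions()
) -> float:
    """Unfolding free energy RT·ln(kf/ku) in kcal·mol⁻¹."""
    if kf <= 0 or ku <= 0:
        raise ValueError("rates must be positive")
    return conditions.rt * float(np.log(kf / ku))
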