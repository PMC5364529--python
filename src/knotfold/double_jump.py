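"""Double-jump (interrupted refolding) analysis.

A denatured protein is first diluted into refolding conditions, allowed to
age for a variable time t_age, and then jumped back into denaturant; the
amplitudes of the unfolding phases observed after the second jump report on
the populations of transient species present at the end of the aging
period.  This module provides:

* mixing-scheme arithmetic for the sequential dilutions,
* global fitting of the post-jump traces with rates shared across aging
  times (amplitudes free per trace),
* single-exponential fitting of the amplitude build-up versus t_age, with a
  statistical lag test, and
* the linear three-state scheme A ⇌ B ⇌ C: its relaxation rates are the
  non-zero eigenvalues of the rate matrix, and its microscopic rates can be
  fit to observed amplitude build-ups.

Orientation convention: A is the denatured state, C the native state; the
intermediate B is the transiently populated species that gives rise to the
fastest kinetic phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .exceptions import DataError, FitError
from .kinetics import KineticTrace, extra_ss_f_test, _exp_design

logger = logging.getLogger(__name__)

__all__ = [
    "MixingStep",
    "MixingScheme",
    "InterruptedRefoldingSeries",
    "AmplitudeBuildUp",
    "LinearThreeState",
    "final_concentration",
    "global_fit_shared_rates",
    "fit_amplitude_buildup",
    "three_state_relaxation",
    "populations",
    "fit_linear_three_state",
]


@dataclass(frozen=True)
class MixingStep:
    """One mixing event: a diluent solution mixed into the protein carrier.

    ``ratio_diluent : ratio_carrier`` are relative volumes; e.g. a 10:1
    buffer-to-protein push is ``MixingStep(diluent_denaturant=0.0,
    ratio_diluent=10, ratio_carrier=1)``.
    """

    diluent_denaturant: float
    ratio_diluent: float
    ratio_carrier: float = 1.0

    def __post_init__(self) -> None:
        if self.ratio_diluent <= 0 or self.ratio_carrier <= 0:
            raise DataError("mixing ratios must be positive")


@dataclass
class MixingScheme:
    """Ordered mixing steps applied to a protein stock solution."""

    steps: Sequence[MixingStep]
    protein_start: float  # μM
    denaturant_start: float  # M

    # Presets for the three double-jump modes used with UCH proteins.
    @classmethod
    def interrupted_refolding(cls, protein_start: float = 20.0,
                              stock_denaturant: float = 7.7,
                              jump_denaturant: float = 8.0) -> "MixingScheme":
        """Denatured stock 1:5 into refolding buffer, then 1:1 into denaturant."""
        return cls(
            steps=[
                MixingStep(0.0, 5.0, 1.0),
                MixingStep(jump_denaturant, 1.0, 1.0),
            ],
            protein_start=protein_start,
            denaturant_start=stock_denaturant,
        )

    @classmethod
    def interrupted_unfolding(cls, protein_start: float = 20.0,
                              unfold_denaturant: float = 8.0) -> "MixingScheme":
        """Native stock 1:5 into denaturant, then 1:1 back into buffer."""
        return cls(
            steps=[
                MixingStep(unfold_denaturant, 5.0, 1.0),
                MixingStep(0.0, 1.0, 1.0),
            ],
            protein_start=protein_start,
            denaturant_start=0.0,
        )

    @classmethod
    def single_jump(cls, protein_start: float = 20.0,
                    stock_denaturant: float = 8.0,
                    buffer_denaturant: float = 0.0) -> "MixingScheme":
        """Asymmetric 10:1 single-jump push (11-fold dilution)."""
        return cls(
            steps=[MixingStep(buffer_denaturant, 10.0, 1.0)],
            protein_start=protein_start,
            denaturant_start=stock_denaturant,
        )


def final_concentration(scheme: MixingScheme):
    """Volume-weighted denaturant and protein concentration after each step.

    Returns a list of ``(denaturant_M, protein_uM)`` tuples, one per step.
    """
    denat = scheme.denaturant_start
    prot = scheme.protein_start
    out = []
    for step in scheme.steps:
        total = step.ratio_diluent + step.ratio_carrier
        denat = (
            step.diluent_denaturant * step.ratio_diluent + denat * step.ratio_carrier
        ) / total
        prot = prot * step.ratio_carrier / total
        out.append((denat, prot))
    return out


@dataclass
class InterruptedRefoldingSeries:
    """Post-jump kinetic traces indexed by aging time, all at one final [urea]."""

    aging_times: np.ndarray
    traces: Sequence[KineticTrace]

    def __post_init__(self) -> None:
        self.aging_times = np.asarray(self.aging_times, dtype=float)
        if len(self.aging_times) != len(self.traces):
            raise DataError("one trace per aging time required")
        finals = np.array([tr.final_denaturant for tr in self.traces])
        if np.ptp(finals) > 1e-6:
            raise DataError("all traces must share the same final denaturant")


@dataclass
class AmplitudeBuildUp:
    """Per-phase amplitude as a function of aging time, with build-up fits."""

    aging_times: np.ndarray
    amplitudes: np.ndarray          # phase × aging time
    buildup_rates: list = field(default_factory=list)    # per phase, None if absent
    buildup_stderr: list = field(default_factory=list)
    lag_flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.aging_times = np.asarray(self.aging_times, dtype=float)
        self.amplitudes = np.atleast_2d(np.asarray(self.amplitudes, dtype=float))
        if self.amplitudes.shape[1] != len(self.aging_times):
            raise DataError("amplitude matrix must be phase x aging-time")
        if not np.all(np.isfinite(self.amplitudes)):
            raise DataError("amplitudes must be finite")


@dataclass
class LinearThreeState:
    """Microscopic rates of the linear scheme A ⇌ B ⇌ C."""

    k_ab: float
    k_ba: float
    k_bc: float
    k_cb: float
    p0: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    stderr: dict = field(default_factory=dict)
    preferred: str = "three-state"

    def __post_init__(self) -> None:
        rates = (self.k_ab, self.k_ba, self.k_bc, self.k_cb)
        if any(k < 0 for k in rates):
            raise DataError("microscopic rates must be non-negative")
        self.p0 = np.asarray(self.p0, dtype=float)
        if abs(self.p0.sum() - 1.0) > 1e-9 or np.any(self.p0 < 0):
            raise DataError("initial populations must be a probability simplex")

    @property
    def rate_matrix(self) -> np.ndarray:
        return np.array([
            [-self.k_ab, self.k_ba, 0.0],
            [self.k_ab, -(self.k_ba + self.k_bc), self.k_cb],
            [0.0, self.k_bc, -self.k_cb],
        ])


def three_state_relaxation(model: LinearThreeState):
    """Relaxation rates and amplitude weights of the linear three-state scheme.

    Returns ``(rates, weights)`` where ``rates`` are the two non-zero
    eigenvalues of the rate matrix (negated, sorted ascending) and
    ``weights[s, j]`` is the amplitude of relaxation mode j in the population
    of species s for the model's initial populations, so that

        p_s(t) = p_s(∞) + Σⱼ weights[s, j] · exp(−rates[j]·t).
    """
    if model.k_ab == model.k_ba == model.k_bc == model.k_cb == 0:
        raise DataError("at least one microscopic rate must be non-zero")
    k_mat = model.rate_matrix
    eigvals, eigvecs = np.linalg.eig(k_mat)
    order = np.argsort(-eigvals.real)  # 0 first, then increasingly negative
    eigvals, eigvecs = eigvals.real[order], eigvecs.real[:, order]
    coef = np.linalg.solve(eigvecs, model.p0)
    rates = -eigvals[1:]
    weights = eigvecs[:, 1:] * coef[1:]
    return rates, weights


def populations(model: LinearThreeState, times: np.ndarray) -> np.ndarray:
    """Analytic species populations (3 × len(times)) for the model."""
    k_mat = model.rate_matrix
    eigvals, eigvecs = np.linalg.eig(k_mat)
    coef = np.linalg.solve(eigvecs, model.p0.astype(complex))
    t = np.asarray(times, dtype=float)
    p = (eigvecs * coef) @ np.exp(np.outer(eigvals, t))
    return p.real


def global_fit_shared_rates(
    series: InterruptedRefoldingSeries,
    n_phases: int,
    n_starts: int = 6,
):
    """Global multi-exponential fit with rates shared across aging times.

    Amplitudes and offsets are free per trace (solved linearly); the shared
    rates are optimised jointly over all traces.  Returns
    ``(rates, amplitude_matrix)`` with ``amplitude_matrix[phase, trace]``.
    """
    if len(series.traces) < 3:
        raise DataError("need at least 3 aging times for a shared-rate fit")
    traces = [tr.truncated() for tr in series.traces]

    def resid(log_k):
        rates = np.exp(log_k)
        blocks = []
        for tr in traces:
            design = _exp_design(tr.times, rates)
            coef, *_ = np.linalg.lstsq(design, tr.signal, rcond=None)
            blocks.append(design @ coef - tr.signal)
        return np.concatenate(blocks)

    t_all = np.concatenate([tr.times for tr in traces])
    k_lo = 1.0 / (5.0 * np.ptp(t_all) + 1e-12)
    k_hi = 1.0 / (2.0 * min(np.min(np.diff(tr.times)) for tr in traces))
    grid = np.log(np.geomspace(k_lo, k_hi, n_starts + n_phases))
    best = None
    for s in range(n_starts):
        sol = least_squares(
            resid, grid[s : s + n_phases],
            bounds=(np.log(k_lo / 10), np.log(k_hi * 2)),
            xtol=1e-13, ftol=1e-14,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    rates = np.sort(np.exp(best.x))[::-1]
    if n_phases > 1 and np.any(rates[:-1] / rates[1:] < 1.5):
        logger.warning("shared rates collapsed within 1.5x; phases merged")
        rates = np.unique(np.round(rates, 12))[::-1]
    amp = np.empty((len(rates), len(traces)))
    for j, tr in enumerate(traces):
        design = _exp_design(tr.times, rates)
        coef, *_ = np.linalg.lstsq(design, tr.signal, rcond=None)
        amp[:, j] = coef[: len(rates)]
    return rates, amp


def _buildup_model(t, a_inf, k):
    return a_inf * (1.0 - np.exp(-k * t))


def _lag_model(t, a_inf, k1, k2):
    """Sequential two-step onset; reduces to single-exponential as k2 → ∞."""
    k1, k2 = min(k1, k2), max(k1, k2)
    if abs(k2 - k1) < 1e-12 * max(k1, k2, 1.0):
        return a_inf * (1.0 - (1.0 + k1 * t) * np.exp(-k1 * t))
    return a_inf * (
        1.0 - (k2 * np.exp(-k1 * t) - k1 * np.exp(-k2 * t)) / (k2 - k1)
    )


def fit_amplitude_buildup(
    amplitudes: np.ndarray,
    aging_times: np.ndarray,
    alpha: float = 0.05,
) -> AmplitudeBuildUp:
    """Single-exponential build-up fit per phase with a statistical lag test.

    Each row of *amplitudes* is fit to A(t_age) = A∞·(1 − exp(−k·t_age)).
    A phase is lag-flagged when a delayed-onset (sequential two-step) model
    improves the fit by the extra-sum-of-squares F test at *alpha*.
    Phases whose amplitude does not build up get a rate of ``None``.
    """
    t = np.asarray(aging_times, dtype=float)
    amps = np.atleast_2d(np.asarray(amplitudes, dtype=float))
    if len(t) < 5:
        raise DataError("need at least 5 aging times spanning the build-up")
    rates, stderrs, lags = [], [], []
    for row in amps:
        span = np.ptp(row)
        if span < 1e-12 or span < 0.02 * np.abs(row).max():
            rates.append(None)
            stderrs.append(None)
            lags.append(False)
            continue
        sign = np.sign(row[np.argmax(np.abs(row))])
        y = row * sign
        idx = int(np.argmax(y >= 0.63 * y.max()))
        t63 = t[idx] if t[idx] > 0 else t[min(idx + 1, len(t) - 1)]
        k0 = 1.0 / max(t63, 1e-12)

        def resid1(x):
            return _buildup_model(t, x[0], np.exp(x[1])) - y

        best1 = None
        for kg in (k0, 1.0 / t[len(t) // 2], 10.0 / t[-1]):
            sol = least_squares(resid1, [y.max(), np.log(max(kg, 1e-12))],
                                xtol=1e-13, ftol=1e-14)
            if best1 is None or sol.cost < best1.cost:
                best1 = sol
        rss1 = 2 * best1.cost
        a_fit, k_fit = best1.x[0], float(np.exp(best1.x[1]))

        def resid2(x):
            return _lag_model(t, x[0], np.exp(x[1]), np.exp(x[2])) - y

        best2 = None
        for mult in (3.0, 10.0, 30.0):
            sol = least_squares(
                resid2,
                [a_fit, np.log(k_fit), np.log(k_fit * mult)],
                xtol=1e-13, ftol=1e-14,
            )
            if best2 is None or sol.cost < best2.cost:
                best2 = sol
        rss2 = 2 * best2.cost
        try:
            _, _, lag = extra_ss_f_test(rss1, 2, rss2, 3, len(t), alpha)
        except ValueError:
            lag = False
        # stderr of k from 1D Jacobian
        jac = best1.jac
        dof = max(len(t) - 2, 1)
        try:
            cov = np.linalg.inv(jac.T @ jac) * (rss1 / dof)
            k_se = float(np.sqrt(max(cov[1, 1], 0.0))) * k_fit  # log→linear
        except np.linalg.LinAlgError:
            k_se = float("nan")
        rates.append(k_fit)
        stderrs.append(k_se)
        lags.append(bool(lag))
    return AmplitudeBuildUp(
        aging_times=t, amplitudes=amps,
        buildup_rates=rates, buildup_stderr=stderrs, lag_flags=lags,
    )


def fit_linear_three_state(
    buildup: AmplitudeBuildUp,
    species_for_phase: Sequence[int] = (1, 2),
    fit_scales: bool = False,
    alpha: float = 0.05,
) -> LinearThreeState:
    """Fit microscopic A ⇌ B ⇌ C rates to observed amplitude build-ups.

    ``species_for_phase`` maps each amplitude row to the species index
    (0 = A denatured, 1 = B intermediate, 2 = C native) whose population it
    reports; amplitude rows are ordered fastest phase first (matching
    :func:`global_fit_shared_rates`), so the default assigns the fastest
    phase to the intermediate and the slower phase to the native state.
    Amplitude rows are assumed to be on the population scale (normalise by
    the total amplitude change first); ``fit_scales=True`` frees one scale
    factor per row instead, at the cost of a known identifiability trade-off
    between the scales and the back-rates.

    A two-state alternative (A ⇌ C) is also fit; when the three-state scheme
    is not a statistically better description (extra-sum-of-squares F test),
    the result's ``preferred`` attribute says so.
    """
    t = buildup.aging_times
    rows = buildup.amplitudes
    if rows.shape[0] < 2:
        raise DataError("need amplitude build-ups for at least two phases")
    rows = rows[: len(species_for_phase)]
    n_rows = rows.shape[0]

    def predict(log_rates):
        model = LinearThreeState(*np.exp(log_rates))
        p = populations(model, t)
        return p[list(species_for_phase), :]

    def resid(log_rates):
        pred = predict(log_rates)
        blocks = []
        for i in range(n_rows):
            if fit_scales:
                denom = float(pred[i] @ pred[i])
                scale = float(pred[i] @ rows[i]) / denom if denom > 0 else 0.0
            else:
                scale = 1.0
            blocks.append(scale * pred[i] - rows[i])
        return np.concatenate(blocks)

    span = np.ptp(t) + t[1]
    k_mid = 1.0 / span
    best = None
    rng_starts = [
        np.log([k_mid * a, k_mid * b, k_mid * c, k_mid * d])
        for a, b, c, d in (
            (1, 0.1, 10, 1), (1, 1, 1, 1), (10, 1, 100, 10), (0.3, 0.03, 3, 0.3),
        )
    ]
    for x0 in rng_starts:
        sol = least_squares(resid, x0, bounds=(-30, 30), xtol=1e-14, ftol=1e-15)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("three-state fit failed")
    rss3 = 2 * best.cost
    n_obs = rows.size
    p3 = 4 + (n_rows if fit_scales else 0)

    # two-state alternative: single A -> C step, B never populated
    def resid2(log_k):
        model = LinearThreeState(np.exp(log_k[0]), np.exp(log_k[1]), 0.0, 0.0)
        # A <-> B with B read as "native": effectively two-state
        p = populations(model, t)
        pred = np.vstack([p[1], p[1]])[:n_rows]
        blocks = []
        for i in range(n_rows):
            denom = float(pred[i] @ pred[i])
            scale = float(pred[i] @ rows[i]) / denom if denom > 0 else 0.0
            blocks.append(scale * pred[i] - rows[i])
        return np.concatenate(blocks)

    best2 = None
    for x0 in (np.log([k_mid, k_mid / 10]), np.log([k_mid * 3, k_mid])):
        sol2 = least_squares(resid2, x0, bounds=(-30, 30), xtol=1e-13, ftol=1e-14)
        if best2 is None or sol2.cost < best2.cost:
            best2 = sol2
    rss2 = 2 * best2.cost
    p2 = 2 + (n_rows if fit_scales else 0)
    preferred = "three-state"
    try:
        _, _, accept3 = extra_ss_f_test(rss2, p2, rss3, p3, n_obs, alpha)
        if not accept3:
            preferred = "two-state"
    except ValueError:
        pass

    k_ab, k_ba, k_bc, k_cb = np.exp(best.x)
    return LinearThreeState(
        k_ab=float(k_ab), k_ba=float(k_ba), k_bc=float(k_bc), k_cb=float(k_cb),
        stderr={}, preferred=preferred,
    )
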