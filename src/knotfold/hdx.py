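"""NMR hydrogen–deuterium exchange: decay fits and protection factors.

Amide cross-peak intensities decay single-exponentially as protons exchange
for deuterons.  The observed rate k_obs is compared with the intrinsic rate
k_int that the same amide would show in an unstructured chain, predicted by
the additive nearest-neighbour log-factor model of Bai & Englander
(poly-DL-alanine reference rates, neighbour-dependent acid/base/water
corrections, Arrhenius temperature scaling).  The protection factor

    PF = k_int / k_obs

measures how strongly structure protects the amide; log10(PF) is the
conventional reporting scale (the UCH comparison spans log10 PF ≈ 3–8).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .conditions import R_KCAL
from .exceptions import DataError, FitError

logger = logging.getLogger(__name__)

__all__ = [
    "ResidueExchangeSeries",
    "IntrinsicRateContext",
    "ProtectionFactorRecord",
    "DecayFit",
    "fit_exchange_decay",
    "intrinsic_exchange_rate",
    "protection_factor",
    "compare_pf_profiles",
]

# Poly-DL-alanine reference rate constants in D2O at 293.15 K (log10 units;
# acid and base in M^-1 min^-1, water in min^-1) and activation energies in
# kcal/mol, from the same source as the bundled factor table.
_LOG_KA_REF = 1.62
_LOG_KB_REF = 10.18
_LOG_KW_REF = -1.5
_EA_ACID = 14.0
_EA_BASE = 17.0
_EA_WATER = 19.0
_T_REF = 293.15
_PKD = 15.05  # ion product of D2O near 20 degC

# Terminal-group corrections (log10): the free N-terminal amine acts on the
# second residue's amide through "right" factors; the C-terminal carboxylate
# acts on the final residue's own amide through "left" factors.
_NTERM_ACID_RIGHT = -1.32
_NTERM_BASE_RIGHT = 1.62
_CTERM_ACID_LEFT = 0.96
_CTERM_BASE_LEFT = -1.80


def _load_factor_table() -> pd.DataFrame:
    with resources.files("knotfold.data").joinpath(
        "intrinsic_exchange_factors.csv"
    ).open() as fh:
        table = pd.read_csv(fh, comment="#")
    return table.set_index("residue")


_FACTORS = _load_factor_table()


@dataclass
class ResidueExchangeSeries:
    """Cross-peak intensity of one residue versus time in D2O."""

    residue_index: int
    residue_label: str
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise DataError("times must be non-negative and strictly increasing")
        if np.any(self.intensities < 0):
            raise DataError("intensities must be non-negative")
        if len(self.times) != len(self.intensities):
            raise DataError("times and intensities must have equal length")


@dataclass(frozen=True)
class IntrinsicRateContext:
    """Sequence and solution conditions for intrinsic-rate prediction.

    ``pd_read`` is the glass-electrode reading; the conventional +0.4
    correction to true pD is applied when ``pd_correction`` is set.  The UCH
    experiments report the uncorrected buffer pH, so the default applies no
    correction (flagged here rather than silently altered).
    """

    sequence: str
    pd_read: float = 7.6
    temperature: float = 298.15
    pd_correction: float = 0.0

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - set(_FACTORS.index)
        if bad:
            raise DataError(f"unknown residue code(s): {sorted(bad)}")
        if not 0 <= self.pd <= 14:
            raise DataError("pD must be within [0, 14]")

    @property
    def pd(self) -> float:
        return self.pd_read + self.pd_correction


@dataclass
class ProtectionFactorRecord:
    """Observed and intrinsic exchange rates of one amide and their ratio."""

    residue_index: int
    k_obs_hdx: float
    k_int: float
    pf: float
    log10_pf: float
    is_lower_bound: bool = False
    anomalous: bool = False


@dataclass
class DecayFit:
    """Single-exponential intensity-decay fit I(t) = I0·exp(−k·t) (+floor)."""

    k_obs: float
    k_stderr: float
    i0: float
    floor: float
    rss: float
    below_detection: bool = False
    detection_bound: float = float("nan")


def fit_exchange_decay(
    series: ResidueExchangeSeries,
    free_floor: bool = False,
) -> DecayFit:
    """Fit one residue's intensity decay to a single exponential.

    The floor is fixed at zero by default (a fully exchanged peak vanishes).
    A series that does not decay measurably is reported as below the
    detection bound (5% decay over the observation window) rather than as a
    rate estimate.
    """
    t, i_obs = series.times, series.intensities
    if len(t) < 4:
        raise DataError("need at least 4 time points")
    t_max = t[-1] if t[-1] > 0 else 1.0
    bound = 0.05 / t_max
    i_max = i_obs.max()
    if i_max <= 0:
        raise DataError("all intensities are zero")
    decay_frac = (i_obs[0] - i_obs[-1]) / i_max
    if decay_frac < 0.02:
        return DecayFit(
            k_obs=bound, k_stderr=float("nan"), i0=float(i_obs[0]), floor=0.0,
            rss=float("nan"), below_detection=True, detection_bound=bound,
        )

    # log-linear initial estimate on the positive part
    pos = i_obs > 0.05 * i_max
    slope, inter = np.polyfit(t[pos], np.log(i_obs[pos]), 1)
    k0 = max(-slope, bound)

    def resid(x):
        i0, logk = x[0], x[1]
        floor = x[2] if free_floor else 0.0
        return i0 * np.exp(-np.exp(logk) * t) + floor - i_obs

    x0 = [np.exp(inter), np.log(k0)] + ([0.0] if free_floor else [])
    sol = least_squares(resid, x0, xtol=1e-14, ftol=1e-15)
    if not sol.success:
        raise FitError("exchange-decay fit did not converge")
    k_fit = float(np.exp(sol.x[1]))
    rss = float(2 * sol.cost)
    dof = max(len(t) - len(sol.x), 1)
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * (rss / dof)
        k_se = float(np.sqrt(max(cov[1, 1], 0.0))) * k_fit
    except np.linalg.LinAlgError:
        k_se = float("nan")
    below = k_fit < bound
    return DecayFit(
        k_obs=k_fit, k_stderr=k_se, i0=float(sol.x[0]),
        floor=float(sol.x[2]) if free_floor else 0.0,
        rss=rss, below_detection=below, detection_bound=bound,
    )


def intrinsic_exchange_rate(context: IntrinsicRateContext, residue_index: int) -> float:
    """Intrinsic (random-coil) exchange rate of the amide of *residue_index*.

    The rate combines acid-, base-, and water-catalysed terms, each scaled
    by the nearest-neighbour log-factors of the residue itself ("left") and
    its preceding neighbour ("right"), with terminal-group corrections and
    Arrhenius temperature scaling from the 293 K reference.  Returned in
    s⁻¹.  The first residue and prolines carry no exchangeable backbone
    amide in this model.
    """
    seq = context.sequence
    if residue_index < 2 or residue_index > len(seq):
        raise DataError("residue_index must be in [2, len(sequence)]")
    res = seq[residue_index - 1]
    prev = seq[residue_index - 2]
    if res == "P":
        raise DataError(f"residue {residue_index} is proline: no backbone amide")

    acid_l = _FACTORS.at[res, "acid_left"]
    base_l = _FACTORS.at[res, "base_left"]
    acid_r = _FACTORS.at[prev, "acid_right"]
    base_r = _FACTORS.at[prev, "base_right"]
    if residue_index == 2:
        acid_r += _NTERM_ACID_RIGHT
        base_r += _NTERM_BASE_RIGHT
    if residue_index == len(seq):
        acid_l += _CTERM_ACID_LEFT
        base_l += _CTERM_BASE_LEFT

    temp = context.temperature
    arr = lambda ea: np.exp(-(ea / R_KCAL) * (1.0 / temp - 1.0 / _T_REF))
    ka = 10.0**_LOG_KA_REF * arr(_EA_ACID)
    kb = 10.0**_LOG_KB_REF * arr(_EA_BASE)
    kw = 10.0**_LOG_KW_REF * arr(_EA_WATER)

    d_conc = 10.0 ** (-context.pd)
    od_conc = 10.0 ** (context.pd - _PKD)
    k_min = (
        ka * 10.0 ** (acid_l + acid_r) * d_conc
        + kb * 10.0 ** (base_l + base_r) * od_conc
        + kw * 10.0 ** (base_l + base_r)
    )
    return float(k_min / 60.0)  # min^-1 -> s^-1


def protection_factor(
    k_int: float,
    k_obs_hdx: float,
    residue_index: int = 0,
    is_lower_bound: bool = False,
) -> ProtectionFactorRecord:
    """Protection factor PF = k_int / k_obs for one amide.

    When k_obs is only a detection bound the PF is a lower bound.  PF < 1
    (exchange faster than random coil) is flagged as anomalous.
    """
    if k_int <= 0 or k_obs_hdx <= 0:
        raise DataError("both rates must be positive")
    pf = k_int / k_obs_hdx
    return ProtectionFactorRecord(
        residue_index=residue_index,
        k_obs_hdx=k_obs_hdx,
        k_int=k_int,
        pf=pf,
        log10_pf=float(np.log10(pf)),
        is_lower_bound=is_lower_bound,
        anomalous=pf < 1.0,
    )


def pf_table(records: Sequence[ProtectionFactorRecord]) -> pd.DataFrame:
    """Tabulate PF records (columns residue,k_obs,k_int,pf,log10_pf)."""
    return pd.DataFrame(
        {
            "residue": [r.residue_index for r in records],
            "k_obs": [r.k_obs_hdx for r in records],
            "k_int": [r.k_int for r in records],
            "pf": [r.pf for r in records],
            "log10_pf": [r.log10_pf for r in records],
        }
    )


def compare_pf_profiles(
    profiles: dict,
    segments: dict,
) -> pd.DataFrame:
    """Compare per-residue PF profiles across proteins by structural segment.

    ``profiles`` maps protein name to a sequence of
    :class:`ProtectionFactorRecord`; ``segments`` maps segment name to an
    inclusive ``(start, end)`` residue range shared across the proteins.
    Returns a table of median log10 PF per protein and segment, plus an
    ``overall`` column; rows are ordered from most to least protected.
    """
    if len(profiles) < 2:
        raise DataError("need at least two profiles to compare")
    if not segments:
        raise DataError("segment annotation is empty")
    rows = {}
    for name, records in profiles.items():
        by_res = {r.residue_index: r.log10_pf for r in records}
        row = {}
        for seg, (start, end) in segments.items():
            vals = [v for i, v in by_res.items() if start <= i <= end]
            row[seg] = float(np.median(vals)) if vals else float("nan")
        row["overall"] = float(np.median(list(by_res.values())))
        rows[name] = row
    out = pd.DataFrame(rows).T
    if out.drop(columns="overall").isna().all(axis=None):
        raise DataError("no profile overlaps any annotated segment")
    return out.sort_values("overall", ascending=False)
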