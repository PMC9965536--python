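"""Noncompartmental analysis and prediction-accuracy statistics.

This module holds the verification arithmetic of the pipeline: NCA
metrics (Cmax, Tmax, AUC by linear-up/log-down trapezoid, terminal
half-life), geometric summary statistics, the average absolute fold error

    AAFE = 10 ** mean(|log10(pred / obs)|)

fold-error summaries (fractions within 1.25- and 2-fold), observed vs
predicted ratio tables, Wagner-Nelson and impulse-response deconvolution,
and fed/fasted exposure ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "ConcentrationProfile",
    "PKMetrics",
    "ComparisonRow",
    "FoldErrorSummary",
    "nca",
    "geometric_stats",
    "aafe",
    "fold_error_summary",
    "ratio_table",
    "wagner_nelson",
    "numerical_deconvolution",
    "food_effect_ratio",
]


@dataclass
class ConcentrationProfile:
    """Plasma concentration-time series (h, ng/mL)."""

    times: np.ndarray
    concentrations: np.ndarray
    dose_mg: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must have equal length")
        if len(self.times) and self.times[0] < 0:
            raise ValueError("times must start at or after 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")

    def scaled(self, factor: float) -> "ConcentrationProfile":
        return ConcentrationProfile(
            self.times, self.concentrations * factor, self.dose_mg, self.label
        )


@dataclass
class PKMetrics:
    """Summary exposure metrics of one profile."""

    cmax: float  # ng/mL
    tmax: float  # h
    auc_0_t: float  # ng*h/mL
    auc_0_inf: Optional[float]  # ng*h/mL; None when kel is undefined
    t_half: Optional[float]  # h; None when the terminal slope is undefined
    kel: Optional[float] = None  # 1/h
    terminal_points: int = 0


def _auc_linear_up_log_down(t: np.ndarray, c: np.ndarray) -> float:
    auc = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if c2 < c1 and c2 > 0:
            auc += dt * (c1 - c2) / math.log(c1 / c2)
        else:
            auc += dt * 0.5 * (c1 + c2)
    return auc


def _terminal_slope(t: np.ndarray, c: np.ndarray, i_tmax: int):
    """Best-adjusted-R^2 contiguous terminal log-linear fit (>= 3 points)."""
    mask = c > 0
    best = None
    n_pts = len(t)
    for start in range(i_tmax + 1, n_pts - 2):
        idx = np.arange(start, n_pts)
        idx = idx[mask[idx]]
        if len(idx) < 3:
            continue
        x, y = t[idx], np.log(c[idx])
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0:
            continue
        resid = y - (slope * x + intercept)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0:
            continue
        r2 = 1.0 - ss_res / ss_tot
        n = len(idx)
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        if best is None or adj > best[0]:
            best = (adj, -slope, n)
    return best  # (adj_r2, kel, n) or None


def nca(profile: ConcentrationProfile) -> PKMetrics:
    """Noncompartmental metrics of a concentration-time profile.

    AUC(0-t) uses the linear-up/log-down trapezoid; the terminal rate
    constant comes from the log-linear regression over the contiguous
    tail (at least 3 declining points after Tmax) with the best adjusted
    R^2, and AUC(0-inf) = AUC(0-t) + C_last / kel.  When no valid
    terminal phase exists, ``t_half`` and ``auc_0_inf`` are None.
    """
    t, c = profile.times, profile.concentrations
    if len(t) < 3:
        raise ValueError("NCA requires at least 3 time points")
    i_tmax = int(np.argmax(c))
    cmax = float(c[i_tmax])
    tmax = float(t[i_tmax])
    auc_t = _auc_linear_up_log_down(t, c)
    fit = _terminal_slope(t, c, i_tmax)
    if fit is None:
        return PKMetrics(cmax, tmax, auc_t, None, None, None, 0)
    _, kel, n_pts = fit
    c_last = c[c > 0][-1]
    auc_inf = auc_t + float(c_last) / kel
    return PKMetrics(cmax, tmax, auc_t, auc_inf, math.log(2.0) / kel, kel, n_pts)


def geometric_stats(values: Iterable[float]) -> tuple[float, float]:
    """Geometric mean and geometric CV% of positive values.

    ``CV% = 100 * sqrt(exp(var(ln x)) - 1)`` (sample variance).
    """
    x = np.asarray(list(values), dtype=float)
    if np.any(x <= 0):
        raise ValueError("geometric statistics require positive values")
    logs = np.log(x)
    gmean = float(np.exp(logs.mean()))
    var = float(np.var(logs, ddof=1)) if len(x) > 1 else 0.0
    return gmean, 100.0 * math.sqrt(math.exp(var) - 1.0)


def aafe(pairs: Iterable[tuple[float, float]]) -> float:
    """Average absolute fold error of (predicted, observed) pairs.

    ``10 ** mean(|log10(pred/obs)|)``; always >= 1, equal to 1 iff every
    prediction matches its observation, and symmetric under swapping
    prediction and observation in any pair.
    """
    logs = []
    for pred, obs in pairs:
        if pred <= 0 or obs <= 0:
            raise ValueError("AAFE requires positive predicted and observed values")
        logs.append(abs(math.log10(pred / obs)))
    if not logs:
        raise ValueError("AAFE requires at least one pair")
    return 10.0 ** (sum(logs) / len(logs))


@dataclass
class ComparisonRow:
    """One observed/predicted comparison of a PK metric."""

    study: str
    dose_mg: float
    metric: str  # Cmax | Tmax | AUC
    observed: float
    predicted: float
    state: str = ""

    @property
    def ratio_pred_obs(self) -> float:
        return self.predicted / self.observed

    @property
    def fold_deviation(self) -> float:
        r = self.ratio_pred_obs
        return max(r, 1.0 / r)


@dataclass
class FoldErrorSummary:
    max_fold_deviation: float
    fraction_within_1_25: float
    fraction_within_2: float


def fold_error_summary(rows: Sequence[ComparisonRow]) -> FoldErrorSummary:
    """Worst fold deviation and fractions within 1.25- and 2-fold."""
    folds = np.array([row.fold_deviation for row in rows])
    if len(folds) == 0:
        raise ValueError("no comparison rows")
    return FoldErrorSummary(
        max_fold_deviation=float(folds.max()),
        fraction_within_1_25=float(np.mean(folds <= 1.25)),
        fraction_within_2=float(np.mean(folds <= 2.0)),
    )


def ratio_table(
    observed: Sequence[float],
    predicted: Sequence[float],
    labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Predicted/observed ratio table.

    Raw ratios are retained in ``ratio_pred_obs``; ``ratio_2dp`` is the
    render-time 2-decimal rounding.  Rows with a zero observation are
    flagged and carry NaN ratios (excluded from downstream summaries).
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    if labels is None:
        labels = [f"row{i}" for i in range(len(observed))]
    flagged = observed == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(flagged, np.nan, predicted / observed)
    return pd.DataFrame(
        {
            "label": list(labels),
            "observed": observed,
            "predicted": predicted,
            "ratio_pred_obs": ratios,
            "ratio_2dp": np.round(ratios, 2),
            "flagged_zero_observed": flagged,
        }
    )


def wagner_nelson(
    profile: ConcentrationProfile, kel: float, monotone: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative fraction absorbed by Wagner-Nelson mass balance.

    ``F(t) = (C(t) + kel * AUC(0-t)) / (kel * AUC(0-inf))`` with linear
    trapezoidal cumulative AUC and the log-linear terminal correction
    ``AUC(0-inf) = AUC(0-t_last) + C_last / kel``.  With ``monotone`` the
    result is projected onto non-decreasing values and clipped to [0, 1].
    """
    if not kel > 0:
        raise ValueError("kel must be positive")
    t, c = profile.times, profile.concentrations
    cum_auc = np.concatenate(
        [[0.0], np.cumsum(0.5 * (c[1:] + c[:-1]) * np.diff(t))]
    )
    auc_inf = cum_auc[-1] + c[-1] / kel
    f = (c + kel * cum_auc) / (kel * auc_inf)
    if monotone:
        f = np.clip(np.maximum.accumulate(f), 0.0, 1.0)
    return t, f


def numerical_deconvolution(
    oral_profile: ConcentrationProfile,
    unit_impulse_response: ConcentrationProfile,
    ridge: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Input-rate profile (mg/h) by regularized non-negative deconvolution.

    The unit impulse response (UIR) is the concentration profile produced
    by a unit (1 mg) instantaneous systemic input.  The absorbed input is
    represented as a non-negative staircase on the oral profile's time
    grid and recovered by non-negative least squares with a ridge penalty
    ``ridge`` on the rate amplitudes; convolving the recovered staircase
    with the UIR reproduces the oral profile up to the regularized
    residual.  Returns ``(interval_midpoints_h, rate_mg_h)``.
    """
    t = oral_profile.times
    c = oral_profile.concentrations
    t_u = unit_impulse_response.times
    c_u = unit_impulse_response.concentrations
    if t_u[0] > 0 or t_u[-1] < t[-1] - t[0]:
        raise ValueError(
            "unit impulse response must cover lags from 0 to the oral "
            "profile duration (same or finer grid)"
        )
    edges = t
    mids = 0.5 * (edges[1:] + edges[:-1])
    widths = np.diff(edges)
    n_obs, n_in = len(t), len(mids)
    m = np.zeros((n_obs, n_in))
    for j in range(n_in):
        lags = t - mids[j]
        valid = lags >= 0
        m[valid, j] = widths[j] * np.interp(lags[valid], t_u, c_u)
    scale = max(np.abs(m).max(), 1e-300)
    a = np.vstack([m, math.sqrt(ridge) * scale * np.eye(n_in)])
    b = np.concatenate([c, np.zeros(n_in)])
    rate, _ = nnls(a, b)
    return mids, rate


def food_effect_ratio(
    fed: PKMetrics, fasted: PKMetrics
) -> tuple[float, float]:
    """Fed/fasted Cmax and AUC ratios (AUC(0-inf) when available)."""
    if fasted.cmax <= 0 or fasted.auc_0_t <= 0:
        raise ValueError("fasted metrics must be positive")
    auc_fed = fed.auc_0_inf if fed.auc_0_inf is not None else fed.auc_0_t
    auc_fasted = (
        fasted.auc_0_inf if fasted.auc_0_inf is not None else fasted.auc_0_t
    )
    return fed.cmax / fasted.cmax, auc_fed / auc_fasted
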