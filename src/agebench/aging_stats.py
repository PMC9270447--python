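"""Aging diagnostics: percentile trends, accuracy-retention curves, pattern
classification and periodicity detection.

The raw output of a degradation suite is a cloud of (dT, E_rel) points.  This
module condenses it into:

* an *aging curve* — moving 25th/50th/75th percentiles of E_rel along the dT
  axis (best-case, median, worst-case trends);
* a *P_ac curve* — the per-bin probability of retaining an accurate model,
  defined as E_rel < threshold (default 2.0, strict inequality);
* a qualitative *degradation pattern* label (stable / gradual / explosive /
  variability growth) with the numeric evidence behind it;
* a *periodicity report* — Lomb–Scargle spectral analysis of the detrended
  median curve with a permutation significance test (the binned curve may be
  unevenly reported after count-floor omission, which rules out a plain FFT).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import signal, stats

from .engine import AgingResult

__all__ = [
    "AgingCurve",
    "PacCurve",
    "PatternLabel",
    "PeriodicityReport",
    "BandwidthError",
    "moving_percentiles",
    "p_accurate",
    "classify_pattern",
    "detect_periodicity",
]

PATTERN_LABELS = ("stable", "gradual", "explosive", "variability_growth")


class BandwidthError(ValueError):
    """Every moving-percentile bin fell under the count floor."""


def _dt_erel(results) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(results, AgingResult):
        return results.dT, results.e_rel
    dt, e = results
    return np.asarray(dt, dtype=float), np.asarray(e, dtype=float)


@dataclasses.dataclass
class AgingCurve:
    """Moving percentile trends of E_rel vs model age dT."""

    dt_grid: np.ndarray
    p25: np.ndarray
    p50: np.ndarray
    p75: np.ndarray
    counts: np.ndarray
    bandwidth_days: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dt": self.dt_grid, "p25": self.p25, "p50": self.p50, "p75": self.p75, "count": self.counts}
        )

    @property
    def iqr(self) -> np.ndarray:
        return self.p75 - self.p25

    @property
    def span(self) -> float:
        return float(self.dt_grid[-1] - self.dt_grid[0])


@dataclasses.dataclass
class PacCurve:
    """Probability of retaining an accurate model (E_rel < threshold) per dT bin."""

    dt_grid: np.ndarray
    p_ac: np.ndarray
    counts: np.ndarray
    threshold: float
    bin_days: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dt": self.dt_grid, "p_ac": self.p_ac, "count": self.counts})


@dataclasses.dataclass
class PatternLabel:
    """Degradation pattern with the statistics that justify it."""

    label: str
    evidence: dict

    def to_dict(self) -> dict:
        return {"label": self.label, "evidence": self.evidence}


@dataclasses.dataclass
class PeriodicityReport:
    """Dominant period of the median aging curve with permutation significance."""

    dominant_period_days: float | None
    power: float
    significance_p: float
    periodogram: list[tuple[float, float]]

    def to_dict(self) -> dict:
        return {
            "dominant_period_days": self.dominant_period_days,
            "power": self.power,
            "significance_p": self.significance_p,
            "periodogram": [[p, w] for p, w in self.periodogram],
        }


def moving_percentiles(
    results,
    quantiles: tuple[float, float, float] = (25.0, 50.0, 75.0),
    bandwidth_days: float | None = None,
    grid_step_days: float | None = None,
    min_count: int = 20,
) -> AgingCurve:
    """Moving empirical percentiles of E_rel along the dT axis.

    For each grid point g (default step = bandwidth / 2, i.e. 50% window
    overlap; bandwidth default = 5% of the dT range) the percentiles are
    taken over results with ``|dT − g| <= bandwidth / 2`` using the linear
    interpolation convention.  Bins under ``min_count`` are omitted.
    """
    dt, e_rel = _dt_erel(results)
    lo, hi = float(dt.min()), float(dt.max())
    if bandwidth_days is None:
        bandwidth_days = 0.05 * (hi - lo)
    if grid_step_days is None:
        grid_step_days = bandwidth_days / 2.0
    grid = np.arange(lo, hi + grid_step_days / 2, grid_step_days)

    keep_grid, rows = [], []
    half = bandwidth_days / 2.0
    for g in grid:
        mask = np.abs(dt - g) <= half
        n = int(mask.sum())
        if n < min_count:
            continue
        keep_grid.append(g)
        rows.append((np.percentile(e_rel[mask], quantiles), n))
    if not rows:
        raise BandwidthError(
            f"all {len(grid)} bins under the count floor {min_count}; "
            f"increase bandwidth (currently {bandwidth_days:.1f} d)"
        )
    percs = np.array([r[0] for r in rows])
    return AgingCurve(
        dt_grid=np.array(keep_grid),
        p25=percs[:, 0],
        p50=percs[:, 1],
        p75=percs[:, 2],
        counts=np.array([r[1] for r in rows], dtype=int),
        bandwidth_days=float(bandwidth_days),
    )


def p_accurate(results, threshold: float = 2.0, bin_days: float = 30.0) -> PacCurve:
    """Fraction of instances with E_rel strictly below ``threshold``, per dT bin.

    The strict inequality matters at the boundary: an instance with E_rel
    exactly at the threshold counts as *not* accurate.  Empty bins are omitted.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    dt, e_rel = _dt_erel(results)
    start = np.floor(dt.min() / bin_days) * bin_days
    edges = np.arange(start, dt.max() + bin_days, bin_days)
    idx = np.digitize(dt, edges) - 1
    grid, frac, counts = [], [], []
    for b in range(len(edges)):
        mask = idx == b
        n = int(mask.sum())
        if n == 0:
            continue
        grid.append(edges[b] + bin_days / 2.0)
        frac.append(float(np.mean(e_rel[mask] < threshold)))
        counts.append(n)
    return PacCurve(
        dt_grid=np.array(grid),
        p_ac=np.array(frac),
        counts=np.array(counts, dtype=int),
        threshold=float(threshold),
        bin_days=float(bin_days),
    )


def _quartile_median(values: np.ndarray, first: bool) -> float:
    k = max(1, len(values) // 4)
    chunk = values[:k] if first else values[-k:]
    return float(np.median(chunk))


def _changepoint(values: np.ndarray) -> int:
    """Single changepoint by binary segmentation (max between-segment SSE drop)."""
    n = len(values)
    best, best_gain = n // 2, -np.inf
    total = float(np.sum((values - values.mean()) ** 2))
    for i in range(2, n - 1):
        left, right = values[:i], values[i:]
        sse = float(np.sum((left - left.mean()) ** 2) + np.sum((right - right.mean()) ** 2))
        if total - sse > best_gain:
            best_gain, best = total - sse, i
    return best


def classify_pattern(
    curve: AgingCurve,
    explosive_ratio: float = 5.0,
    explosive_concentration: float = 3.0,
    gradual_growth: float = 1.5,
    iqr_growth: float = 2.0,
) -> PatternLabel:
    """Label the aging curve: stable / gradual / explosive / variability_growth.

    Decision rules (all thresholds configurable and reported as evidence):

    1. *explosive* — the peak median E_rel is at least ``explosive_ratio``
       times the early-bins median, and the excess is concentrated after a
       detected changepoint (post/pre mean ratio ≥ ``explosive_concentration``).
    2. *gradual* — otherwise, a positive robust (Theil–Sen) median trend with
       the late median at least ``gradual_growth`` × the early median.
    3. *variability_growth* — median criteria unmet, but the late IQR is at
       least ``iqr_growth`` × the early IQR with a positive IQR trend.
    4. *stable* — anything else.

    All comparisons are ratios or slope signs, so stretching the dT axis
    leaves the label unchanged.
    """
    if len(curve.dt_grid) < 10:
        raise ValueError(f"need >= 10 reported bins, got {len(curve.dt_grid)}")
    dt, p50, iqr = curve.dt_grid, curve.p50, curve.iqr

    slope_p50 = float(stats.theilslopes(p50, dt).slope)
    slope_iqr = float(stats.theilslopes(iqr, dt).slope)
    early_p50 = _quartile_median(p50, first=True)
    late_p50 = _quartile_median(p50, first=False)
    early_iqr = _quartile_median(iqr, first=True)
    late_iqr = _quartile_median(iqr, first=False)

    cp = _changepoint(p50)
    pre, post = p50[:cp], p50[cp:]
    concentration = float(np.mean(post) / np.mean(pre)) if np.mean(pre) > 0 else np.inf
    peak_ratio = float(np.max(p50) / early_p50) if early_p50 > 0 else np.inf

    evidence = {
        "p50_trend_slope": slope_p50,
        "iqr_trend_slope": slope_iqr,
        "early_p50": early_p50,
        "late_p50": late_p50,
        "late_early_p50_ratio": late_p50 / early_p50 if early_p50 > 0 else np.inf,
        "early_iqr": early_iqr,
        "late_iqr": late_iqr,
        "late_early_iqr_ratio": late_iqr / early_iqr if early_iqr > 0 else np.inf,
        "peak_ratio": peak_ratio,
        "changepoint_day": float(dt[cp]),
        "post_pre_mean_ratio": concentration,
        "thresholds": {
            "explosive_ratio": explosive_ratio,
            "explosive_concentration": explosive_concentration,
            "gradual_growth": gradual_growth,
            "iqr_growth": iqr_growth,
        },
    }

    if peak_ratio >= explosive_ratio and concentration >= explosive_concentration:
        label = "explosive"
    elif slope_p50 > 0 and late_p50 >= gradual_growth * early_p50:
        label = "gradual"
    elif slope_iqr > 0 and late_iqr >= iqr_growth * early_iqr:
        label = "variability_growth"
    else:
        label = "stable"
    return PatternLabel(label=label, evidence=evidence)


def detect_periodicity(
    curve: AgingCurve,
    period_range: tuple[float, float] = (30.0, 500.0),
    n_periods: int = 400,
    n_permutations: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> PeriodicityReport:
    """Dominant period of the median aging curve via Lomb–Scargle.

    A robust (Theil–Sen) linear trend is removed first so that a monotone
    drift does not masquerade as a long period.  The dominant period is the
    power maximum over the tested range (clipped, with a warning, to
    span / 1.5 if the curve is too short); significance comes from permuting
    the detrended bin values over the same dT grid.  When the permutation p
    is ≥ ``alpha`` no dominant period is reported.
    """
    dt, p50 = curve.dt_grid, curve.p50
    p_lo, p_hi = period_range
    max_allowed = curve.span / 1.5
    if p_hi > max_allowed:
        import warnings

        warnings.warn(
            f"curve span {curve.span:.0f} d supports periods up to {max_allowed:.0f} d; "
            f"clipping tested range from {p_hi:.0f}"
        )
        p_hi = max_allowed
    if p_hi <= p_lo:
        raise ValueError("curve too short for the requested period range")

    fit = stats.theilslopes(p50, dt)
    resid = p50 - (fit.intercept + fit.slope * dt)

    periods = np.linspace(p_lo, p_hi, n_periods)
    freqs = 2 * np.pi / periods

    def max_power(values: np.ndarray) -> tuple[float, int]:
        power = signal.lombscargle(dt, values - values.mean(), freqs)
        k = int(np.argmax(power))
        return float(power[k]), k

    obs_power, k = max_power(resid)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm_power, _ = max_power(rng.permutation(resid))
        if perm_power >= obs_power:
            exceed += 1
    p_value = (1 + exceed) / (1 + n_permutations)

    full_power = signal.lombscargle(dt, resid - resid.mean(), freqs)
    return PeriodicityReport(
        dominant_period_days=float(periods[k]) if p_value < alpha else None,
        power=obs_power,
        significance_p=float(p_value),
        periodogram=list(zip(periods.tolist(), full_power.tolist())),
    )
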