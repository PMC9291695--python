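"""Pause half-life estimation from single-round transcription kinetics.

Paused elongation complexes escape with pseudo-first-order kinetics, so the
fraction of signal in the paused band decays exponentially:

    f(t) = (f0 − c) · exp(−k·t) + c,        t½ = ln 2 / k

with the plateau c fixed at 0 by default (single-round assays decay to
background). Fits are unweighted nonlinear least squares with f0 free,
initialized from a log-linear regression of log f against t. Conditions
are compared as a fold change of mean half-lives with Welch's
unequal-variance t-test on the per-replicate half-lives.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

#: decay rates at or below this (1/s) are reported as "no pause detected"
MIN_RATE = 1e-9

#: minimum fractional decay over the observed time span for a pause to count
#: as detected; flat series otherwise fit an arbitrarily tiny positive rate
MIN_SPAN_DECAY = 0.01


@dataclass
class FractionSeries:
    condition: str
    replicate: int
    times_s: np.ndarray
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if not (np.diff(self.times_s) > 0).all():
            raise ValueError("times must be strictly increasing")
        if ((self.fractions < 0) | (self.fractions > 1)).any():
            raise ValueError("fractions must lie in [0, 1]")


@dataclass
class HalfLifeFit:
    condition: str
    replicate: int
    k: float
    half_life_s: float
    f0: float
    plateau_c: float
    sse: float
    n_points: int
    converged: bool

    @property
    def pause_detected(self) -> bool:
        return self.converged and self.k > MIN_RATE


@dataclass
class FoldChangeResult:
    mean_ratio: float
    welch_t: float
    welch_df: float
    p_value: float
    significant: bool


class SeriesRejected(ValueError):
    """A kinetics series has too few usable time points."""


def paused_fraction(table: pd.DataFrame, min_points: int = 4) -> list[FractionSeries]:
    """Convert band intensities to paused fractions per (condition, replicate).

    fraction(t) = paused / (paused + escaped). Time points where both
    signals are zero are dropped with a warning; a series with fewer than
    ``min_points`` usable time points is rejected.
    """
    series: list[FractionSeries] = []
    for (cond, rep), grp in table.groupby(["condition", "replicate"], sort=True):
        grp = grp.sort_values("time_s")
        total = grp["paused_signal"].to_numpy(float) + grp["escaped_signal"].to_numpy(float)
        keep = total > 0
        if (~keep).any():
            logger.warning(
                "series (%s, %s): dropping %d zero-signal time points",
                cond, rep, int((~keep).sum()),
            )
        if keep.sum() < min_points:
            raise SeriesRejected(
                f"series ({cond}, {rep}): {int(keep.sum())} usable time points, "
                f">={min_points} required"
            )
        frac = grp["paused_signal"].to_numpy(float)[keep] / total[keep]
        series.append(FractionSeries(str(cond), int(rep), grp["time_s"].to_numpy(float)[keep], frac))
    return series


def _loglinear_init(t: np.ndarray, f: np.ndarray) -> tuple[float, float]:
    """Initial (f0, k) from a log-linear regression on positive fractions."""
    pos = f > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(f[pos]), 1)
        k0 = max(-slope, 1e-4)
        f0 = min(max(math.exp(intercept), 1e-6), 1.0)
    else:
        k0, f0 = 1e-2, max(float(f.max()), 1e-6)
    return f0, k0


def fit_half_life(series: FractionSeries, with_plateau: bool = False) -> HalfLifeFit:
    """Least-squares exponential-decay fit of one paused-fraction series.

    A fitted rate of ~0 or a failure to converge is reported as a
    non-detected pause (``pause_detected`` False), not an exception —
    flat series genuinely carry no pause signal.
    """
    t, f = series.times_s, series.fractions
    if len(t) < 4:
        raise SeriesRejected("need at least 4 time points")
    if not (f > 0).any():
        raise SeriesRejected("all fractions are zero")
    f0_init, k_init = _loglinear_init(t, f)

    def no_pause(converged: bool) -> HalfLifeFit:
        return HalfLifeFit(series.condition, series.replicate, 0.0, math.inf,
                           float(f.max()), 0.0, float(np.sum((f - f.mean()) ** 2)),
                           len(t), converged)

    try:
        if with_plateau:
            def model(tt, f0, k, c):
                return (f0 - c) * np.exp(-k * tt) + c
            p0 = [f0_init, k_init, 0.0]
            bounds = ([0.0, 0.0, 0.0], [1.5, np.inf, 1.0])
        else:
            def model(tt, f0, k):
                return f0 * np.exp(-k * tt)
            p0 = [f0_init, k_init]
            bounds = ([0.0, 0.0], [1.5, np.inf])
        popt, _ = optimize.curve_fit(model, t, f, p0=p0, bounds=bounds, maxfev=10000)
    except (RuntimeError, optimize.OptimizeWarning):
        return no_pause(False)

    f0, k = float(popt[0]), float(popt[1])
    c = float(popt[2]) if with_plateau else 0.0
    if k <= MIN_RATE or k * (t[-1] - t[0]) < MIN_SPAN_DECAY:
        return no_pause(True)
    sse = float(np.sum((model(t, *popt) - f) ** 2))
    return HalfLifeFit(series.condition, series.replicate, k, math.log(2) / k,
                       f0, c, sse, len(t), True)


def welch_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance t statistic, Welch–Satterthwaite df, two-sided p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
    denom = va + vb
    if denom == 0:
        return 0.0, float(na + nb - 2), 1.0
    tstat = (a.mean() - b.mean()) / math.sqrt(denom)
    df = denom**2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(tstat), df)
    return float(tstat), float(df), float(p)


def welch_fold_change(
    fits_condition: list[HalfLifeFit],
    fits_reference: list[HalfLifeFit],
    alpha: float = 0.05,
) -> FoldChangeResult:
    """Fold change of mean half-lives (condition/reference) with Welch's test."""
    cond = np.array([f.half_life_s for f in fits_condition if f.pause_detected])
    ref = np.array([f.half_life_s for f in fits_reference if f.pause_detected])
    if len(cond) < 2 or len(ref) < 2:
        raise ValueError("need at least 2 converged fits per group")
    ratio = float(cond.mean() / ref.mean())
    tstat, df, p = welch_t_test(cond, ref)
    return FoldChangeResult(ratio, tstat, df, p, p < alpha)


def fit_report(fits: list[HalfLifeFit]) -> pd.DataFrame:
    """One row per fit, for report writing."""
    return pd.DataFrame(
        [
            {
                "condition": f.condition,
                "replicate": f.replicate,
                "k_per_s": f.k,
                "half_life_s": f.half_life_s,
                "f0": f.f0,
                "plateau_c": f.plateau_c,
                "sse": f.sse,
                "n_points": f.n_points,
                "pause_detected": f.pause_detected,
            }
            for f in fits
        ]
    )
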