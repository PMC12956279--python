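"""RT-DNA half-life estimation with dilution correction.

After induction is washed out, per-cell RT-DNA fold change (from
comparative-CT qPCR) declines through two channels: growth-driven dilution
(each division halves the per-volume amount, tracked by the OD600 ratio)
and first-order degradation at rate k.  The model is

    C(t) = 1 + A * exp(-k*t) * OD600(t_ref) / OD600(t)

with the +1 floor being the plasmid contribution to the fold change (an
uninduced culture sits at fold 1).  OD600(t) is itself a logistic fit to
the growth curve,

    OD600(t) = OD_max / (1 + exp(-r*(t - t0))),

fitted first and then substituted — the two fits are sequential, not
joint.  The half-life is ln(2)/k; a fitted k below 1e-6 /min is reported
as the infinity sentinel ("beyond the detection limit"), the regime where
dilution alone explains the data.  Refits with k fixed at preset
half-lives (e.g. 15 and 30 min) give residual sums for model comparison.

Note on t_ref: the OD ratio's reference time is the first sampling time of
the decay series, a distinct quantity from the logistic midpoint t0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "K_DETECTION_LIMIT",
    "GrowthCurve",
    "LogisticFit",
    "DecaySeries",
    "DecayFit",
    "logistic_od",
    "fit_logistic",
    "decay_curve",
    "fit_decay",
    "fixed_k_refit",
    "half_life",
]

#: Degradation rates below this (per minute) are indistinguishable from zero
#: over a feasible assay window and map to an infinite half-life.
K_DETECTION_LIMIT = 1e-6


def _as_series(times, values, vname: str) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape or t.ndim != 1:
        raise ValueError(f"times and {vname} must be equal-length 1-D arrays")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(v <= 0):
        raise ValueError(f"{vname} must be > 0")
    return t, v


@dataclass(frozen=True)
class GrowthCurve:
    times: tuple[float, ...]  # minutes
    od: tuple[float, ...]

    def __post_init__(self) -> None:
        _as_series(self.times, self.od, "od")


@dataclass(frozen=True)
class LogisticFit:
    od_max: float
    r: float  # per minute
    t0: float  # minutes, growth midpoint
    rss: float = 0.0

    def __post_init__(self) -> None:
        if self.od_max <= 0 or self.r <= 0:
            raise ValueError("od_max and r must be > 0")


@dataclass(frozen=True)
class DecaySeries:
    times: tuple[float, ...]  # minutes
    fold_change: tuple[float, ...]

    def __post_init__(self) -> None:
        _as_series(self.times, self.fold_change, "fold_change")


@dataclass(frozen=True)
class DecayFit:
    a: float
    k: float  # per minute
    half_life: float  # minutes; math.inf when k below detection limit
    rss: float
    k_fixed: bool = False


def logistic_od(t, fit: LogisticFit):
    """Logistic growth: OD_max / (1 + exp(-r*(t - t0)))."""
    t = np.asarray(t, dtype=float)
    out = fit.od_max / (1.0 + np.exp(-fit.r * (t - fit.t0)))
    return float(out) if out.ndim == 0 else out


def fit_logistic(curve: GrowthCurve) -> LogisticFit:
    """Least-squares logistic fit of an OD600 growth curve.

    Initial values: OD_max at the maximum reading, t0 at the time the curve
    first crosses half its maximum, r from the central slope.  A curve with
    no net growth (final OD not above the initial OD) is degenerate.
    """
    t, od = _as_series(curve.times, curve.od, "od")
    if t.size < 4:
        raise ValueError("need at least 4 growth points")
    if od[-1] <= od[0] or od.max() <= od.min() * 1.001:
        raise ValueError("degenerate growth curve: no net increase in OD")

    od_max0 = float(od.max())
    half_idx = int(np.argmax(od >= od_max0 / 2))
    t00 = float(t[half_idx])
    span = max(float(t[-1] - t[0]), 1.0)
    r0 = 4.0 / span  # logistic rises over ~4/r minutes

    def resid(x):
        om, r, t0 = x
        return om / (1.0 + np.exp(-r * (t - t0))) - od

    sol = least_squares(
        resid,
        x0=[od_max0, r0, t00],
        bounds=([1e-9, 1e-9, t[0] - 10 * span], [np.inf, np.inf, t[-1] + 10 * span]),
    )
    om, r, t0 = sol.x
    return LogisticFit(od_max=float(om), r=float(r), t0=float(t0), rss=float(2 * sol.cost))


def decay_curve(t, a: float, k: float, logistic: LogisticFit, t_ref: float):
    """Dilution-corrected decay: C(t) = 1 + A·exp(-k·t)·OD(t_ref)/OD(t)."""
    t = np.asarray(t, dtype=float)
    dilution = logistic_od(t_ref, logistic) / logistic_od(t, logistic)
    out = 1.0 + a * np.exp(-k * t) * dilution
    return float(out) if out.ndim == 0 else out


def _decay_rss(series_t, series_c, a, k, logistic, t_ref) -> float:
    pred = decay_curve(series_t, a, k, logistic, t_ref)
    return float(np.sum((pred - series_c) ** 2))


def fit_decay(
    series: DecaySeries,
    logistic: LogisticFit,
    k_max: float = 1.0,
) -> DecayFit:
    """Fit amplitude A and degradation rate k to a fold-change time series.

    k is bounded to [0, k_max] per minute (no negative degradation).  The
    reference time of the dilution ratio is the first sampling time.  A
    fitted k below the detection limit maps to an infinite half-life:
    dilution alone explains the decline.
    """
    t, c = _as_series(series.times, series.fold_change, "fold_change")
    if t.size < 3:
        raise ValueError("need at least 3 decay points")
    t_ref = float(t[0])

    a0 = max(float(c[0] - 1.0), 1e-6)

    def resid(x):
        a, k = x
        return decay_curve(t, a, k, logistic, t_ref) - c

    best = None
    # Two starts: pure dilution and a fast-decay start; the surface is
    # smooth in (A, k) so these cover both regimes.
    for k0 in (0.0, min(0.1, k_max)):
        sol = least_squares(resid, x0=[a0, k0], bounds=([0.0, 0.0], [np.inf, k_max]))
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
    a, k = best.x
    return DecayFit(
        a=float(a), k=float(k), half_life=half_life(float(k)), rss=float(2 * best.cost)
    )


def fixed_k_refit(
    series: DecaySeries, logistic: LogisticFit, half_life_min: float
) -> DecayFit:
    """Refit with k fixed at ln(2)/half_life; only the amplitude A is free.

    With k fixed the model is linear in A, so A has the closed-form
    least-squares solution A = Σ g·(C−1) / Σ g² with g(t) the fixed decay ×
    dilution kernel.  ``half_life_min=inf`` requests the k = 0 constrained
    fit.  The reported rss supports comparison against the free fit.
    """
    if half_life_min <= 0:
        raise ValueError("half_life must be > 0")
    k = 0.0 if math.isinf(half_life_min) else math.log(2.0) / half_life_min
    t, c = _as_series(series.times, series.fold_change, "fold_change")
    if t.size < 3:
        raise ValueError("need at least 3 decay points")
    t_ref = float(t[0])
    g = np.exp(-k * t) * (logistic_od(t_ref, logistic) / logistic_od(t, logistic))
    a = max(float(np.dot(g, c - 1.0) / np.dot(g, g)), 0.0)
    return DecayFit(
        a=a,
        k=k,
        half_life=half_life(k) if k > 0 else math.inf,
        rss=_decay_rss(t, c, a, k, logistic, t_ref),
        k_fixed=True,
    )


def half_life(k: float) -> float:
    """ln(2)/k in minutes; infinite below the detection limit."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if k < K_DETECTION_LIMIT:
        return math.inf
    return math.log(2.0) / k
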