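"""Global fitting of fluorogen titrations with the quadratic tight-binding isotherm.

Fluorogenic aptamer affinities here are comparable to the reagent
concentrations used in the titration, so ligand depletion matters and the
hyperbolic (Michaelis-type) isotherm is biased.  The exact single-site
solution for the fluorescence at total DNA concentration At and total
fluorogen concentration Bt is

    F(At) = C1 * [ (At + Bt + Kd) - sqrt((At + Bt + Kd)^2 - 4*At*Bt) ] / (2*Bt) + C0

where C0 and C1 are the lower plateau and amplitude.  Several titration
series (aptamer variants) share C0, C1 and Bt globally; each series gets
its own Kd.  Bt is nominally known (the fluorogen stock concentration) but
carries stock-concentration uncertainty, so it is fitted inside a tight
relative constraint box around its nominal value.

Fits use bounded nonlinear least squares with multi-start over Kd (the
isotherm is weakly identifiable when Kd >> max(At)); confidence intervals
come from a residual-resampling bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "IsothermParams",
    "TitrationSeries",
    "BindingFitResult",
    "isotherm",
    "fit_global",
    "bootstrap_ci",
]


@dataclass(frozen=True)
class IsothermParams:
    """Parameters of the quadratic binding isotherm (concentrations in µM)."""

    c0: float  # lower fluorescence plateau
    c1: float  # fluorescence amplitude (upper plateau = c0 + c1)
    bt: float  # total fluorogen concentration, µM
    kd: float  # dissociation constant, µM

    def __post_init__(self) -> None:
        if self.c1 < 0:
            raise ValueError("c1 must be >= 0")
        if self.bt <= 0:
            raise ValueError("bt must be > 0")
        if self.kd < 0:
            raise ValueError("kd must be >= 0")


@dataclass(frozen=True)
class TitrationSeries:
    """One construct's fluorescence-vs-DNA-concentration titration."""

    construct: str
    bt_nominal: float  # µM
    at: tuple[float, ...]  # µM DNA
    fluorescence: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.at) != len(self.fluorescence):
            raise ValueError("at and fluorescence must have equal length")
        if any(a < 0 for a in self.at):
            raise ValueError("DNA concentrations must be >= 0")
        if self.bt_nominal <= 0:
            raise ValueError("bt_nominal must be > 0")


@dataclass
class BindingFitResult:
    c0: float
    c1: float
    bt: float
    kd: dict[str, float]
    kd_ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    shared_ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    residual_sum: float = 0.0
    n_points: int = 0
    degenerate: bool = False  # flat series: Kd unidentifiable


def isotherm(at, p: IsothermParams):
    """Evaluate the quadratic tight-binding isotherm at DNA concentration(s) ``at``.

    The radicand is clamped at zero to absorb floating-point negatives at
    the saturation boundary (Kd = 0, At = Bt).
    """
    at = np.asarray(at, dtype=float)
    if np.any(at < 0):
        raise ValueError("At must be >= 0")
    s = at + p.bt + p.kd
    radicand = np.clip(s * s - 4.0 * at * p.bt, 0.0, None)
    bound_frac = (s - np.sqrt(radicand)) / (2.0 * p.bt)
    out = p.c1 * bound_frac + p.c0
    return float(out) if out.ndim == 0 else out


def _pack_residuals(params, series_list):
    c0, c1, bt = params[0], params[1], params[2]
    res = []
    for idx, s in enumerate(series_list):
        p = IsothermParams(c0=c0, c1=max(c1, 0.0), bt=bt, kd=max(params[3 + idx], 0.0))
        res.append(isotherm(np.asarray(s.at), p) - np.asarray(s.fluorescence))
    return np.concatenate(res)


def _fit_once(series_list, x0, lo, hi):
    return least_squares(
        _pack_residuals, x0, args=(series_list,), bounds=(lo, hi), method="trf"
    )


def fit_global(
    series: Sequence[TitrationSeries],
    bt_box: float = 0.2,
    seed: int | None = 0,
    n_starts: int = 8,
) -> BindingFitResult:
    """Globally fit shared (C0, C1, Bt) and per-series Kd by bounded least squares.

    Bt is constrained to ``bt_nominal * (1 ± bt_box)``.  Eight multi-starts
    initialize Kd log-uniformly in [0.01, 100] µM (seeded, reproducible),
    C0 at the minimum observed fluorescence and C1 at the observed span;
    the start with the lowest residual sum wins, ties going to the earliest
    start.

    Series whose fluorescence span is (numerically) zero are flagged
    ``degenerate``: C1 collapses toward 0 and Kd is unidentifiable.
    """
    series = list(series)
    if not series:
        raise ValueError("need at least one titration series")
    for s in series:
        if len(s.at) < 4:
            raise ValueError(f"series {s.construct!r} has fewer than 4 points")
    bt_nom = series[0].bt_nominal
    if any(abs(s.bt_nominal - bt_nom) > 1e-9 for s in series):
        raise ValueError("bt_nominal must be consistent across series")
    n_params = 3 + len(series)
    n_points = sum(len(s.at) for s in series)
    if n_points < n_params:
        raise ValueError(f"{n_points} points cannot constrain {n_params} parameters")

    f_all = np.concatenate([np.asarray(s.fluorescence, dtype=float) for s in series])
    f_min, f_span = float(f_all.min()), float(f_all.max() - f_all.min())
    degenerate = f_span <= 1e-12 * max(1.0, abs(f_min))

    lo = np.array([-np.inf, 0.0, bt_nom * (1 - bt_box)] + [0.0] * len(series))
    hi = np.array([np.inf, np.inf, bt_nom * (1 + bt_box)] + [np.inf] * len(series))

    rng = np.random.default_rng(seed)
    kd_starts = 10.0 ** rng.uniform(-2, 2, size=(n_starts, len(series)))
    best = None
    for start in range(n_starts):
        x0 = np.concatenate([[f_min, max(f_span, 1e-6), bt_nom], kd_starts[start]])
        x0 = np.clip(x0, lo + 1e-12, np.where(np.isfinite(hi), hi - 1e-12, x0))
        try:
            sol = _fit_once(series, x0, lo, hi)
        except Exception:
            continue
        if best is None or sol.cost < best.cost - 1e-12:
            best = sol
    if best is None:
        raise RuntimeError("global isotherm fit failed from every start")

    x = best.x
    return BindingFitResult(
        c0=float(x[0]),
        c1=float(x[1]),
        bt=float(x[2]),
        kd={s.construct: float(x[3 + i]) for i, s in enumerate(series)},
        residual_sum=float(2 * best.cost),
        n_points=n_points,
        degenerate=degenerate,
    )


def bootstrap_ci(
    fit: BindingFitResult,
    series: Sequence[TitrationSeries],
    n_boot: int = 1000,
    seed: int | None = 0,
    bt_box: float = 0.2,
) -> BindingFitResult:
    """Percentile 95% CIs for Kd and the shared parameters by residual resampling.

    Fitted values replace observations, residuals are resampled with
    replacement within each bootstrap replicate, and the model is refitted
    warm-started from the point estimate.  Reproducible under ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for stable percentile intervals")
    series = list(series)
    rng = np.random.default_rng(seed)
    x_hat = np.array([fit.c0, fit.c1, fit.bt] + [fit.kd[s.construct] for s in series])
    fitted = [
        isotherm(np.asarray(s.at), IsothermParams(fit.c0, fit.c1, fit.bt, fit.kd[s.construct]))
        for s in series
    ]
    residuals = np.concatenate(
        [f - np.asarray(s.fluorescence) for f, s in zip(fitted, series)]
    )
    bt_nom = series[0].bt_nominal
    lo = np.array([-np.inf, 0.0, bt_nom * (1 - bt_box)] + [0.0] * len(series))
    hi = np.array([np.inf, np.inf, bt_nom * (1 + bt_box)] + [np.inf] * len(series))
    x0 = np.clip(x_hat, lo + 1e-12, np.where(np.isfinite(hi), hi - 1e-12, x_hat))

    draws = np.empty((n_boot, len(x_hat)))
    n_ok = 0
    splits = np.cumsum([len(s.at) for s in series])[:-1]
    for b in range(n_boot):
        eps = rng.choice(residuals, size=residuals.size, replace=True)
        pseudo = []
        for f, e in zip(fitted, np.split(eps, splits)):
            pseudo.append(f - e)
        boot_series = [
            TitrationSeries(s.construct, s.bt_nominal, s.at, tuple(p))
            for s, p in zip(series, pseudo)
        ]
        try:
            sol = _fit_once(boot_series, x0, lo, hi)
        except Exception:
            continue
        draws[n_ok] = sol.x
        n_ok += 1
    if n_ok < n_boot // 2:
        raise RuntimeError("bootstrap refits failed in more than half the replicates")
    draws = draws[:n_ok]

    def ci(col: int) -> tuple[float, float]:
        lo_q, hi_q = np.percentile(draws[:, col], [2.5, 97.5])
        return float(lo_q), float(hi_q)

    fit.shared_ci = {"c0": ci(0), "c1": ci(1), "bt": ci(2)}
    fit.kd_ci = {s.construct: ci(3 + i) for i, s in enumerate(series)}
    return fit
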