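"""Exponential RNA decay fitting and half-life estimation.

Two nested models are supported for transcript abundance after
transcription shut-off:

* one-phase decay            N(t) = N0 * exp(-k t)
* plateau-then-one-phase     N(t) = N0            for t <= t0
                             N(t) = N0 * exp(-k (t - t0))  afterwards

``half_life = ln 2 / k`` in both.  Fits are unweighted least squares on
the natural scale (the convention of the usual curve-fitting packages for
such time courses); a log-scale option is available for strongly
multiplicative noise.  Model choice uses the small-sample-corrected Akaike
criterion (AICc), ties going to the simpler model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

LN2 = math.log(2.0)


@dataclass
class DecayFit:
    model: str                 # "one_phase" | "plateau_one_phase"
    n0: float
    k: float                   # 1/min
    t0: float                  # plateau end (min); 0 for one_phase
    half_life: float           # min, = ln2 / k
    rss: float
    aicc: float
    n_points: int
    converged: bool

    @property
    def n_params(self) -> int:
        return 2 if self.model == "one_phase" else 3


def _series_arrays(series: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(series["time_min"], dtype=float)
    v = np.asarray(series["value"], dtype=float)
    if np.any(t < 0):
        raise ValueError("timepoints must be >= 0")
    if np.any(v <= 0):
        raise ValueError("abundances must be positive")
    return t, v


def _aicc(rss: float, n: int, n_params: int) -> float:
    """AICc with the Gaussian log-likelihood (variance counted as a parameter)."""
    k = n_params + 1
    if rss <= 0:
        rss = 1e-300
    aic = n * math.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


def _one_phase(t, n0, k):
    return n0 * np.exp(-k * t)


def _plateau_one_phase(t, n0, k, t0):
    return np.where(t <= t0, n0, n0 * np.exp(-k * (t - t0)))


def fit_one_phase(series: pd.DataFrame, log_scale: bool = False) -> DecayFit:
    """Fit N(t) = N0 exp(-k t) by least squares.

    Requires >= 3 timepoints.  ``log_scale`` minimizes residuals of
    log N instead (robust to multiplicative noise).  A fit that runs into
    the k > 0 bound (effectively constant data) is flagged unconverged.
    """
    t, v = _series_arrays(series)
    if len(np.unique(t)) < 3:
        raise ValueError("need at least 3 distinct timepoints")
    # log-linear init: ln v = ln n0 - k t
    slope, intercept = np.polyfit(t, np.log(v), 1)
    k0 = max(-slope, 1e-6)
    n00 = math.exp(intercept)

    def resid(p):
        pred = _one_phase(t, p[0], p[1])
        if log_scale:
            return np.log(np.maximum(pred, 1e-300)) - np.log(v)
        return pred - v

    sol = optimize.least_squares(resid, [n00, k0],
                                 bounds=([1e-12, 1e-9], [np.inf, np.inf]),
                                 ftol=1e-12, xtol=1e-12)
    n0, k = sol.x
    rss = float(np.sum((_one_phase(t, n0, k) - v) ** 2))
    # flag fits with no measurable decline over the observed window
    converged = bool(sol.status > 0) and k * t.max() > 1e-3
    return DecayFit("one_phase", float(n0), float(k), 0.0, LN2 / k, rss,
                    _aicc(rss, len(t), 2), len(t), converged)


def fit_plateau_one_phase(series: pd.DataFrame,
                          log_scale: bool = False) -> DecayFit:
    """Fit the plateau-then-one-phase model.

    Requires >= 4 timepoints.  Because the objective is only piecewise
    smooth in t0, the plateau end is first scanned over a grid spanning
    the observed time range and the best grid point then refined jointly
    with (N0, k) by bounded least squares.
    """
    t, v = _series_arrays(series)
    if len(np.unique(t)) < 4:
        raise ValueError("need at least 4 distinct timepoints")
    t_max = float(t.max())

    def resid(p):
        pred = _plateau_one_phase(t, p[0], p[1], p[2])
        if log_scale:
            return np.log(np.maximum(pred, 1e-300)) - np.log(v)
        return pred - v

    base = fit_one_phase(series, log_scale=log_scale)
    grid = np.unique(np.concatenate([np.unique(t)[:-1],
                                     np.linspace(0.0, 0.8 * t_max, 9)]))
    best = None
    for t0g in grid:
        sol = optimize.least_squares(
            resid, [base.n0, max(base.k, 1e-6), t0g],
            bounds=([1e-12, 1e-9, 0.0], [np.inf, np.inf, t_max]),
            ftol=1e-12, xtol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol
    n0, k, t0 = best.x
    rss = float(np.sum((_plateau_one_phase(t, n0, k, t0) - v) ** 2))
    converged = bool(best.status > 0)
    if k * max(t_max - t0, 0.0) < 1e-3:
        converged = False  # decay phase unobserved: unidentifiable
    t_pos = t[t > 0]
    if len(t_pos) and 1e-9 < t0 < t_pos.min():
        # only the t=0 sample lies on the claimed plateau: its end is not
        # resolved by the sampling and the model degenerates to one-phase
        converged = False
    return DecayFit("plateau_one_phase", float(n0), float(k), float(t0),
                    LN2 / k, rss, _aicc(rss, len(t), 3), len(t), converged)


def select_model(fit_one: DecayFit, fit_plateau: DecayFit) -> DecayFit:
    """Pick the better of the two fits on the same data by AICc.

    Ties (and any unconverged plateau fit) fall back to the simpler
    one-phase model.  The AICc margin is available from the two fits.
    """
    if fit_one.n_points != fit_plateau.n_points:
        raise ValueError("fits must be on the same data")
    if not fit_plateau.converged:
        return fit_one
    if not fit_one.converged:
        return fit_plateau
    return fit_plateau if fit_plateau.aicc < fit_one.aicc else fit_one


def fit_auto(series: pd.DataFrame, log_scale: bool = False) -> DecayFit:
    """Fit both models and return the AICc-preferred one."""
    f1 = fit_one_phase(series, log_scale=log_scale)
    f2 = fit_plateau_one_phase(series, log_scale=log_scale)
    return select_model(f1, f2)
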