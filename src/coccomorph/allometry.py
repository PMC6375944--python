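"""Allometric scaling fits for coccolith morphometrics.

Three relations link the mass ``m`` (pg), peripheral grid perimeter ``p``
(µm) and segment count ``n`` of Noëlaerhabdaceae coccoliths:

    m = k_p · p^β          (mass vs grid perimeter)
    p = w · n              (perimeter vs segment count, through the origin)
    m = k_n · n^β          (mass vs segment count, with k_n = k_p · w^β)

Power laws are fitted by ordinary least squares of ln y on ln x — the
multiplicative scatter of the data makes the log scale the natural one —
with 95% confidence half-widths from the t distribution (delta method for
the prefactor) and R² reported on the log scale.  A linear-space
nonlinear fit is available as an alternative mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .exceptions import FitError

__all__ = [
    "PowerLawFit",
    "LinearFit",
    "fit_power_law",
    "fit_power_law_fixed_exponent",
    "fit_through_origin",
    "consistency_kn",
    "predict_mass",
]


@dataclass
class PowerLawFit:
    """y = prefactor · x^exponent with 95% CI half-widths and log-scale R²."""

    prefactor: float
    exponent: float
    ci95_prefactor: float
    ci95_exponent: float
    r2: float
    n_points: int

    def predict(self, x: float | np.ndarray) -> float | np.ndarray:
        return self.prefactor * np.asarray(x, dtype=float) ** self.exponent


@dataclass
class LinearFit:
    """p = slope · n through the origin, with 95% CI half-width and R²."""

    slope: float
    ci95_slope: float
    r2: float
    n_points: int


def _check_positive_pairs(x: np.ndarray, y: np.ndarray, n_min: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise FitError("x and y must be paired")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise FitError("x and y must be finite")
    if np.any(x <= 0) or np.any(y <= 0):
        raise FitError("power-law fits require strictly positive values")
    if x.size < n_min:
        raise FitError(f"need at least {n_min} points")
    return x, y


def fit_power_law(x, y, *, log_space: bool = True) -> PowerLawFit:
    """Fit y = k · x^β.

    The default (and recommended) mode is OLS of ln y on ln x: the exponent
    is the slope, the prefactor is exp(intercept), the 95% CIs come from
    the t distribution (delta method for the prefactor) and R² is computed
    on the log scale.  ``log_space=False`` refines (k, β) by nonlinear
    least squares in linear space, keeping log-scale CIs.
    """
    x, y = _check_positive_pairs(x, y, 3)
    lx, ly = np.log(x), np.log(y)
    res = stats.linregress(lx, ly)
    beta, c = res.slope, res.intercept
    n = x.size
    tval = stats.t.ppf(0.975, n - 2)
    k = math.exp(c)
    r2 = res.rvalue ** 2

    if not log_space:
        popt, _ = optimize.curve_fit(
            lambda xx, kk, bb: kk * xx ** bb, x, y, p0=[k, beta], maxfev=10000
        )
        k, beta = float(popt[0]), float(popt[1])

    return PowerLawFit(
        prefactor=k,
        exponent=float(beta),
        ci95_prefactor=k * tval * res.intercept_stderr,
        ci95_exponent=tval * res.stderr,
        r2=float(min(max(r2, 0.0), 1.0)),
        n_points=n,
    )


def fit_power_law_fixed_exponent(x, y, exponent: float) -> PowerLawFit:
    """Fit y = k · x^β with β held fixed.

    k = exp(mean(ln y − β ln x)); the CI of the prefactor follows from the
    t distribution of the log residuals (delta method).  R² is computed on
    the log scale against the fixed-exponent prediction and clipped to
    [0, 1].  A single pair is accepted (closed form, infinite CI).
    """
    x, y = _check_positive_pairs(x, y, 1)
    n = x.size
    r = np.log(y) - exponent * np.log(x)
    c = float(np.mean(r))
    k = math.exp(c)
    if n > 1:
        se = float(np.std(r, ddof=1)) / math.sqrt(n)
        tval = stats.t.ppf(0.975, n - 1)
        ci_k = k * tval * se
    else:
        ci_k = math.inf
    ly = np.log(y)
    ss_res = float(np.sum((ly - (c + exponent * np.log(x))) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(
        prefactor=k,
        exponent=float(exponent),
        ci95_prefactor=ci_k,
        ci95_exponent=0.0,
        r2=float(min(max(r2, 0.0), 1.0)),
        n_points=n,
    )


def fit_through_origin(n_values, p_values) -> LinearFit:
    """Least-squares fit of p = w · n through the origin.

    slope = Σ(n·p)/Σ(n²); the CI half-width comes from the residual
    variance (a single pair is accepted and yields an infinite CI).
    """
    n_arr, p_arr = _check_positive_pairs(n_values, p_values, 1)
    sn2 = float(np.sum(n_arr ** 2))
    slope = float(np.sum(n_arr * p_arr)) / sn2
    npts = n_arr.size
    resid = p_arr - slope * n_arr
    if npts > 1:
        s2 = float(np.sum(resid ** 2)) / (npts - 1)
        tval = stats.t.ppf(0.975, npts - 1)
        ci = tval * math.sqrt(s2 / sn2)
    else:
        ci = math.inf
    ss_tot = float(np.sum((p_arr - p_arr.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return LinearFit(slope=slope, ci95_slope=ci, r2=float(min(max(r2, 0.0), 1.0)), n_points=npts)


def consistency_kn(k_p: float, w: float, beta: float) -> float:
    """Mass-vs-segment-count prefactor implied by m = k_p p^β and p = w n.

    k_n = k_p · w^β, with w in µm and the result in pg.
    """
    if k_p <= 0 or w <= 0 or beta <= 0:
        raise FitError("k_p, w and beta must be positive")
    return k_p * w ** beta


def predict_mass(p_or_n: float, fit: PowerLawFit) -> float:
    """Mass (pg) predicted for a perimeter (µm) or segment count."""
    if p_or_n <= 0:
        raise FitError("predictor must be positive")
    return float(fit.prefactor * p_or_n ** fit.exponent)
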