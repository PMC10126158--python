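"""Growth-curve quantification with the modified logistic model.

The model for a colony's normalized log-density N(t) is

    N(t) = A / (1 + exp((4 mu_m / A) (lam - t) + 2))

where ``A`` is the asymptotic density, ``mu_m`` the maximum growth rate
(slope of the steepest tangent, per hour), and ``lam`` the lag time (hours):
the tangent at the inflection point crosses N = 0 at t = lam.  The module
provides the forward model, its closed-form inverse (used as a fitting-free
time-to-threshold oracle), nonlinear least-squares fitting, and the
derivative-based summary rates.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import expit

from .types import DomainError, FitConvergenceError, GrowthCurve, LogisticFit

__all__ = [
    "logistic_model",
    "invert_logistic_for_threshold",
    "fit_logistic",
    "time_to_threshold",
    "manual_growth_rate",
    "instantaneous_growth_rate",
    "smooth",
]


def logistic_model(t, A: float, mu_m: float, lam: float):
    """Evaluate the modified logistic growth model at time(s) ``t`` (hours).

    Vectorized over ``t``.  Raises :class:`DomainError` for non-positive ``A``.
    """
    if A <= 0:
        raise DomainError(f"asymptote A must be positive, got {A}")
    t = np.asarray(t, dtype=float)
    x = (4.0 * mu_m / A) * (lam - t) + 2.0
    out = A * expit(-x)  # A / (1 + e^x), overflow-safe
    return float(out) if out.ndim == 0 else out


def invert_logistic_for_threshold(A: float, mu_m: float, lam: float, threshold: float) -> float:
    """Closed-form time at which the model crosses ``threshold``.

    t* = lam + (A / (4 mu_m)) * (2 - ln(A/threshold - 1)).
    Requires 0 < threshold < A; above A the curve never arrives.
    """
    if A <= 0:
        raise DomainError(f"asymptote A must be positive, got {A}")
    if not (0 < threshold < A):
        raise DomainError(
            f"threshold must lie in (0, A): threshold={threshold}, A={A}"
        )
    return lam + (A / (4.0 * mu_m)) * (2.0 - np.log(A / threshold - 1.0))


def smooth(values: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average with edge truncation (default 3 points)."""
    values = np.asarray(values, dtype=float)
    if window <= 1 or len(values) < window:
        return values.copy()
    kernel = np.ones(window) / window
    out = np.convolve(values, kernel, mode="same")
    # fix edges: renormalize by the actual number of contributing points
    norm = np.convolve(np.ones_like(values), kernel, mode="same")
    return out / norm


def _initial_guess(times: np.ndarray, values: np.ndarray):
    """Data-driven start: A from the max, mu from the max discrete slope,
    lam from where that tangent line crosses zero."""
    a0 = max(float(values.max()), 1e-6)
    ys = smooth(values)
    slopes = np.diff(ys) / np.diff(times)
    i = int(np.argmax(slopes))
    mu0 = max(float(slopes[i]), 1e-3)
    t_mid = 0.5 * (times[i] + times[i + 1])
    y_mid = 0.5 * (ys[i] + ys[i + 1])
    lam0 = max(t_mid - y_mid / mu0, 0.0)
    return a0, mu0, lam0


def fit_logistic(curve: GrowthCurve | None = None, *, times=None, values=None,
                 max_iter: int = 1000) -> LogisticFit:
    """Nonlinear least-squares fit of the modified logistic model.

    Accepts either a :class:`GrowthCurve` or raw ``times``/``values`` arrays.
    Bounds: A > 0, mu_m > 0, lam >= 0.  Degenerate inputs (constant or
    all-zero curves) raise :class:`FitConvergenceError`; a failed optimizer
    is reported with ``converged=False`` rather than silently dropped.
    """
    if curve is not None:
        times, values = curve.times, curve.values
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if np.any(times < 0):
        raise ValueError("negative times are not valid for growth curves")
    if len(times) < 8:
        raise FitConvergenceError("need at least 8 points to fit the logistic model")
    if np.ptp(values) < 1e-12:
        raise FitConvergenceError("constant curve: logistic parameters unidentifiable")

    p0 = _initial_guess(times, values)
    bounds = ([1e-12, 1e-12, 0.0], [np.inf, np.inf, np.inf])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                logistic_model, times, values, p0=p0, bounds=bounds,
                method="trf", xtol=1e-10, ftol=1e-10, gtol=1e-10,
                max_nfev=max_iter * 4,
            )
        converged = True
    except RuntimeError:
        popt, converged = p0, False
    a, mu, lam = (float(v) for v in popt)
    resid = values - logistic_model(times, a, mu, lam)
    rss = float(np.dot(resid, resid))
    return LogisticFit(A=a, mu_m=mu, lam=lam, rss=rss, converged=converged)


def time_to_threshold(curve: GrowthCurve | None = None, threshold: float = 0.8,
                      mode: str = "nearest_sample", *, times=None, values=None) -> float:
    """Time (hours) at which a curve first reaches ``threshold``.

    ``mode="nearest_sample"`` returns the sampled time closest to the first
    crossing (the field convention of reading the closest scan frame);
    ``mode="interpolate"`` linearly interpolates between the bracketing
    samples.  A curve that never reaches the threshold returns ``nan`` —
    that is a QC outcome, not an exception.
    """
    if curve is not None:
        times, values = curve.times, curve.values
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if threshold <= 0:
        raise DomainError("threshold must be positive")
    if mode not in ("nearest_sample", "interpolate"):
        raise ValueError(f"unknown mode {mode!r}")

    above = values >= threshold
    if not above.any():
        return float("nan")
    i = int(np.argmax(above))  # first index at/above threshold
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    v0, v1 = values[i - 1], values[i]
    if v1 == v0:
        t_cross = t1
    else:
        t_cross = t0 + (threshold - v0) * (t1 - t0) / (v1 - v0)
    if mode == "interpolate":
        return float(t_cross)
    return float(t0 if abs(t_cross - t0) < abs(t1 - t_cross) else t1)


def manual_growth_rate(curve: GrowthCurve | None = None, *, times=None, values=None,
                       half_window: int = 2) -> float:
    """Tangent-line growth rate at the steepest point of the smoothed curve.

    Finds the index i of the maximum smoothed discrete derivative and
    returns the secant slope across the samples ``half_window`` steps above
    and below i (a 1-h window at 15-min sampling).  Near the curve ends the
    window is truncated symmetrically (with a warning).  A curve with no
    rising region raises ``ValueError``.
    """
    if curve is not None:
        times, values = curve.times, curve.values
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) < 5:
        raise ValueError("need at least 5 points for the tangent-line rate")
    ys = smooth(values)
    deriv = np.gradient(ys, times)
    i = 1 + int(np.argmax(deriv[1:-1]))  # steepest interior point
    if deriv[i] <= 0:
        raise ValueError("no exponential region: curve is non-increasing")
    k = min(half_window, i, len(times) - 1 - i)
    if k < half_window:
        warnings.warn(
            "steepest point within %d samples of the curve edge; "
            "tangent window truncated to +/-%d" % (half_window, max(k, 1)),
            stacklevel=2,
        )
    k = max(k, 1)
    # secant on the raw values; smoothing is only used to locate the peak
    return float((values[i + k] - values[i - k]) / (times[i + k] - times[i - k]))


def instantaneous_growth_rate(curve: GrowthCurve | None = None, *, times=None,
                              values=None, log_base: float = np.e) -> np.ndarray:
    """Per-interval instantaneous rate: log(x(t)/x(t-dt)) / dt.

    Natural log by default (rate convention); the base is configurable.
    Returns one fewer element than the input.  Intervals whose ratio is
    undefined (zero or negative density) are returned as NaN.
    """
    if curve is not None:
        times, values = curve.times, curve.values
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    dt = np.diff(times)
    out = np.full(len(values) - 1, np.nan)
    ok = (values[:-1] > 0) & (values[1:] > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out[ok] = np.log(values[1:][ok] / values[:-1][ok]) / dt[ok]
    if log_base != np.e:
        out = out / np.log(log_base)
    return out
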