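"""FRAP trace normalization, single-exponential recovery fitting, and the
mobile-fraction-versus-AICAP regression.

The recovery model is FRAP(t) = A * (1 - exp(-t / tau)) + y0 with t measured
from the first post-bleach frame: A is the mobile-fraction amplitude, tau the
time constant and y0 the first post-bleach intensity. Half-recovery time
t_half = tau * ln 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .core import FRAPTrace

__all__ = ["FRAPFit", "normalize_trace", "fit_frap", "mobility_regression", "recovery_model"]


def recovery_model(t, A, tau, y0):
    return A * (1.0 - np.exp(-t / tau)) + y0


@dataclass
class FRAPFit:
    A: float  # mobile-fraction amplitude (proportion)
    tau: float  # time constant, s
    y0: float  # first post-bleach intensity (proportion)
    t_half: float  # tau * ln 2, s
    rms: float  # residual root-mean-square
    wide_tau: bool = False  # flat trace: tau unidentifiable


def normalize_trace(raw: FRAPTrace) -> FRAPTrace:
    """Double normalization: background-subtract, divide by the unbleached
    control, then scale so the pre-bleach mean is 1."""
    bleached = raw.bleached - raw.background
    control = raw.control - raw.background
    if np.any(control <= 0):
        raise ValueError("non-positive control intensity after background subtraction")
    ratio = bleached / control
    pre = ratio[: raw.n_prebleach].mean()
    if pre <= 0:
        raise ValueError("non-positive pre-bleach intensity")
    return FRAPTrace(
        raw.times,
        raw.bleached,
        raw.control,
        raw.background,
        raw.n_prebleach,
        normalized=ratio / pre,
    )


def fit_frap(trace: FRAPTrace) -> FRAPFit:
    """Nonlinear least squares of the recovery model on post-bleach points.

    Initialization: A0 = last - first, tau0 = first time the trace exceeds
    y0 + A0/2 (fallback span/3), y0_0 = first post-bleach value. Bounds:
    A in [0, 2], tau in (0, 10*span], y0 in [0, 1.5].
    """
    if trace.normalized is None:
        raise ValueError("trace must be normalized first (normalize_trace)")
    y = np.asarray(trace.normalized[trace.n_prebleach:], dtype=float)
    t = trace.post_times
    if y.size < 5:
        raise ValueError("need at least 5 post-bleach points")
    span = t[-1] - t[0]
    y0_0 = float(np.clip(y[0], 0, 1.5))
    a0 = float(np.clip(y[-1] - y[0], 1e-6, 2))
    above = np.nonzero(y > y0_0 + a0 / 2)[0]
    tau0 = float(t[above[0]]) if above.size and t[above[0]] > 0 else span / 3
    tau0 = float(np.clip(tau0, 1e-6, 10 * span))
    try:
        popt, _ = optimize.curve_fit(
            recovery_model,
            t,
            y,
            p0=(a0, tau0, y0_0),
            bounds=([0, 1e-9, 0], [2, 10 * span, 1.5]),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"FRAP fit did not converge (init A={a0:.3g}, tau={tau0:.3g}, "
            f"y0={y0_0:.3g}; {y.size} points)"
        ) from err
    A, tau, y0 = (float(v) for v in popt)
    resid = y - recovery_model(t, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    # flat trace: amplitude ~0 makes tau unidentifiable
    wide_tau = bool(A < 1e-3 or tau > 5 * span)
    if A < 1e-3:
        A = 0.0
    return FRAPFit(A, tau, y0, tau * np.log(2), rms, wide_tau)


def mobility_regression(amplitudes, aicaps):
    """OLS of mobile fraction A on AICAP: slope, intercept, Pearson r, p.

    Two-sided p-value for the slope; requires >= 3 paired proteins and a
    non-constant predictor.
    """
    a = np.asarray(amplitudes, dtype=float)
    x = np.asarray(aicaps, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(x)
    if ok.sum() < 3:
        raise ValueError("need at least 3 proteins with both values")
    if np.ptp(x[ok]) == 0:
        raise ValueError("constant AICAP predictor")
    if np.ptp(a[ok]) == 0:  # flat response: slope 0, no correlation
        return {"slope": 0.0, "intercept": float(a[ok][0]), "r": 0.0,
                "p_value": 1.0, "n": int(ok.sum())}
    res = stats.linregress(x[ok], a[ok])
    return {
        "slope": res.slope,
        "intercept": res.intercept,
        "r": res.rvalue,
        "p_value": res.pvalue,
        "n": int(ok.sum()),
    }
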