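"""Exact-propagation integrator for the linear one-compartment ODE.

Both the dispersion operator (y' = (x - y)/tau) and the one-tissue
compartment model (C' = K1*Cp - k2*C) are first-order linear ODEs driven by
a sampled input. On a uniform grid with the input taken piecewise-linear,
the update

    y[i+1] = e^(-a*dt) * y[i] + b * integral_0^dt e^(-a*(dt-s)) * x(s) ds

has a closed form, which makes the propagation exact for piecewise-linear
inputs (second-order accurate for smooth ones) and unconditionally stable.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter


def linear_ode_response(x: np.ndarray, dt: float, a: float, b: float) -> np.ndarray:
    """Solve y' = b*x(t) - a*y, y(0)=b-weighted zero state, on a uniform grid.

    Parameters
    ----------
    x : input samples on a uniform grid of spacing ``dt`` (same time unit
        as ``a`` and ``b`` rates).
    dt : grid spacing.
    a : decay rate (>= 0).
    b : input gain.

    Returns
    -------
    y sampled on the same grid, with y[0] = 0.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("input must be 1-D")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if a < 0:
        raise ValueError("decay rate must be non-negative")
    if x.size < 2:
        return np.zeros_like(x)

    x0 = x[:-1]
    m = (x[1:] - x[:-1]) / dt  # slope on each interval
    if a == 0:
        # y[i+1] = y[i] + b * trapezoid increment
        incr = b * dt * (x[:-1] + x[1:]) / 2.0
        return np.concatenate([[0.0], np.cumsum(incr)])

    rate_dt = a * dt
    decay = np.exp(-rate_dt)
    # closed-form integral of e^(-a(dt-s)) (x0 + m s) ds over [0, dt];
    # expm1 and a small-rate series avoid catastrophic cancellation as
    # a*dt -> 0 (the limit must approach the trapezoid rule smoothly)
    c0 = -np.expm1(-rate_dt) / a
    if rate_dt < 1e-4:
        c1 = dt * dt * (0.5 - rate_dt / 6.0 + rate_dt * rate_dt / 24.0)
    else:
        c1 = (dt - c0) / a
    forcing = b * (x0 * c0 + m * c1)
    # recursion y[i+1] = decay*y[i] + forcing[i], y[0] = 0
    y_tail = lfilter([1.0], [1.0, -decay], forcing)
    return np.concatenate([[0.0], y_tail])


def disperse(x: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """Convolve ``x`` with the dispersion kernel (1/tau) e^(-t/tau).

    tau <= 0 disables dispersion (identity).
    """
    if tau <= 0:
        return np.asarray(x, dtype=float).copy()
    return linear_ode_response(x, dt, a=1.0 / tau, b=1.0 / tau)


def tissue_response(cp: np.ndarray, dt_s: float, k1_per_min: float, k2_per_min: float) -> np.ndarray:
    """One-tissue-compartment tissue curve C(t) = K1 * int Cp e^(-k2(t-s)) ds.

    ``cp`` is sampled at ``dt_s`` seconds; K1 and k2 are in 1/min and are
    converted internally.
    """
    if k1_per_min < 0 or k2_per_min < 0:
        raise ValueError("rate constants must be non-negative")
    return linear_ode_response(cp, dt_s, a=k2_per_min / 60.0, b=k1_per_min / 60.0)
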