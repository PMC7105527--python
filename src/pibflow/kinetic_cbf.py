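"""Voxelwise K1/CBF estimation under the one-tissue compartment model.

The production estimator is the three-weighted-integral method: with
weights w1 = 1, w2 = t, w3 = t^2 over the 0-180 s fit window, the frame-sum
integrals I_j = sum_f w_j(t_f) C_f dt_f of the tissue curve are linear in
K1, so the ratio I2/I1 depends on k2 alone. k2 is recovered by inverting a
precomputed monotone lookup of that ratio over a log-spaced k2 grid; K1
then follows from I1 against the unit-K1 basis integral, and I3 serves as a
consistency check. A nonlinear least-squares fit of the same model is
provided as an independent reference estimator.

K1 converts to cerebral blood flow through the fixed first-pass extraction
fraction E = 0.65: K1 [1/min] = E x CBF [mL/min/100 g] / 100, assuming unit
tissue density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import least_squares

from pibflow._ode import tissue_response
from pibflow.input_function import InputFunction
from pibflow.io_core import DynamicImage, FrameSchedule, ParametricMap

DEFAULT_EXTRACTION = 0.65
DEFAULT_FIT_WINDOW_S = (0.0, 180.0)

WeightFn = Callable[[np.ndarray], np.ndarray]


def _default_weights() -> tuple[WeightFn, WeightFn, WeightFn]:
    return (lambda t: np.ones_like(t), lambda t: t, lambda t: t**2)


@dataclass
class KineticConfig:
    """Settings of the weighted-integral K1 estimator."""

    extraction_fraction: float = DEFAULT_EXTRACTION
    fit_window_s: tuple[float, float] = DEFAULT_FIT_WINDOW_S
    k2_grid_per_min: np.ndarray = field(
        default_factory=lambda: np.geomspace(1e-3, 1.0, 200)
    )
    weights: tuple[WeightFn, WeightFn, WeightFn] = field(default_factory=_default_weights)
    dense_dt_s: float = 0.25

    def __post_init__(self) -> None:
        if not (0 < self.extraction_fraction <= 1):
            raise ValueError("extraction fraction must be in (0, 1]")
        grid = np.asarray(self.k2_grid_per_min, dtype=float)
        if grid.ndim != 1 or grid.size < 3 or np.any(np.diff(grid) <= 0):
            raise ValueError("k2 grid must be monotone increasing with >= 3 points")
        self.k2_grid_per_min = grid
        if len(self.weights) != 3:
            raise ValueError("exactly three weight functions are required")


def model_tac(
    k1: float,
    k2: float,
    cp: InputFunction,
    schedule: FrameSchedule,
    fit_window_s: tuple[float, float] = DEFAULT_FIT_WINDOW_S,
    dense_dt_s: float = 0.25,
) -> np.ndarray:
    """Frame-averaged 1TCM tissue curve on the fit window.

    C(t) = K1 int_0^t Cp(s) e^(-k2 (t-s)) ds, averaged over each frame that
    ends within the window. K1 and k2 in 1/min; returns kBq/mL per frame.
    """
    if k1 < 0 or k2 < 0:
        raise ValueError("rate constants must be non-negative")
    frames = _frames_in_window(schedule, fit_window_s)
    t_dense = np.arange(0.0, fit_window_s[1] + dense_dt_s / 2, dense_dt_s)
    cp_dense = cp.sample_plasma(t_dense)
    dense = tissue_response(cp_dense, dense_dt_s, k1, k2)
    return _frame_means(t_dense, dense, schedule, frames)


def _frames_in_window(schedule: FrameSchedule, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    sel = np.flatnonzero((schedule.starts >= lo - 1e-9) & (schedule.ends <= hi + 1e-9))
    if sel.size == 0:
        raise ValueError(f"no frames inside fit window [{lo}, {hi}] s")
    return sel


def _frame_means(
    t_dense: np.ndarray, curve: np.ndarray, schedule: FrameSchedule, frames: np.ndarray
) -> np.ndarray:
    from scipy.integrate import cumulative_trapezoid

    cum = np.concatenate([[0.0], cumulative_trapezoid(curve, t_dense)])
    lo = np.interp(schedule.starts[frames], t_dense, cum)
    hi = np.interp(schedule.ends[frames], t_dense, cum)
    return (hi - lo) / schedule.durations[frames]


class WeightedIntegralFitter:
    """Precomputed weighted-integral machinery for one input function.

    Building the fitter computes, for every k2 on the grid, the unit-K1
    basis TAC and its three weighted integrals; the I2/I1 ratio is checked
    to be strictly monotone in k2 and inverted with a monotone (PCHIP)
    interpolant. Fitting a voxel is then two dot products and two
    interpolant evaluations, so whole-brain fits are vectorized.
    """

    def __init__(self, cp: InputFunction, schedule: FrameSchedule, cfg: KineticConfig | None = None):
        self.cfg = cfg or KineticConfig()
        self.schedule = schedule
        self.frames = _frames_in_window(schedule, self.cfg.fit_window_s)
        t_f = schedule.mid_times[self.frames]
        dt_f = schedule.durations[self.frames]
        self.weight_vectors = np.stack(
            [w(t_f) * dt_f for w in self.cfg.weights]
        )  # (3, n_frames)

        dt = self.cfg.dense_dt_s
        t_dense = np.arange(0.0, self.cfg.fit_window_s[1] + dt / 2, dt)
        cp_dense = cp.sample_plasma(t_dense)

        grid = self.cfg.k2_grid_per_min
        basis = np.empty((grid.size, self.frames.size))
        for i, k2 in enumerate(grid):
            dense = tissue_response(cp_dense, dt, 1.0, k2)
            basis[i] = _frame_means(t_dense, dense, schedule, self.frames)
        self.basis_integrals = basis @ self.weight_vectors.T  # (n_k2, 3)

        ratio = self.basis_integrals[:, 1] / self.basis_integrals[:, 0]
        d = np.diff(ratio)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise RuntimeError("I2/I1 ratio is not strictly monotone in k2")
        if d[0] < 0:  # store ascending for PCHIP
            self._ratio_sorted = ratio[::-1]
            self._k2_sorted = grid[::-1]
        else:
            self._ratio_sorted = ratio
            self._k2_sorted = grid
        self._k2_of_ratio = PchipInterpolator(self._ratio_sorted, self._k2_sorted)
        self._b1_of_k2 = PchipInterpolator(grid, self.basis_integrals[:, 0])
        self._b3_of_k2 = PchipInterpolator(grid, self.basis_integrals[:, 2])

    def fit(self, tacs: np.ndarray) -> dict[str, np.ndarray]:
        """Fit (k1, k2) for each row of ``tacs`` (n_voxels x n_fit_frames).

        Returns arrays ``k1``, ``k2`` (1/min), ``flags`` (True where the
        ratio fell outside the lookup or k1 was floored at 0), and
        ``consistency`` (relative I3 deviation; NaN for zero voxels).
        """
        tacs = np.atleast_2d(np.asarray(tacs, dtype=float))
        integrals = tacs @ self.weight_vectors.T  # (n, 3)
        i1, i2, i3 = integrals.T
        n = tacs.shape[0]
        k1 = np.zeros(n)
        k2 = np.full(n, np.nan)
        flags = np.zeros(n, dtype=bool)
        consistency = np.full(n, np.nan)

        active = i1 > 0
        if np.any(active):
            ratio = i2[active] / i1[active]
            lo, hi = self._ratio_sorted[0], self._ratio_sorted[-1]
            clamped = (ratio < lo) | (ratio > hi)
            ratio = np.clip(ratio, lo, hi)
            k2_act = self._k2_of_ratio(ratio)
            b1 = self._b1_of_k2(k2_act)
            k1_act = i1[active] / b1
            neg = k1_act < 0
            k1_act[neg] = 0.0
            k1[active] = k1_act
            k2[active] = k2_act
            flags[active] = clamped | neg
            b3 = self._b3_of_k2(k2_act)
            with np.errstate(invalid="ignore", divide="ignore"):
                consistency[active] = np.abs(i3[active] - k1_act * b3) / np.abs(i3[active])
        return {"k1": k1, "k2": k2, "flags": flags, "consistency": consistency}


def fit_weighted_integral(
    tac: np.ndarray,
    cp: InputFunction,
    schedule: FrameSchedule,
    cfg: KineticConfig | None = None,
) -> tuple[float, float]:
    """Weighted-integral (k1, k2) estimate for a single tissue TAC.

    ``tac`` holds the frame values of the fit window (or the full schedule,
    from which the window frames are taken).
    """
    fitter = WeightedIntegralFitter(cp, schedule, cfg)
    tac = np.asarray(tac, dtype=float)
    if tac.size == schedule.n_frames:
        tac = tac[fitter.frames]
    if tac.size != fitter.frames.size:
        raise ValueError(
            f"TAC has {tac.size} frames; expected {fitter.frames.size} (fit window) "
            f"or {schedule.n_frames} (full schedule)"
        )
    res = fitter.fit(tac[None, :])
    return float(res["k1"][0]), float(res["k2"][0])


def fit_nlls(
    tac: np.ndarray,
    cp: InputFunction,
    schedule: FrameSchedule,
    init: tuple[float, float] = (0.3, 0.1),
    cfg: KineticConfig | None = None,
) -> tuple[float, float]:
    """Nonlinear least-squares (k1, k2): reference estimator for validation."""
    cfg = cfg or KineticConfig()
    frames = _frames_in_window(schedule, cfg.fit_window_s)
    tac = np.asarray(tac, dtype=float)
    if tac.size == schedule.n_frames:
        tac = tac[frames]

    dt = cfg.dense_dt_s
    t_dense = np.arange(0.0, cfg.fit_window_s[1] + dt / 2, dt)
    cp_dense = cp.sample_plasma(t_dense)

    def residuals(params):
        k1, k2 = params
        dense = tissue_response(cp_dense, dt, k1, k2)
        return _frame_means(t_dense, dense, schedule, frames) - tac

    sol = least_squares(residuals, x0=init, bounds=([0.0, 0.0], [5.0, 5.0]), xtol=1e-12, ftol=1e-12)
    if not sol.success:
        raise RuntimeError(f"NLLS fit did not converge: {sol.message}")
    return float(sol.x[0]), float(sol.x[1])


def k1_to_cbf(k1_map: ParametricMap, extraction_fraction: float = DEFAULT_EXTRACTION) -> ParametricMap:
    """CBF = 100 x K1 / E (mL/min/100 g from K1 in 1/min)."""
    if not (0 < extraction_fraction <= 1):
        raise ValueError("extraction fraction must be in (0, 1]")
    return ParametricMap(100.0 * k1_map.data / extraction_fraction, k1_map.affine, "CBF")


@dataclass
class KineticResult:
    """K1, k2 and CBF maps from a voxelwise kinetic fit."""

    k1_map: ParametricMap
    k2_map: ParametricMap
    cbf_map: ParametricMap
    flag_map: ParametricMap  # 1 where the fit was clamped or floored


def cbf_image(
    dyn: DynamicImage,
    cp: InputFunction,
    cfg: KineticConfig | None = None,
    brain_mask: np.ndarray | None = None,
) -> KineticResult:
    """Voxelwise weighted-integral fit inside ``brain_mask`` (0 outside).

    ``cp`` must already be plasma- and dispersion-corrected. All-zero voxel
    series yield k1 = 0 without a flag.
    """
    cfg = cfg or KineticConfig()
    fitter = WeightedIntegralFitter(cp, dyn.schedule, cfg)
    shape = dyn.data.shape[:3]
    if brain_mask is None:
        brain_mask = np.ones(shape, dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != shape:
        raise ValueError("brain mask grid does not match the dynamic image")

    tacs = dyn.data[brain_mask][:, fitter.frames]
    res = fitter.fit(tacs)

    k1 = np.zeros(shape)
    k2 = np.zeros(shape)
    flags = np.zeros(shape)
    k1[brain_mask] = res["k1"]
    k2[brain_mask] = np.nan_to_num(res["k2"], nan=0.0)
    flags[brain_mask] = res["flags"].astype(float)

    k1_map = ParametricMap(k1, dyn.affine, "K1")
    return KineticResult(
        k1_map=k1_map,
        k2_map=ParametricMap(k2, dyn.affine, "K1"),
        cbf_map=k1_to_cbf(k1_map, cfg.extraction_fraction),
        flag_map=ParametricMap(flags, dyn.affine, "activity"),
    )
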