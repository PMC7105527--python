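"""ALFF / fALFF maps from resting-state 4-D series.

After discarding initial volumes, removing the per-voxel linear trend and
optionally residualizing against nuisance regressors, the amplitude
spectrum of each voxel is the square root of its (windowless, one-sided)
periodogram. ALFF sums the amplitudes of the 0.01-0.08 Hz band; fALFF
divides that by the amplitude sum over all positive-frequency bins, giving
a scale-invariant fraction in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pibflow.io_core import ParametricMap


@dataclass
class FalffConfig:
    discard_volumes: int = 10
    band_hz: tuple[float, float] = (0.01, 0.08)
    tr_s: float = 2.3
    detrend: bool = True
    nuisance_regressors: np.ndarray | None = None  # (time after discard, k)

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("TR must be positive")
        lo, hi = self.band_hz
        nyquist = 0.5 / self.tr_s
        if not (0 < lo < hi <= nyquist):
            raise ValueError(
                f"band must satisfy 0 < low < high <= Nyquist ({nyquist:.4g} Hz)"
            )
        if self.discard_volumes < 0:
            raise ValueError("discard_volumes must be >= 0")


def preprocess(series: np.ndarray, cfg: FalffConfig) -> np.ndarray:
    """Discard initial volumes, detrend, and residualize nuisance signals.

    The nuisance regression is ordinary least squares per voxel against the
    supplied regressor matrix (an intercept column is always included); a
    rank-deficient design is rejected.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 4:
        raise ValueError("series must be 4-D (x, y, z, time)")
    n_t = series.shape[3]
    if n_t <= cfg.discard_volumes:
        raise ValueError(
            f"series length {n_t} not greater than discard count {cfg.discard_volumes}"
        )
    out = series[..., cfg.discard_volumes :].copy()
    n = out.shape[3]
    if not cfg.detrend and cfg.nuisance_regressors is None:
        return out

    design_cols = [np.ones(n)]
    if cfg.detrend:
        design_cols.append(np.arange(n, dtype=float))
    if cfg.nuisance_regressors is not None:
        reg = np.asarray(cfg.nuisance_regressors, dtype=float)
        if reg.ndim != 2 or reg.shape[0] != n:
            raise ValueError(
                f"nuisance regressors must be ({n}, k) after volume discard, got {reg.shape}"
            )
        design_cols.extend(reg.T)
    design = np.column_stack(design_cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient nuisance design matrix")

    flat = out.reshape(-1, n).T  # (time, voxels)
    beta, *_ = np.linalg.lstsq(design, flat, rcond=None)
    resid = flat - design @ beta
    # the intercept (and trend) are modelled and removed; nuisance columns
    # are projected out in the same pass
    return resid.T.reshape(out.shape)


def falff_map(
    series: np.ndarray, cfg: FalffConfig, affine: np.ndarray | None = None
) -> tuple[ParametricMap, ParametricMap]:
    """ALFF and fALFF maps of a (preprocessed) 4-D series.

    Band-edge bins are included (0.01 <= f <= 0.08 Hz); the fALFF
    denominator spans every positive-frequency bin. Zero-variance voxels
    get fALFF = 0.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 4:
        raise ValueError("series must be 4-D")
    if affine is None:
        affine = np.eye(4)
    n = series.shape[3]
    freqs = np.fft.rfftfreq(n, d=cfg.tr_s)
    pos = freqs > 0
    in_band = pos & (freqs >= cfg.band_hz[0]) & (freqs <= cfg.band_hz[1])
    if not in_band.any():
        raise ValueError("no spectral bins inside the band; series too short?")

    amplitude = np.abs(np.fft.rfft(series, axis=3))
    alff = amplitude[..., in_band].sum(axis=3)
    total = amplitude[..., pos].sum(axis=3)
    with np.errstate(invalid="ignore", divide="ignore"):
        falff = np.where(total > 0, alff / total, 0.0)
    return (
        ParametricMap(alff, affine, "ALFF"),
        ParametricMap(falff, affine, "fALFF"),
    )


def zscore_map(pmap: ParametricMap, mask: np.ndarray) -> ParametricMap:
    """Standardize a subject map to zero mean, unit SD within the mask.

    SD uses ddof=1. Voxels outside the mask are set to 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pmap.data.shape:
        raise ValueError("mask grid does not match the map")
    if mask.sum() < 2:
        raise ValueError("mask must contain at least 2 voxels")
    vals = pmap.data[mask]
    sd = vals.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance within mask; z-scores undefined")
    z = np.zeros_like(pmap.data)
    z[mask] = (vals - vals.mean()) / sd
    return ParametricMap(z, pmap.affine, "z")
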