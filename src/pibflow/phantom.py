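"""Synthetic PET/MRI phantoms with known ground truth.

The generator emulates the signal structure of a dynamic [11C]PiB PET/MRI
study of early Alzheimer's disease (27 AD) versus healthy controls (16 CTL):

* an arterial bolus (gamma-variate) whose measured, dispersed version fills
  a bright intracranial-artery blob, while its undispersed plasma fraction
  drives one-tissue-compartment tissue curves with region-specific
  K1 = E x CBF / 100 (CBF levels seeded from the study groups' regional
  means, E = 0.65);
* a late-frame static image whose regional contrast encodes target SUVr
  values (cerebellar reference = 1; white matter equal across groups);
* BOLD-like 4-D series with controllable low-frequency (0.01-0.08 Hz)
  amplitude for fALFF testing;
* a subject cohort (dose, weight, MMSE, visual score, regional CBF/SUVr
  draws) for group statistics and correlation analyses.

All randomness flows from explicit integer seeds; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from pibflow._ode import disperse, tissue_response
from pibflow.input_function import InputFunction, PLASMA_FRACTION
from pibflow.io_core import (
    DynamicImage,
    FrameSchedule,
    Parcellation,
    ParametricMap,
    SubjectRecord,
)

EXTRACTION_FRACTION = 0.65

LOBES = ("frontal", "temporal", "parietal", "occipital")
HEMIS = ("right", "left")

# Regional PET-CBF (mL/min/100 g) and PiB SUVr group means +/- SD, per
# (region, hemisphere), for the control (CTL) and early-AD (AD) groups.
CTL_CBF = {
    ("frontal", "right"): (41.6, 4.5), ("frontal", "left"): (39.9, 4.0),
    ("temporal", "right"): (39.9, 3.0), ("temporal", "left"): (36.6, 3.1),
    ("parietal", "right"): (44.3, 5.8), ("parietal", "left"): (41.7, 4.7),
    ("occipital", "right"): (44.0, 5.8), ("occipital", "left"): (42.3, 4.7),
    ("cerebellum", "right"): (45.4, 5.9), ("cerebellum", "left"): (43.9, 5.9),
}
AD_CBF = {
    ("frontal", "right"): (38.7, 8.7), ("frontal", "left"): (37.7, 8.0),
    ("temporal", "right"): (34.5, 8.6), ("temporal", "left"): (32.2, 7.4),
    ("parietal", "right"): (37.8, 10.6), ("parietal", "left"): (36.3, 9.3),
    ("occipital", "right"): (39.7, 10.4), ("occipital", "left"): (38.4, 9.4),
    ("cerebellum", "right"): (42.7, 9.4), ("cerebellum", "left"): (41.6, 8.7),
}
CTL_SUVR = {
    ("frontal", "right"): (1.02, 0.18), ("frontal", "left"): (1.04, 0.19),
    ("temporal", "right"): (1.00, 0.12), ("temporal", "left"): (0.99, 0.12),
    ("parietal", "right"): (1.01, 0.16), ("parietal", "left"): (1.03, 0.19),
    ("occipital", "right"): (0.99, 0.12), ("occipital", "left"): (1.02, 0.12),
}
AD_SUVR = {
    ("frontal", "right"): (1.74, 0.28), ("frontal", "left"): (1.77, 0.32),
    ("temporal", "right"): (1.54, 0.28), ("temporal", "left"): (1.54, 0.27),
    ("parietal", "right"): (1.79, 0.30), ("parietal", "left"): (1.81, 0.31),
    ("occipital", "right"): (1.50, 0.24), ("occipital", "left"): (1.51, 0.21),
}
# White matter: myelin-bound uptake above CTL cortex and equal across groups.
WM_SUVR = (1.25, 0.10)
WM_CBF = 20.0  # typical white-matter flow; not a study-reported value

# Clinical seeds: MMSE (mean, SD) and group sizes of the emulated cohort.
GROUP_SIZES = {"AD": 27, "CTL": 16}
MMSE_SEED = {"AD": (24.0, 3.0), "CTL": (29.0, 1.0)}
# hippocampal volume index (arbitrary units) driving VSRAD-style z-scores.
# VSRAD references an external normal database, emulated by the constants
# below; the group seeds put the database-referenced z means near 1.86 (AD)
# and 1.27 (CTL)
NORMATIVE_HIPPO = (5.0, 0.5)  # normal-database mean, SD
HIPPO_SEED = {"AD": (4.07, 0.60), "CTL": (4.365, 0.50)}

REGION_LABELS = {
    1: "frontal_r", 2: "frontal_l",
    3: "temporal_r", 4: "temporal_l",
    5: "parietal_r", 6: "parietal_l",
    7: "occipital_r", 8: "occipital_l",
    9: "cerebellum_r", 10: "cerebellum_l",
    11: "white_matter", 12: "artery",
}
ARTERY_LABEL = 12
WM_LABEL = 11
CEREBELLUM_LABELS = (9, 10)
CORTEX_LABELS = (1, 2, 3, 4, 5, 6, 7, 8)

_HEMI_SUFFIX = {"right": "r", "left": "l"}


def _region_name(lobe: str, hemi: str) -> str:
    return f"{lobe}_{_HEMI_SUFFIX[hemi]}"


@dataclass
class PhantomSpec:
    """Geometry, kinetic ground truth, and noise settings of the phantom."""

    grid_shape: tuple[int, int, int] = (20, 20, 20)
    voxel_size_mm: float = 4.0
    region_labels: dict[int, str] = field(default_factory=lambda: dict(REGION_LABELS))
    region_cbf: dict[str, float] = field(default_factory=dict)  # mL/min/100 g
    region_suvr: dict[str, float] = field(default_factory=dict)
    k2_per_region: dict[str, float] = field(default_factory=dict)  # 1/min
    dispersion_tau_s: float = 4.0
    noise_scale: float = 0.0
    seed: int = 0
    extraction_fraction: float = EXTRACTION_FRACTION
    input_peak_time_s: float = 25.0
    input_peak_kbq_ml: float = 80.0
    dt_s: float = 0.25

    def __post_init__(self) -> None:
        if any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        names = set(self.region_labels.values())
        if "artery" not in names:
            raise ValueError("phantom requires an artery region")
        if not any(n.startswith("cerebellum") for n in names):
            raise ValueError("phantom requires a cerebellar region (SUVr reference)")
        for name, cbf in self.region_cbf.items():
            if cbf <= 0:
                raise ValueError(f"CBF must be positive (region {name}: {cbf})")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff

    def label_of(self, name: str) -> int:
        for k, v in self.region_labels.items():
            if v == name:
                return k
        raise KeyError(name)


def default_phantom_spec(group: str = "CTL", **overrides) -> PhantomSpec:
    """Phantom spec seeded with one group's regional CBF/SUVr means.

    k2 defaults: 0.10 1/min in cortex, 0.12 in cerebellum, 0.05 in white
    matter — plausible early-phase PiB efflux rates.
    """
    cbf_seed = CTL_CBF if group == "CTL" else AD_CBF
    suvr_seed = CTL_SUVR if group == "CTL" else AD_SUVR
    region_cbf: dict[str, float] = {}
    region_suvr: dict[str, float] = {}
    k2: dict[str, float] = {}
    for (lobe, hemi), (mean, _sd) in cbf_seed.items():
        name = _region_name(lobe, hemi)
        region_cbf[name] = mean
        k2[name] = 0.12 if lobe == "cerebellum" else 0.10
    for (lobe, hemi), (mean, _sd) in suvr_seed.items():
        region_suvr[_region_name(lobe, hemi)] = mean
    region_suvr["cerebellum_r"] = 1.0
    region_suvr["cerebellum_l"] = 1.0
    region_cbf["white_matter"] = WM_CBF
    region_suvr["white_matter"] = WM_SUVR[0]
    k2["white_matter"] = 0.05
    region_suvr["artery"] = 0.5  # residual blood pool at late times
    return PhantomSpec(
        region_cbf=region_cbf, region_suvr=region_suvr, k2_per_region=k2, **overrides
    )


def build_parcellation(spec: PhantomSpec) -> Parcellation:
    """Deterministic block geometry on the spec's grid.

    A one-voxel background border surrounds the volume. The bottom slab is
    cerebellum (split by hemisphere) with a small artery blob at its centre;
    above it, a central white-matter core is wrapped by a cortical shell
    divided into four lobes (anterior to posterior) per hemisphere.
    """
    nx, ny, nz = spec.grid_shape
    if min(nx, ny, nz) < 10:
        raise ValueError("grid too small for the phantom geometry (min 10 per axis)")
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    interior = (
        (x >= 1) & (x < nx - 1) & (y >= 1) & (y < ny - 1) & (z >= 1) & (z < nz - 1)
    )
    right = x < nx // 2  # lower-x half = right hemisphere

    z_cereb = max(3, nz // 5)
    cereb = interior & (z < 1 + z_cereb)
    labels[cereb & right] = 9
    labels[cereb & ~right] = 10

    # supratentorial compartment
    supra = interior & (z >= 1 + z_cereb)
    # white-matter core
    core = (
        supra
        & (x >= nx // 4) & (x < nx - nx // 4)
        & (y >= ny // 4) & (y < ny - ny // 4)
        & (z >= 1 + z_cereb + (nz - z_cereb) // 5)
        & (z < nz - 1 - (nz - z_cereb) // 5)
    )
    # cortical shell: remaining supratentorial voxels, lobes by y-quartile
    ybins = np.clip(((y - 1) * 4) // (ny - 2), 0, 3)
    lobe_label_right = {0: 1, 1: 3, 2: 5, 3: 7}
    lobe_label_left = {0: 2, 1: 4, 2: 6, 3: 8}
    for b in range(4):
        sel = supra & ~core & (ybins == b)
        labels[sel & right] = lobe_label_right[b]
        labels[sel & ~right] = lobe_label_left[b]
    labels[core] = WM_LABEL

    # artery blob: 3 x 3 x 4 voxels at the base, overriding cerebellum
    cx, cy = nx // 2 - 1, ny // 2 - 1
    labels[cx - 1 : cx + 2, cy - 1 : cy + 2, 1:5] = ARTERY_LABEL

    return Parcellation(labels, dict(spec.region_labels), spec.affine)


def make_input_function(
    peak_time: float = 25.0,
    peak_value: float = 80.0,
    tau: float = 4.0,
    t_end: float = 180.0,
    dt: float = 0.25,
    onset: float = 5.0,
    shape_alpha: float = 3.0,
    plasma_fraction: float = PLASMA_FRACTION,
) -> tuple[InputFunction, InputFunction]:
    """Gamma-variate arterial bolus and its dispersed version.

    Returns ``(undispersed, dispersed)`` on a dense uniform grid; the
    dispersed curve is the convolution with (1/tau) e^(-t/tau) (identity for
    ``tau <= 0``). The bolus is b(t) = A * u^alpha * e^(alpha(1-u)) with
    u = (t - onset)/(peak_time - onset), peaking exactly at ``peak_time``
    with value ``peak_value``.
    """
    if peak_time <= onset:
        raise ValueError("peak_time must exceed the bolus onset")
    if dt <= 0 or dt > 1.0:
        raise ValueError("dense grid spacing must be in (0, 1] s")
    t = np.arange(0.0, t_end + dt / 2, dt)
    u = np.maximum(t - onset, 0.0) / (peak_time - onset)
    bolus = peak_value * u**shape_alpha * np.exp(shape_alpha * (1.0 - u))
    dispersed = disperse(bolus, dt, tau)
    return (
        InputFunction(t, bolus, plasma_fraction=plasma_fraction),
        InputFunction(t, dispersed, plasma_fraction=plasma_fraction),
    )


@dataclass
class GroundTruth:
    """Known truth carried alongside a generated phantom."""

    true_input: InputFunction  # undispersed whole-blood bolus
    true_input_dispersed: InputFunction
    true_k1_map: ParametricMap  # 1/min
    true_cbf_map: ParametricMap  # mL/min/100 g
    true_k2_map: ParametricMap
    parcellation: Parcellation


def _frame_average(dense_t: np.ndarray, dense_c: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Mean of a dense curve over each frame interval (exact trapezoid)."""
    cum = np.concatenate([[0.0], cumulative_trapezoid(dense_c, dense_t)])
    at = lambda s: np.interp(s, dense_t, cum)  # noqa: E731
    return (at(schedule.ends) - at(schedule.starts)) / schedule.durations


def make_dynamic_pet(
    spec: PhantomSpec, schedule: FrameSchedule
) -> tuple[DynamicImage, GroundTruth]:
    """Forward-simulate a decay-corrected 4-D dynamic PET volume.

    Tissue voxels follow the one-tissue compartment model driven by the
    *undispersed* plasma input (C(t) = K1 int Cp e^(-k2(t-s)) ds) with
    region K1 = E x CBF / 100; artery voxels carry the dispersed whole-blood
    curve. Gaussian noise has SD = noise_scale * sqrt(C / frame duration).
    """
    if schedule.total_duration < 180.0:
        raise ValueError("schedule must cover at least 0-180 s")
    parc = build_parcellation(spec)
    undisp, disp = make_input_function(
        peak_time=spec.input_peak_time_s,
        peak_value=spec.input_peak_kbq_ml,
        tau=spec.dispersion_tau_s,
        t_end=schedule.total_duration,
        dt=spec.dt_s,
    )
    t = undisp.times
    cp = undisp.plasma

    k1_map = np.zeros(spec.grid_shape)
    cbf_map = np.zeros(spec.grid_shape)
    k2_map = np.zeros(spec.grid_shape)
    data = np.zeros(spec.grid_shape + (schedule.n_frames,))

    for label, name in spec.region_labels.items():
        region = parc.labels == label
        if not region.any():
            continue
        if name == "artery":
            frames = _frame_average(t, disp.whole_blood, schedule)
        else:
            cbf = spec.region_cbf[name]
            k1 = spec.extraction_fraction * cbf / 100.0
            k2 = spec.k2_per_region[name]
            dense = tissue_response(cp, spec.dt_s, k1, k2)
            frames = _frame_average(t, dense, schedule)
            k1_map[region] = k1
            cbf_map[region] = cbf
            k2_map[region] = k2
        data[region, :] = frames

    if spec.noise_scale > 0:
        rng = np.random.default_rng(spec.seed)
        sd = spec.noise_scale * np.sqrt(
            np.maximum(data, 0.0) / schedule.durations[None, None, None, :]
        )
        data = data + rng.standard_normal(data.shape) * sd

    dyn = DynamicImage(data, spec.affine, schedule)
    truth = GroundTruth(
        true_input=undisp,
        true_input_dispersed=disp,
        true_k1_map=ParametricMap(k1_map, spec.affine, "K1"),
        true_cbf_map=ParametricMap(cbf_map, spec.affine, "CBF"),
        true_k2_map=ParametricMap(k2_map, spec.affine, "K1"),
        parcellation=parc,
    )
    return dyn, truth


def make_late_static(
    spec: PhantomSpec,
    dose_mbq: float = 740.0,
    weight_kg: float = 60.0,
    reference_suv: float = 1.2,
    frame_duration_s: float = 1200.0,
) -> tuple[ParametricMap, ParametricMap]:
    """Late-frame (50-70 min) static activity image plus its true SUVr map.

    Regional activity = region_suvr * reference_suv * (dose/weight), so the
    SUV chain (divide by dose-per-gram, normalize to cerebellum) recovers
    the spec's SUVr pattern exactly in the noise-free case.
    """
    if dose_mbq <= 0 or weight_kg <= 0:
        raise ValueError("dose and weight must be positive")
    parc = build_parcellation(spec)
    dose_per_g = dose_mbq * 1000.0 / (weight_kg * 1000.0)  # kBq/g == kBq/mL at 1 g/mL
    suvr = np.zeros(spec.grid_shape)
    for label, name in spec.region_labels.items():
        suvr[parc.labels == label] = spec.region_suvr.get(name, 0.0)
    activity = suvr * reference_suv * dose_per_g
    if spec.noise_scale > 0:
        rng = np.random.default_rng(spec.seed + 1)
        sd = spec.noise_scale * np.sqrt(np.maximum(activity, 0.0) / frame_duration_s)
        activity = activity + rng.standard_normal(activity.shape) * sd
    return (
        ParametricMap(activity, spec.affine, "activity"),
        ParametricMap(suvr, spec.affine, "SUVr"),
    )


@dataclass
class BoldPhantom:
    """BOLD-like 4-D series with a per-voxel target fALFF."""

    data: np.ndarray  # (x, y, z, time)
    tr: float  # s
    target_falff: np.ndarray  # 3-D


def make_bold_series(
    grid_shape: tuple[int, int, int] = (12, 12, 12),
    n_volumes: int = 201,
    tr: float = 2.3,
    low_freq_amp: float = 1.0,
    broadband_amp: float = 0.2,
    seed: int = 0,
    trend_slope: float = 0.0,
    sinusoid_freqs: tuple[float, ...] = (0.02, 0.04, 0.06),
    band: tuple[float, float] = (0.01, 0.08),
    amp_map: np.ndarray | None = None,
    snap_to_bins: bool = True,
) -> BoldPhantom:
    """Sinusoids in the low-frequency band + white noise + optional trend.

    Each voxel's series is ``low_freq_amp * (local scale) * sum_k
    sin(2 pi f_k t + phase_k)`` with voxelwise random phases, plus white
    noise of SD ``broadband_amp`` and a linear trend of ``trend_slope`` per
    volume. ``amp_map`` optionally modulates the low-frequency amplitude
    voxelwise (e.g. to plant a regional deficit).

    The recorded target fALFF combines the exact amplitude spectrum of the
    deterministic component with the expected flat amplitude spectrum of
    the white noise; it is exact in the pure-sinusoid and pure-noise limits
    and an expectation-level approximation for mixtures.
    """
    if n_volumes < 20:
        raise ValueError("need at least 20 volumes")
    if tr <= 0:
        raise ValueError("TR must be positive")
    rng = np.random.default_rng(seed)
    shape = tuple(int(n) for n in grid_shape)
    n_vox = int(np.prod(shape))
    t = np.arange(n_volumes) * tr

    if snap_to_bins:
        # align sinusoids with DFT bins of the generated window so the
        # pure-sinusoid limit is leakage-free (target fALFF -> 1)
        window = n_volumes * tr
        sinusoid_freqs = tuple(max(round(f * window), 1) / window for f in sinusoid_freqs)

    scale = np.ones(n_vox) if amp_map is None else np.asarray(amp_map, float).ravel()
    det = np.zeros((n_vox, n_volumes))
    for f in sinusoid_freqs:
        phase = rng.uniform(0, 2 * np.pi, size=n_vox)
        det += np.sin(2 * np.pi * f * t[None, :] + phase[:, None])
    det *= low_freq_amp * scale[:, None]

    noise = broadband_amp * rng.standard_normal((n_vox, n_volumes))
    series = det + noise + trend_slope * np.arange(n_volumes)[None, :]

    # target fALFF: exact deterministic amplitudes + expected noise amplitudes
    freqs = np.fft.rfftfreq(n_volumes, d=tr)
    pos = freqs > 0
    in_band = pos & (freqs >= band[0]) & (freqs <= band[1])
    det_amp = np.abs(np.fft.rfft(det, axis=1))
    a_band = det_amp[:, in_band].sum(axis=1)
    a_pos = det_amp[:, pos].sum(axis=1)
    noise_bin = broadband_amp * np.sqrt(np.pi * n_volumes) / 2.0  # E|CN(0, N sigma^2)|
    denom = a_pos + noise_bin * pos.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        target = np.where(denom > 0, (a_band + noise_bin * in_band.sum()) / denom, 0.0)

    return BoldPhantom(
        data=series.reshape(shape + (n_volumes,)),
        tr=tr,
        target_falff=target.reshape(shape),
    )


# ---------------------------------------------------------------------------
# cohort generation


def _cortical_mean(suvr_by_region: dict[tuple[str, str], float]) -> float:
    per_hemi = []
    for hemi in HEMIS:
        per_hemi.append(np.mean([suvr_by_region[(lobe, hemi)] for lobe in LOBES]))
    return float(np.mean(per_hemi))


def _visual_score(cortical_suvr_mean: float) -> int:
    """Map cortical uptake intensity to the 4-point visual scale."""
    if cortical_suvr_mean < 1.2:
        return 0
    if cortical_suvr_mean < 1.5:
        return 1
    if cortical_suvr_mean < 1.9:
        return 2
    return 3


def generate_cohort(
    n_ad: int = GROUP_SIZES["AD"],
    n_ctl: int = GROUP_SIZES["CTL"],
    seed: int = 0,
) -> tuple[list[SubjectRecord], pd.DataFrame, pd.DataFrame]:
    """Draw a synthetic AD/CTL cohort with per-subject regional values.

    Regional CBF and SUVr are drawn from the group means/SDs that seed the
    phantom. AD subjects carry a latent severity factor that jointly lowers
    MMSE and raises cortical SUVr, so uptake-cognition correlations emerge
    at the cohort level. White-matter SUVr is drawn identically in both
    groups. Visual scores are thresholded from each subject's cortical
    SUVr mean.

    Returns ``(subjects, regional, extras)``: a SubjectRecord list, a long
    regional table (subject, region, hemisphere, quantity, value), and a
    subject-level table with MMSE, visual score and a hippocampal volume
    index (control-referenced z-scoring of which emulates VSRAD).
    """
    rng = np.random.default_rng(seed)
    subjects: list[SubjectRecord] = []
    regional_rows = []
    extra_rows = []

    for group, n in (("CTL", n_ctl), ("AD", n_ad)):
        cbf_seed = CTL_CBF if group == "CTL" else AD_CBF
        suvr_seed = CTL_SUVR if group == "CTL" else AD_SUVR
        mmse_mu, mmse_sd = MMSE_SEED[group]
        hippo_mu, hippo_sd = HIPPO_SEED[group]
        for i in range(n):
            sid = f"{group.lower()}{i + 1:02d}"
            severity = rng.standard_normal() if group == "AD" else 0.0
            dose = rng.uniform(700.0, 750.0)
            weight = float(np.clip(rng.normal(60.0, 8.0), 40.0, 95.0))
            mmse = int(np.clip(round(rng.normal(mmse_mu, mmse_sd) - 1.5 * severity), 0, 30))

            suvr_by_region: dict[tuple[str, str], float] = {}
            for (lobe, hemi), (mu, sd) in suvr_seed.items():
                shift = 0.6 * severity * sd if group == "AD" else 0.0
                val = max(rng.normal(mu + shift, 0.8 * sd if group == "AD" else sd), 0.1)
                suvr_by_region[(lobe, hemi)] = val
                regional_rows.append((sid, lobe, hemi, "SUVr", val))
            for (lobe, hemi), (mu, sd) in cbf_seed.items():
                val = max(rng.normal(mu, sd), 5.0)
                regional_rows.append((sid, lobe, hemi, "CBF", val))
            wm_suvr = max(rng.normal(*WM_SUVR), 0.5)
            regional_rows.append((sid, "white_matter", "both", "SUVr", wm_suvr))
            regional_rows.append((sid, "cerebellum", "both", "SUVr", 1.0))

            score = _visual_score(_cortical_mean(suvr_by_region))
            hippo = max(rng.normal(hippo_mu, hippo_sd), 1.0)
            subjects.append(
                SubjectRecord(
                    id=sid,
                    group=group,
                    injected_dose_mbq=dose,
                    body_weight_kg=weight,
                    mmse=mmse,
                    visual_score=score,
                )
            )
            extra_rows.append((sid, group, mmse, score, hippo))

    regional = pd.DataFrame(
        regional_rows, columns=["subject", "region", "hemisphere", "quantity", "value"]
    )
    extras = pd.DataFrame(
        extra_rows,
        columns=["subject", "group", "mmse", "visual_score", "hippocampal_value"],
    )
    return subjects, regional, extras


def ad_phantom_spec(**overrides) -> PhantomSpec:
    """Convenience: phantom spec seeded with the AD group means."""
    return default_phantom_spec(group="AD", **overrides)
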