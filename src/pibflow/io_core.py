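"""Shared data model and NIfTI/JSON/CSV readers and writers.

Conventions: voxel indices are 0-based; world coordinates follow the NIfTI
affine (RAS+); all times are in seconds; activity concentrations in kBq/mL.
Frame schedules travel as BIDS-PET-style JSON sidecars with
``FrameTimesStart`` and ``FrameDuration`` arrays in seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

#: quantity tags a ParametricMap may carry (unit in parentheses)
MAP_QUANTITIES = frozenset(
    {"K1", "CBF", "SUV", "SUVr", "fALFF", "ALFF", "z", "t", "activity"}
)

AFFINE_TOL_MM = 1e-4


class GridMismatchError(ValueError):
    """Raised when two images do not share a voxel grid / affine."""


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous dynamic-PET frame timing.

    Parameters
    ----------
    starts : frame start times in seconds, monotone, first frame at 0.
    durations : frame durations in seconds, all positive.
    """

    starts: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "durations", durations)
        if starts.ndim != 1 or starts.shape != durations.shape:
            raise ValueError("starts and durations must be 1-D and equal length")
        if starts.size == 0:
            raise ValueError("empty schedule")
        if starts[0] != 0:
            raise ValueError(f"first frame must start at 0 s, got {starts[0]}")
        if np.any(durations <= 0):
            raise ValueError("all frame durations must be positive")
        ends = starts + durations
        if not np.allclose(starts[1:], ends[:-1], atol=1e-9):
            raise ValueError("schedule must be contiguous (start[i+1] == end[i])")

    @property
    def n_frames(self) -> int:
        return self.starts.size

    @property
    def mid_times(self) -> np.ndarray:
        """Frame mid-times in seconds (start + duration/2)."""
        return self.starts + self.durations / 2.0

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.durations

    @property
    def total_duration(self) -> float:
        return float(self.ends[-1])

    def frames_within(self, t_max: float) -> np.ndarray:
        """Indices of frames ending at or before ``t_max`` seconds."""
        return np.flatnonzero(self.ends <= t_max + 1e-9)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "FrameTimesStart": self.starts.tolist(),
            "FrameDuration": self.durations.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FrameSchedule":
        payload = json.loads(Path(path).read_text())
        return cls(
            np.asarray(payload["FrameTimesStart"], dtype=float),
            np.asarray(payload["FrameDuration"], dtype=float),
        )


def default_schedule() -> FrameSchedule:
    """The study's 70-min dynamic composition.

    12 x 5 s, 6 x 10 s, 3 x 20 s, 4 x 30 s, 5 x 60 s, 4 x 5 min, 4 x 10 min
    (38 frames); the first 21 frames tile exactly the first 3 minutes used
    for kinetic fitting.
    """
    durations = np.concatenate(
        [
            np.full(12, 5.0),
            np.full(6, 10.0),
            np.full(3, 20.0),
            np.full(4, 30.0),
            np.full(5, 60.0),
            np.full(4, 300.0),
            np.full(4, 600.0),
        ]
    )
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return FrameSchedule(starts, durations)


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    return affine


def affines_match(a: np.ndarray, b: np.ndarray, tol: float = AFFINE_TOL_MM) -> bool:
    return bool(np.all(np.abs(np.asarray(a) - np.asarray(b)) <= tol))


def require_same_grid(a: "ParametricMap | DynamicImage", b) -> None:
    if a.data.shape[:3] != b.data.shape[:3] or not affines_match(a.affine, b.affine):
        raise GridMismatchError(
            f"grid mismatch: shapes {a.data.shape[:3]} vs {b.data.shape[:3]}, "
            f"max affine diff {np.max(np.abs(a.affine - b.affine)):.3g} mm"
        )


@dataclass
class DynamicImage:
    """4-D decay-corrected activity (kBq/mL) with affine and frame schedule."""

    data: np.ndarray
    affine: np.ndarray
    schedule: FrameSchedule

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = _check_affine(self.affine)
        if self.data.ndim != 4:
            raise ValueError("dynamic image must be 4-D")
        if self.data.shape[3] != self.schedule.n_frames:
            raise ValueError(
                f"frame-count mismatch: image has {self.data.shape[3]} frames, "
                f"schedule has {self.schedule.n_frames}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("dynamic image contains non-finite values")

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class ParametricMap:
    """3-D map of a single quantity on a voxel grid.

    ``quantity`` is one of: K1 (1/min), CBF (mL/min/100 g), SUV, SUVr,
    fALFF, ALFF, z, t (unitless), or activity (kBq/mL).
    """

    data: np.ndarray
    affine: np.ndarray
    quantity: str = "activity"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = _check_affine(self.affine)
        if self.data.ndim != 3:
            raise ValueError("parametric map must be 3-D")
        if self.quantity not in MAP_QUANTITIES:
            raise ValueError(
                f"unknown quantity {self.quantity!r}; expected one of {sorted(MAP_QUANTITIES)}"
            )


@dataclass
class Parcellation:
    """Integer label volume with a legend; 0 is background."""

    labels: np.ndarray
    legend: dict[int, str]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("parcellation must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("parcellation labels must be integers")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative (0 = background)")
        self.affine = _check_affine(self.affine)
        self.legend = {int(k): str(v) for k, v in self.legend.items()}
        present = set(np.unique(self.labels).tolist())
        missing = [k for k in self.legend if k != 0 and k not in present]
        if missing:
            raise ValueError(f"legend labels absent from volume: {missing}")

    @property
    def data(self) -> np.ndarray:  # grid-compat shim for require_same_grid
        return self.labels

    def mask(self, label: int | Sequence[int]) -> np.ndarray:
        labels = np.atleast_1d(label)
        return np.isin(self.labels, labels)

    def label_of(self, name: str) -> int:
        for k, v in self.legend.items():
            if v == name:
                return k
        raise KeyError(f"region {name!r} not in legend")


@dataclass
class SubjectRecord:
    """Per-subject metadata: dose (MBq), weight (kg), MMSE, group, visual score."""

    id: str
    group: str
    injected_dose_mbq: float
    body_weight_kg: float
    mmse: int
    visual_score: int | None = None

    def __post_init__(self) -> None:
        if self.group not in ("AD", "CTL"):
            raise ValueError(f"group must be 'AD' or 'CTL', got {self.group!r}")
        if self.injected_dose_mbq <= 0 or self.body_weight_kg <= 0:
            raise ValueError("dose and weight must be positive")
        if not (0 <= int(self.mmse) <= 30):
            raise ValueError(f"MMSE must be in 0..30, got {self.mmse}")
        self.mmse = int(self.mmse)
        if self.visual_score is not None:
            if int(self.visual_score) not in (0, 1, 2, 3):
                raise ValueError(
                    f"visual score must be in {{0,1,2,3}}, got {self.visual_score}"
                )
            self.visual_score = int(self.visual_score)


# ---------------------------------------------------------------------------
# file I/O


def write_map(pmap: ParametricMap, path: str | Path) -> None:
    """Write a 3-D map as NIfTI-1 (float32 data, affine preserved exactly)."""
    img = nib.Nifti1Image(pmap.data.astype(np.float32), pmap.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_map(path: str | Path, quantity: str = "activity") -> ParametricMap:
    img = nib.load(str(path))
    return ParametricMap(np.asarray(img.dataobj, dtype=float), img.affine, quantity)


def write_dynamic(dyn: DynamicImage, path: str | Path, sidecar: str | Path | None = None) -> None:
    img = nib.Nifti1Image(dyn.data.astype(np.float32), dyn.affine)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    if sidecar is None:
        sidecar = _sidecar_path(path)
    dyn.schedule.to_json(sidecar)


def read_dynamic(path: str | Path, schedule_path: str | Path | None = None) -> DynamicImage:
    """Read a 4-D NIfTI with its frame-schedule JSON sidecar.

    Rejects with both counts named if the schedule and image disagree on the
    number of frames.
    """
    img = nib.load(str(path))
    if schedule_path is None:
        schedule_path = _sidecar_path(path)
    schedule = FrameSchedule.from_json(schedule_path)
    return DynamicImage(np.asarray(img.dataobj, dtype=float), img.affine, schedule)


def _sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")


def write_parcellation(parc: Parcellation, path: str | Path) -> None:
    img = nib.Nifti1Image(parc.labels.astype(np.int16), parc.affine)
    nib.save(img, str(path))
    legend_path = _sidecar_path(path)
    legend_path.write_text(json.dumps({str(k): v for k, v in parc.legend.items()}, indent=1))


def read_parcellation(path: str | Path, legend_path: str | Path | None = None) -> Parcellation:
    img = nib.load(str(path))
    if legend_path is None:
        legend_path = _sidecar_path(path)
    legend = {int(k): v for k, v in json.loads(Path(legend_path).read_text()).items()}
    return Parcellation(np.asarray(img.dataobj).astype(np.int32), legend, img.affine)


SUBJECT_COLUMNS = ["id", "group", "dose_mbq", "weight_kg", "mmse", "visual_score"]


def write_subjects(subjects: Sequence[SubjectRecord], path: str | Path) -> None:
    rows = [
        {
            "id": s.id,
            "group": s.group,
            "dose_mbq": s.injected_dose_mbq,
            "weight_kg": s.body_weight_kg,
            "mmse": s.mmse,
            "visual_score": s.visual_score if s.visual_score is not None else "",
        }
        for s in subjects
    ]
    pd.DataFrame(rows, columns=SUBJECT_COLUMNS).to_csv(path, index=False)


def read_subjects(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        score = row.get("visual_score")
        score = None if pd.isna(score) else int(score)
        out.append(
            SubjectRecord(
                id=str(row["id"]),
                group=str(row["group"]),
                injected_dose_mbq=float(row["dose_mbq"]),
                body_weight_kg=float(row["weight_kg"]),
                mmse=int(row["mmse"]),
                visual_score=score,
            )
        )
    return out
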