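"""Late-frame amyloid quantification: SUV, SUVr, GM/WM ratio, correlations.

SUV = activity / (injected dose per body weight); SUVr normalizes SUV to
the mean over the cerebellar cortical reference, and the cortical SUVr
ratio further divides the cortical gray-matter SUVr mean by the
white-matter SUVr to contrast specific cortical binding against the
group-stable myelin-bound component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from pibflow.io_core import Parcellation, ParametricMap, SubjectRecord, require_same_grid


def suv_image(static: ParametricMap, dose_mbq: float, weight_kg: float) -> ParametricMap:
    """Standardized uptake value: activity / (dose per gram body weight).

    With activity in kBq/mL and unit tissue density, a voxel whose
    concentration equals the injected dose per gram of body weight maps to
    SUV = 1.
    """
    if dose_mbq <= 0 or weight_kg <= 0:
        raise ValueError("dose and weight must be positive")
    dose_per_g = dose_mbq * 1000.0 / (weight_kg * 1000.0)  # kBq/g
    return ParametricMap(static.data / dose_per_g, static.affine, "SUV")


def suvr_image(
    suv: ParametricMap,
    parc: Parcellation,
    reference: int | Sequence[int],
) -> ParametricMap:
    """Normalize an SUV map by the mean over the reference label(s).

    The cerebellar cortex is the conventional reference for PiB; passing
    both hemisphere labels averages over their union.
    """
    require_same_grid(suv, parc)
    ref_mask = parc.mask(reference)
    if not ref_mask.any():
        raise ValueError(f"reference label(s) {reference} empty in parcellation")
    ref_mean = float(suv.data[ref_mask].mean())
    if ref_mean <= 0:
        raise ValueError(f"non-positive reference mean ({ref_mean:g})")
    return ParametricMap(suv.data / ref_mean, suv.affine, "SUVr")


def suvr_ratio(
    regional_suvr: Mapping[str, float] | pd.Series,
    gm_regions: Sequence[str],
    wm_region: str = "white_matter",
) -> float:
    """Cortical gray-matter SUVr mean divided by white-matter SUVr."""
    values = dict(regional_suvr)
    missing = [r for r in (*gm_regions, wm_region) if r not in values]
    if missing:
        raise KeyError(f"regions missing from table: {missing}")
    wm = float(values[wm_region])
    if wm <= 0:
        raise ValueError(f"non-positive white-matter SUVr ({wm:g})")
    gm = float(np.mean([values[r] for r in gm_regions]))
    return gm / wm


def cortical_suvr_mean(
    regional: pd.DataFrame, subject: str, lobes: Sequence[str], hemis: Sequence[str] = ("right", "left")
) -> float:
    """Per-hemisphere lobar mean, then averaged across hemispheres.

    The lobar average is unweighted; the two hemisphere means are averaged
    so an unequal number of regions per hemisphere cannot skew the result.
    This convention is configurable by passing different region lists.
    """
    sub = regional[(regional["subject"] == subject) & (regional["quantity"] == "SUVr")]
    hemi_means = []
    for hemi in hemis:
        vals = sub[(sub["hemisphere"] == hemi) & (sub["region"].isin(lobes))]["value"]
        if len(vals) == 0:
            raise ValueError(f"no SUVr values for subject {subject}, hemisphere {hemi}")
        hemi_means.append(vals.mean())
    return float(np.mean(hemi_means))


@dataclass
class CorrelationReport:
    """Pearson correlations of uptake metrics against cognition (MMSE)."""

    table: pd.DataFrame  # columns: pair, r, p, n, flagged

    def r(self, pair: str) -> float:
        row = self.table[self.table["pair"] == pair]
        if row.empty:
            raise KeyError(pair)
        return float(row["r"].iloc[0])


def score_correlations(
    subjects: Sequence[SubjectRecord],
    cortical_suvr: Mapping[str, float],
    suvr_ratios: Mapping[str, float] | None = None,
) -> CorrelationReport:
    """Pearson r and two-sided p for uptake metrics vs MMSE.

    Pairs reported: (MMSE, cortical SUVr mean), (MMSE, visual score) and,
    when ratios are supplied, (MMSE, SUVr ratio). Subjects missing a value
    are dropped pairwise; a pair with fewer than 3 complete subjects or
    zero variance in either variable is flagged with r = NaN.
    """
    rows = []

    def add_pair(name: str, xs: list[float], ys: list[float]) -> None:
        n = len(xs)
        if n < 3 or np.std(xs) == 0 or np.std(ys) == 0:
            rows.append({"pair": name, "r": np.nan, "p": np.nan, "n": n, "flagged": True})
            return
        r, p = stats.pearsonr(xs, ys)
        rows.append({"pair": name, "r": float(r), "p": float(p), "n": n, "flagged": False})

    mmse = {s.id: s.mmse for s in subjects}

    xs, ys = zip(*[(mmse[i], v) for i, v in cortical_suvr.items() if i in mmse])
    add_pair("mmse_vs_cortical_suvr", list(xs), list(ys))

    scored = [(s.mmse, s.visual_score) for s in subjects if s.visual_score is not None]
    if scored:
        xs2, ys2 = zip(*scored)
        add_pair("mmse_vs_visual_score", list(xs2), list(ys2))

    if suvr_ratios is not None:
        xs3, ys3 = zip(*[(mmse[i], v) for i, v in suvr_ratios.items() if i in mmse])
        add_pair("mmse_vs_suvr_ratio", list(xs3), list(ys3))

    return CorrelationReport(pd.DataFrame(rows))
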