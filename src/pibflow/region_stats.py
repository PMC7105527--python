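"""Regional summaries, VSRAD-style z-scores, and voxelwise group inference.

Voxelwise two-sample comparisons follow the neuroimaging convention: a
pooled-variance t-map thresholded at the t-value whose upper-tail p equals
the height threshold (default p < 0.005, one-sided for decreases), then
connected-component (18-connectivity) cluster-extent filtering at 50
voxels. Cluster-level p-values, when requested, come from permutation of
group labels against the null distribution of the maximum cluster size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from pibflow.io_core import Parcellation, ParametricMap, require_same_grid


def regional_means(pmap: ParametricMap, parc: Parcellation) -> pd.DataFrame:
    """Unweighted mean of the map over each parcellation label.

    Returns a table with columns label, region, hemisphere, value,
    n_voxels; an empty label yields NaN with n_voxels = 0. Region names of
    the form ``<region>_r`` / ``<region>_l`` are split into region and
    hemisphere; others get hemisphere "both".
    """
    require_same_grid(pmap, parc)
    rows = []
    for label, name in sorted(parc.legend.items()):
        if label == 0:
            continue
        mask = parc.labels == label
        n = int(mask.sum())
        value = float(pmap.data[mask].mean()) if n else np.nan
        if name.endswith("_r"):
            region, hemi = name[:-2], "right"
        elif name.endswith("_l"):
            region, hemi = name[:-2], "left"
        else:
            region, hemi = name, "both"
        rows.append(
            {"label": label, "region": region, "hemisphere": hemi, "value": value, "n_voxels": n}
        )
    return pd.DataFrame(rows)


def vsrad_z(value: float | np.ndarray, control_mean: float, control_sd: float):
    """Atrophy-positive z-score: (control mean - individual) / control SD.

    Values *below* the control mean give positive z, so larger z means more
    atrophy relative to the control database.
    """
    if control_sd <= 0:
        raise ValueError("control SD must be positive")
    return (control_mean - np.asarray(value, dtype=float)) / control_sd


def group_compare_regions(
    table: pd.DataFrame,
    groups: dict[str, str] | pd.Series,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Regional AD-vs-CTL comparison of a long-format table.

    ``table`` has columns (subject, region, hemisphere, quantity, value);
    ``groups`` maps subject id to "AD" / "CTL". Per (quantity, region,
    hemisphere): group means +/- SD and a Welch two-sample t-test flagged
    at p < ``alpha``. A repeated-measures-style mixed ANOVA (region as
    within-subject factor, group as between) is run per quantity.
    """
    groups = dict(groups)
    df = table.copy()
    df["group"] = df["subject"].map(groups)
    if df["group"].isna().any():
        missing = sorted(df.loc[df["group"].isna(), "subject"].unique())
        raise ValueError(f"subjects without a group assignment: {missing}")
    for g in ("AD", "CTL"):
        if df[df["group"] == g]["subject"].nunique() < 2:
            raise ValueError(f"group {g} has fewer than 2 subjects")

    rows = []
    for (quantity, region, hemi), sub in df.groupby(["quantity", "region", "hemisphere"]):
        a = sub[sub["group"] == "AD"]["value"].to_numpy()
        c = sub[sub["group"] == "CTL"]["value"].to_numpy()
        if len(a) < 2 or len(c) < 2:
            continue
        if a.std(ddof=1) == 0 and c.std(ddof=1) == 0:
            # degenerate (e.g. the constant reference region): no evidence
            # of a difference when the constants agree
            t, p = (0.0, 1.0) if np.isclose(a.mean(), c.mean()) else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(a, c, equal_var=False)
        rows.append(
            {
                "quantity": quantity,
                "region": region,
                "hemisphere": hemi,
                "ad_mean": a.mean(),
                "ad_sd": a.std(ddof=1),
                "ctl_mean": c.mean(),
                "ctl_sd": c.std(ddof=1),
                "t": float(t),
                "p": float(p),
                "n_ad": len(a),
                "n_ctl": len(c),
                "significant": bool(p < alpha),
            }
        )
    regional = pd.DataFrame(rows)

    anova_rows = []
    for quantity, sub in df.groupby("quantity"):
        wide = sub.pivot_table(
            index="subject", columns=["region", "hemisphere"], values="value"
        ).dropna(axis=1, how="any")
        if wide.shape[1] < 2:
            continue
        try:
            import pingouin as pg

            long = wide.stack([0, 1], future_stack=True).rename("value").reset_index()
            long["roi"] = long["region"] + "_" + long["hemisphere"]
            long["group"] = long["subject"].map(groups)
            res = pg.mixed_anova(
                data=long, dv="value", within="roi", subject="subject", between="group"
            )
            grp = res[res["Source"] == "group"].iloc[0]
            anova_rows.append(
                {
                    "quantity": quantity,
                    "effect": "group",
                    "F": float(grp["F"]),
                    "p": float(grp["p-unc"]),
                    "significant": bool(grp["p-unc"] < alpha),
                }
            )
        except Exception as exc:  # pragma: no cover - degenerate designs
            anova_rows.append(
                {"quantity": quantity, "effect": "group", "F": np.nan, "p": np.nan,
                 "significant": False, "note": f"ANOVA unavailable: {exc}"}
            )
    return {"regional": regional, "anova": pd.DataFrame(anova_rows)}


@dataclass
class ClusterResult:
    """Voxelwise t-map with cluster-extent-thresholded components."""

    t_map: ParametricMap
    suprathreshold_mask: np.ndarray
    clusters: pd.DataFrame  # size_voxels, peak_i/j/k, peak_t [, cluster_p]
    t_threshold: float
    df: int


def _pooled_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sample pooled-variance t over axis 0 stacks (a minus b)."""
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (ma - mb) / denom, 0.0)


def voxelwise_ttest(
    maps_a: list[ParametricMap] | np.ndarray,
    maps_b: list[ParametricMap] | np.ndarray,
    mask: np.ndarray,
    height_p: float = 0.005,
    extent: int = 50,
    two_sided: bool = False,
    n_permutations: int = 0,
    seed: int = 0,
) -> ClusterResult:
    """Two-sample t contrast (A minus B) with cluster-extent thresholding.

    One-sided by default (suprathreshold where t >= t*), matching the
    reporting of group decreases only; ``two_sided=True`` thresholds |t|.
    Clusters are 18-connected components of the suprathreshold mask;
    components smaller than ``extent`` voxels are discarded. With
    ``n_permutations`` > 0, each surviving cluster gets a permutation
    cluster-level p (share of label permutations whose maximum cluster size
    reaches it).
    """
    stack_a, affine = _stack(maps_a)
    stack_b, _ = _stack(maps_b)
    if stack_a.shape[0] < 2 or stack_b.shape[0] < 2:
        raise ValueError("each group needs at least 2 maps")
    if stack_a.shape[1:] != stack_b.shape[1:]:
        raise ValueError("groups are on different grids")
    mask = np.asarray(mask, dtype=bool)

    na, nb = stack_a.shape[0], stack_b.shape[0]
    dof = na + nb - 2
    t_star = stats.t.isf(height_p if not two_sided else height_p / 2, dof)

    t_map = _pooled_t(stack_a, stack_b) * mask
    supra = (np.abs(t_map) >= t_star) if two_sided else (t_map >= t_star)
    supra &= mask

    structure = ndimage.generate_binary_structure(3, 2)  # 18-connectivity
    labeled, n_comp = ndimage.label(supra, structure=structure)
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n_comp + 1))

    kept_mask = np.zeros_like(supra)
    rows = []
    for comp, size in enumerate(sizes, start=1):
        if size < extent:
            continue
        comp_mask = labeled == comp
        kept_mask |= comp_mask
        tv = np.where(comp_mask, np.abs(t_map) if two_sided else t_map, -np.inf)
        peak = np.unravel_index(np.argmax(tv), t_map.shape)
        rows.append(
            {
                "size_voxels": int(size),
                "peak_i": int(peak[0]),
                "peak_j": int(peak[1]),
                "peak_k": int(peak[2]),
                "peak_t": float(t_map[peak]),
            }
        )
    clusters = pd.DataFrame(rows, columns=["size_voxels", "peak_i", "peak_j", "peak_k", "peak_t"])

    if n_permutations > 0 and not clusters.empty:
        null_max = _max_cluster_null(
            stack_a, stack_b, mask, t_star, two_sided, structure, n_permutations, seed
        )
        clusters["cluster_p"] = [
            float((null_max >= s).mean()) for s in clusters["size_voxels"]
        ]

    return ClusterResult(
        t_map=ParametricMap(t_map, affine, "t"),
        suprathreshold_mask=kept_mask,
        clusters=clusters,
        t_threshold=float(t_star),
        df=int(dof),
    )


def _stack(maps) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(maps, np.ndarray):
        return np.asarray(maps, dtype=float), np.eye(4)
    affine = maps[0].affine
    for m in maps[1:]:
        require_same_grid(maps[0], m)
    return np.stack([m.data for m in maps]), affine


def _max_cluster_null(
    stack_a, stack_b, mask, t_star, two_sided, structure, n_permutations, seed
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([stack_a, stack_b], axis=0)
    na = stack_a.shape[0]
    n = pooled.shape[0]
    out = np.empty(n_permutations)
    for p in range(n_permutations):
        perm = rng.permutation(n)
        t_map = _pooled_t(pooled[perm[:na]], pooled[perm[na:]]) * mask
        supra = (np.abs(t_map) >= t_star) if two_sided else (t_map >= t_star)
        supra &= mask
        labeled, n_comp = ndimage.label(supra, structure=structure)
        if n_comp == 0:
            out[p] = 0
        else:
            out[p] = ndimage.sum_labels(
                np.ones_like(labeled), labeled, index=np.arange(1, n_comp + 1)
            ).max()
    return out
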