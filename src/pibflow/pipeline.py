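"""End-to-end synthetic study: phantom -> IDIF -> CBF -> SUVr -> fALFF -> stats.

``run_study`` executes the stages in dependency order into an output
directory and writes a manifest (seed, configuration, per-stage outputs
with SHA-256 checksums); re-running with the same configuration and seed
reproduces the checksums bit for bit. ``make_report`` renders the manifest
into a deterministic markdown report with the study's regional tables,
correlation panel and cluster table.

Every stage draws its randomness from the single study seed via
numpy SeedSequence spawning; no stage uses unseeded random numbers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pibflow import __version__, phantom as ph
from pibflow.amyloid_uptake import (
    cortical_suvr_mean,
    score_correlations,
    suv_image,
    suvr_image,
    suvr_ratio,
)
from pibflow.falff import FalffConfig, falff_map, preprocess, zscore_map
from pibflow.input_function import (
    InputFunction,
    correct_dispersion,
    early_average,
    extract_idif_mask,
    idif_tac,
)
from pibflow.io_core import (
    default_schedule,
    read_dynamic,
    read_map,
    read_parcellation,
    read_subjects,
    write_dynamic,
    write_map,
    write_parcellation,
    write_subjects,
)
from pibflow.kinetic_cbf import KineticConfig, cbf_image
from pibflow.region_stats import (
    group_compare_regions,
    regional_means,
    voxelwise_ttest,
    vsrad_z,
)

STAGES = ("phantom", "idif", "cbf", "suvr", "falff", "stats")


@dataclass
class StudyConfig:
    """Configuration of a full synthetic study run.

    Numeric defaults are the pipeline constants: plasma fraction 0.95,
    dispersion 4 s, extraction 0.65, 30 IDIF voxels, 10-40 s early window,
    0-180 s fit window, discard 10 volumes, 0.01-0.08 Hz band, height
    p < 0.005, extent 50 voxels.
    """

    out_dir: str = "study_out"
    seed: int = 0
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    noise_scale: float = 0.2
    n_ad: int = 27
    n_ctl: int = 16
    # static-image acquisition stand-ins
    dose_mbq: float = 740.0
    weight_kg: float = 60.0
    # resting-state simulation
    bold_grid: tuple[int, int, int] = (12, 12, 14)
    bold_volumes: int = 201
    tr_s: float = 2.3
    bold_low_freq_amp: float = 1.0
    bold_broadband_amp: float = 0.6
    bold_deficit_scale: float = 0.45  # low-freq amplitude multiplier in the AD deficit block
    # statistics
    height_p: float = 0.005
    extent_voxels: int = 50
    n_permutations: int = 1000
    kinetic: KineticConfig = field(default_factory=KineticConfig)
    falff: FalffConfig = field(default_factory=FalffConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kin = KineticConfig(**raw.pop("kinetic", {}))
        fal = FalffConfig(**{k: tuple(v) if k == "band_hz" else v for k, v in raw.pop("falff", {}).items()})
        for key in ("grid_shape", "bold_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(kinetic=kin, falff=fal, **raw)

    def snapshot(self) -> dict:
        d = asdict(self)
        d["kinetic"]["k2_grid_per_min"] = [
            float(self.kinetic.k2_grid_per_min[0]),
            float(self.kinetic.k2_grid_per_min[-1]),
            int(self.kinetic.k2_grid_per_min.size),
        ]
        d["kinetic"].pop("weights", None)
        d["falff"].pop("nuisance_regressors", None)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _seeds(seed: int, n: int) -> list[int]:
    """Derive n child seeds (< 2**31) from the study seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


class StudyRunner:
    """Stage driver bound to one config and output directory."""

    def __init__(self, config: StudyConfig):
        self.cfg = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        (
            self.seed_phantom,
            self.seed_cohort,
            self.seed_bold,
            self.seed_perm,
        ) = _seeds(config.seed, 4)
        self.schedule = default_schedule()

    # -- stage implementations -------------------------------------------

    def stage_phantom(self) -> list[Path]:
        cfg = self.cfg
        outputs: list[Path] = []
        ctl_spec = ph.default_phantom_spec(
            group="CTL", grid_shape=cfg.grid_shape, noise_scale=cfg.noise_scale,
            seed=self.seed_phantom,
        )
        ad_spec = ph.default_phantom_spec(
            group="AD", grid_shape=cfg.grid_shape, noise_scale=cfg.noise_scale,
            seed=self.seed_phantom + 1,
        )
        dyn, truth = ph.make_dynamic_pet(ctl_spec, self.schedule)
        write_dynamic(dyn, self.out / "ctl_dynamic.nii.gz")
        outputs += [self.out / "ctl_dynamic.nii.gz", self.out / "ctl_dynamic.json"]
        write_parcellation(truth.parcellation, self.out / "parcellation.nii.gz")
        outputs += [self.out / "parcellation.nii.gz", self.out / "parcellation.json"]
        write_map(truth.true_k1_map, self.out / "true_k1.nii.gz")
        write_map(truth.true_cbf_map, self.out / "true_cbf.nii.gz")
        outputs += [self.out / "true_k1.nii.gz", self.out / "true_cbf.nii.gz"]
        truth.true_input.to_csv(self.out / "true_input.csv")
        outputs.append(self.out / "true_input.csv")

        for name, spec in (("ctl", ctl_spec), ("ad", ad_spec)):
            static, true_suvr = ph.make_late_static(
                spec, dose_mbq=cfg.dose_mbq, weight_kg=cfg.weight_kg
            )
            write_map(static, self.out / f"{name}_static.nii.gz")
            write_map(true_suvr, self.out / f"{name}_true_suvr.nii.gz")
            outputs += [self.out / f"{name}_static.nii.gz", self.out / f"{name}_true_suvr.nii.gz"]

        subjects, regional, extras = ph.generate_cohort(
            n_ad=cfg.n_ad, n_ctl=cfg.n_ctl, seed=self.seed_cohort
        )
        write_subjects(subjects, self.out / "subjects.csv")
        regional.to_csv(self.out / "cohort_regional.csv", index=False)
        extras.to_csv(self.out / "cohort_extras.csv", index=False)
        outputs += [
            self.out / "subjects.csv",
            self.out / "cohort_regional.csv",
            self.out / "cohort_extras.csv",
        ]
        return outputs

    def stage_idif(self) -> list[Path]:
        dyn = self._require_dynamic()
        parc = read_parcellation(self.out / "parcellation.nii.gz")
        early = early_average(dyn)
        write_map(early, self.out / "early_average.nii.gz")
        mask = extract_idif_mask(early, parc, label=parc.label_of("artery"))
        tac = idif_tac(dyn, mask)
        corrected = correct_dispersion(tac)
        corrected.to_csv(self.out / "input_function.csv")
        (self.out / "idif_mask.json").write_text(
            json.dumps({"voxels": [list(v) for v in mask]})
        )
        return [
            self.out / "early_average.nii.gz",
            self.out / "input_function.csv",
            self.out / "idif_mask.json",
        ]

    def stage_cbf(self) -> list[Path]:
        dyn = self._require_dynamic()
        parc = read_parcellation(self.out / "parcellation.nii.gz")
        if not (self.out / "input_function.csv").exists():
            raise FileNotFoundError(
                "stage 'cbf' needs input_function.csv; run the 'idif' stage first"
            )
        cp = InputFunction.from_csv(self.out / "input_function.csv")
        brain = (parc.labels > 0) & (parc.labels != parc.label_of("artery"))
        result = cbf_image(dyn, cp, self.cfg.kinetic, brain)
        write_map(result.k1_map, self.out / "k1.nii.gz")
        write_map(result.cbf_map, self.out / "cbf.nii.gz")
        table = regional_means(result.cbf_map, parc)
        truth = regional_means(read_map(self.out / "true_cbf.nii.gz", "CBF"), parc)
        table = table.merge(
            truth[["label", "value"]].rename(columns={"value": "true_cbf"}), on="label"
        )
        table["rel_err_pct"] = 100.0 * (table["value"] - table["true_cbf"]) / table["true_cbf"]
        table.to_csv(self.out / "cbf_regional.csv", index=False)
        return [self.out / "k1.nii.gz", self.out / "cbf.nii.gz", self.out / "cbf_regional.csv"]

    def stage_suvr(self) -> list[Path]:
        cfg = self.cfg
        parc = read_parcellation(self.out / "parcellation.nii.gz")
        ref_labels = [parc.label_of("cerebellum_r"), parc.label_of("cerebellum_l")]
        outputs: list[Path] = []
        rows = []
        for name in ("ctl", "ad"):
            static = read_map(self.out / f"{name}_static.nii.gz")
            suv = suv_image(static, cfg.dose_mbq, cfg.weight_kg)
            suvr = suvr_image(suv, parc, ref_labels)
            write_map(suvr, self.out / f"{name}_suvr.nii.gz")
            outputs.append(self.out / f"{name}_suvr.nii.gz")
            table = regional_means(suvr, parc)
            table.insert(0, "image", name)
            rows.append(table)
        pd.concat(rows).to_csv(self.out / "suvr_regional.csv", index=False)
        outputs.append(self.out / "suvr_regional.csv")

        # cohort-level uptake metrics and correlations
        subjects = read_subjects(self.out / "subjects.csv")
        regional = pd.read_csv(self.out / "cohort_regional.csv")
        lobes = list(ph.LOBES)
        cortical = {}
        ratios = {}
        for s in subjects:
            cortical[s.id] = cortical_suvr_mean(regional, s.id, lobes)
            sub = regional[
                (regional["subject"] == s.id) & (regional["quantity"] == "SUVr")
            ]
            wm = float(sub[sub["region"] == "white_matter"]["value"].iloc[0])
            ratios[s.id] = cortical[s.id] / wm
        metrics = pd.DataFrame(
            {
                "subject": list(cortical),
                "cortical_suvr": [cortical[k] for k in cortical],
                "suvr_ratio": [ratios[k] for k in cortical],
            }
        )
        metrics.to_csv(self.out / "uptake_metrics.csv", index=False)
        outputs.append(self.out / "uptake_metrics.csv")
        report = score_correlations(subjects, cortical, ratios)
        report.table.to_csv(self.out / "correlations.csv", index=False)
        outputs.append(self.out / "correlations.csv")
        return outputs

    def _deficit_block(self) -> tuple[slice, slice, slice]:
        """Planted fALFF-deficit block (>= extent_voxels voxels)."""
        nx, ny, nz = self.cfg.bold_grid
        return (slice(2, 7), slice(2, 7), slice(2, max(5, min(nz - 2, 6))))

    def stage_falff(self) -> list[Path]:
        cfg = self.cfg
        fal = FalffConfig(
            discard_volumes=cfg.falff.discard_volumes,
            band_hz=cfg.falff.band_hz,
            tr_s=cfg.tr_s,
            detrend=cfg.falff.detrend,
        )
        amp_ad = np.ones(cfg.bold_grid)
        amp_ad[self._deficit_block()] = cfg.bold_deficit_scale
        n_total = cfg.n_ctl + cfg.n_ad
        bold_seeds = _seeds(self.seed_bold, n_total)
        z_stacks = {"CTL": [], "AD": []}
        falff_means = {"CTL": [], "AD": []}
        mask = np.ones(cfg.bold_grid, dtype=bool)
        for i in range(n_total):
            group = "CTL" if i < cfg.n_ctl else "AD"
            series = ph.make_bold_series(
                grid_shape=cfg.bold_grid,
                n_volumes=cfg.bold_volumes,
                tr=cfg.tr_s,
                low_freq_amp=cfg.bold_low_freq_amp,
                broadband_amp=cfg.bold_broadband_amp,
                seed=bold_seeds[i],
                amp_map=None if group == "CTL" else amp_ad,
            )
            clean = preprocess(series.data, fal)
            _, fmap = falff_map(clean, fal)
            z = zscore_map(fmap, mask)
            z_stacks[group].append(z.data)
            falff_means[group].append(fmap.data)
        for group in ("CTL", "AD"):
            np.save(self.out / f"z_{group.lower()}.npy", np.stack(z_stacks[group]).astype(np.float32))
            mean_map = np.mean(falff_means[group], axis=0)
            from pibflow.io_core import ParametricMap

            write_map(ParametricMap(mean_map, np.eye(4), "fALFF"), self.out / f"falff_mean_{group.lower()}.nii.gz")
        return [
            self.out / "z_ctl.npy",
            self.out / "z_ad.npy",
            self.out / "falff_mean_ctl.nii.gz",
            self.out / "falff_mean_ad.nii.gz",
        ]

    def stage_stats(self) -> list[Path]:
        cfg = self.cfg
        subjects = read_subjects(self.out / "subjects.csv")
        groups = {s.id: s.group for s in subjects}
        regional = pd.read_csv(self.out / "cohort_regional.csv")
        res = group_compare_regions(regional, groups)
        res["regional"].to_csv(self.out / "group_regional_stats.csv", index=False)
        res["anova"].to_csv(self.out / "group_anova.csv", index=False)

        # VSRAD-style hippocampal z-scores against the emulated normative
        # database (VSRAD references an external normal cohort, not the
        # study controls)
        extras = pd.read_csv(self.out / "cohort_extras.csv")
        norm_mean, norm_sd = ph.NORMATIVE_HIPPO
        extras["vsrad_z"] = vsrad_z(
            extras["hippocampal_value"].to_numpy(), norm_mean, norm_sd
        )
        extras.to_csv(self.out / "vsrad_scores.csv", index=False)

        z_ctl = np.load(self.out / "z_ctl.npy")
        z_ad = np.load(self.out / "z_ad.npy")
        mask = np.ones(z_ctl.shape[1:], dtype=bool)
        cluster = voxelwise_ttest(
            z_ctl, z_ad, mask,
            height_p=cfg.height_p, extent=cfg.extent_voxels,
            n_permutations=cfg.n_permutations, seed=self.seed_perm,
        )
        from pibflow.io_core import ParametricMap  # local import to avoid cycle noise

        write_map(cluster.t_map, self.out / "tmap_ctl_gt_ad.nii.gz")
        cluster.clusters.to_csv(self.out / "clusters.csv", index=False)
        summary = {
            "t_threshold": cluster.t_threshold,
            "df": cluster.df,
            "n_clusters": int(len(cluster.clusters)),
            "suprathreshold_voxels": int(cluster.suprathreshold_mask.sum()),
        }
        (self.out / "cluster_summary.json").write_text(json.dumps(summary, indent=1))
        return [
            self.out / "group_regional_stats.csv",
            self.out / "group_anova.csv",
            self.out / "vsrad_scores.csv",
            self.out / "tmap_ctl_gt_ad.nii.gz",
            self.out / "clusters.csv",
            self.out / "cluster_summary.json",
        ]

    # -- helpers ----------------------------------------------------------

    def _require_dynamic(self):
        path = self.out / "ctl_dynamic.nii.gz"
        if not path.exists():
            raise FileNotFoundError(
                "stage needs ctl_dynamic.nii.gz; run the 'phantom' stage first"
            )
        return read_dynamic(path)

    def run_stage(self, name: str) -> list[Path]:
        fn = getattr(self, f"stage_{name}", None)
        if fn is None:
            raise ValueError(f"unknown stage {name!r}; choose from {STAGES}")
        return fn()


def run_study(config: StudyConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages in order and write the manifest."""
    runner = StudyRunner(config)
    manifest: dict = {
        "pibflow_version": __version__,
        "seed": config.seed,
        "config": config.snapshot(),
        "stages": {},
    }
    for stage in stages:
        outputs = runner.run_stage(stage)
        manifest["stages"][stage] = {
            str(p.relative_to(runner.out)): _sha256(p) for p in outputs
        }
    path = runner.out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def make_report(out_dir: str | Path, report_name: str = "report.md") -> Path:
    """Render the study outputs into a deterministic markdown report.

    Regenerating from an unchanged output directory is byte-identical;
    missing stage outputs are reported as gaps rather than errors.
    """
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    lines = ["# Synthetic PiB-PET/MRI study report", ""]
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines += [f"Seed: {manifest['seed']}  ", f"Pipeline version: {manifest['pibflow_version']}", ""]
    else:
        lines += ["(no manifest found)", ""]

    def fmt(x: float, nd=2) -> str:
        return f"{x:.{nd}f}"

    gaps = []

    subj_path = out / "subjects.csv"
    if subj_path.exists():
        df = pd.read_csv(subj_path)
        lines.append("## Cohort")
        lines.append("")
        lines.append("| group | n | MMSE mean +/- SD |")
        lines.append("|---|---|---|")
        for g, sub in df.groupby("group"):
            lines.append(f"| {g} | {len(sub)} | {fmt(sub['mmse'].mean())} +/- {fmt(sub['mmse'].std(ddof=1))} |")
        lines.append("")
    else:
        gaps.append("cohort")

    stats_path = out / "group_regional_stats.csv"
    if stats_path.exists():
        st = pd.read_csv(stats_path)
        for quantity in ("CBF", "SUVr"):
            sub = st[(st["quantity"] == quantity) & st["hemisphere"].isin(["right", "left"])]
            if sub.empty:
                continue
            lines.append(f"## Regional {quantity} by group (mean +/- SD)")
            lines.append("")
            lines.append("| region | CTL right | CTL left | AD right | AD left | p(R) | p(L) |")
            lines.append("|---|---|---|---|---|---|---|")
            for region in ["frontal", "temporal", "parietal", "occipital", "cerebellum"]:
                r = {h: sub[(sub["region"] == region) & (sub["hemisphere"] == h)] for h in ("right", "left")}
                if r["right"].empty or r["left"].empty:
                    continue
                rr, rl = r["right"].iloc[0], r["left"].iloc[0]
                star = lambda p: "*" if p < 0.05 else ""  # noqa: E731
                lines.append(
                    f"| {region} | {fmt(rr['ctl_mean'])} +/- {fmt(rr['ctl_sd'])} "
                    f"| {fmt(rl['ctl_mean'])} +/- {fmt(rl['ctl_sd'])} "
                    f"| {fmt(rr['ad_mean'])} +/- {fmt(rr['ad_sd'])}{star(rr['p'])} "
                    f"| {fmt(rl['ad_mean'])} +/- {fmt(rl['ad_sd'])}{star(rl['p'])} "
                    f"| {rr['p']:.4g} | {rl['p']:.4g} |"
                )
            lines.append("")
    else:
        gaps.append("group statistics")

    corr_path = out / "correlations.csv"
    if corr_path.exists():
        corr = pd.read_csv(corr_path)
        lines.append("## Uptake-cognition correlations")
        lines.append("")
        lines.append("| pair | r | p | n |")
        lines.append("|---|---|---|---|")
        for _, row in corr.iterrows():
            lines.append(f"| {row['pair']} | {row['r']:.3f} | {row['p']:.3g} | {int(row['n'])} |")
        lines.append("")
    else:
        gaps.append("correlations")

    cbf_path = out / "cbf_regional.csv"
    if cbf_path.exists():
        cbf = pd.read_csv(cbf_path)
        cbf = cbf[cbf["region"] != "artery"]
        lines.append("## CBF recovery on the noisy control phantom")
        lines.append("")
        lines.append("| region | hemisphere | true CBF | estimated | rel. err (%) |")
        lines.append("|---|---|---|---|---|")
        for _, row in cbf.iterrows():
            lines.append(
                f"| {row['region']} | {row['hemisphere']} | {fmt(row['true_cbf'], 1)} "
                f"| {fmt(row['value'])} | {fmt(row['rel_err_pct'])} |"
            )
        lines.append("")
    else:
        gaps.append("CBF recovery")

    clus_path = out / "clusters.csv"
    if clus_path.exists():
        clus = pd.read_csv(clus_path)
        lines.append("## fALFF clusters (CTL > AD)")
        lines.append("")
        if clus.empty:
            lines.append("No suprathreshold cluster survived the extent threshold.")
        else:
            cols = list(clus.columns)
            lines.append("| " + " | ".join(cols) + " |")
            lines.append("|" + "---|" * len(cols))
            for _, row in clus.iterrows():
                lines.append("| " + " | ".join(
                    f"{row[c]:.4g}" if isinstance(row[c], float) else str(row[c]) for c in cols
                ) + " |")
        lines.append("")
    else:
        gaps.append("clusters")

    if gaps:
        lines.append("## Gaps")
        lines.append("")
        for g in gaps:
            lines.append(f"- missing stage output: {g}")
        lines.append("")

    report_path = out / report_name
    report_path.write_text("\n".join(lines))
    return report_path
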