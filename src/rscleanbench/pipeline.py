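"""End-to-end benchmark: simulate -> preprocess -> decompose -> clean ->
connectivity -> evaluation -> group statistics.

The library entry point is :func:`analyze_cohort`, which runs every subject
through the shared preprocessing, the requested cleanup variants and both
connectivity estimators, keeping only per-subject summary images and
scalars. :func:`run_full_benchmark` wraps it with group-level statistics
and writes the report tables (TSV) and maps (NIfTI) to an output
directory; rerunning with the same configuration reproduces the TSVs
bit-identically.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cleaning import CleanupMode, clean, expand_motion_24
from .connectivity import dual_regression, seed_fc_zmap, select_dmn_map
from .ica import IcaConvergenceError, label_by_ground_truth, label_by_rules, spatial_ica
from .metrics import consistency_map, delta_std_map, exceedance_probability_map, paired_t_over_voxels, temporal_snr
from .preprocess import PreprocessConfig, preprocess_subject
from .simulate import CohortDataset, ConfigurationError, GroundTruth, SimulationConfig, generate_cohort
from .stats import SummaryStats, build_group_gm_mask, cluster_correct, permutation_group_glm, roi_mean_pe, two_sample_t_summary

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "CohortAnalysis", "analyze_cohort", "run_full_benchmark"]

ALL_MODES = ["none", "motreg", "mwcreg", "compsoft", "compagg"]
ALL_METHODS = ["seed", "dualreg"]

DEFAULT_N_COMPONENTS = 16


def _ica_with_fallback(data, brain_mask, n_components, seed):
    """Decompose robustly: relax the FastICA tolerance at the requested
    model order first, and only then step the order down. Dropping
    components is the last resort because an under-decomposed subject can
    leave whole artifact sources in the data."""
    k = DEFAULT_N_COMPONENTS if n_components is None else n_components
    if k == "auto":
        candidates = [(k, 1e-3), (k, 5e-3)]
    else:
        candidates = [(k, 1e-3), (k, 5e-3), (max(k - 4, 4), 1e-3), (max(k - 8, 4), 5e-3)]
    last = None
    for kk, tol in candidates:
        try:
            return spatial_ica(data, brain_mask, n_components=kk, seed=seed, tol=tol)
        except IcaConvergenceError as exc:  # pragma: no cover - data dependent
            logger.warning("ICA at k=%s (tol=%g) failed to converge; relaxing", kk, tol)
            last = exc
    raise last


@dataclass
class RunConfig:
    """Full benchmark configuration; loss-lessly (de)serialisable to YAML."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cleanup_modes: list[str] = field(default_factory=lambda: list(ALL_MODES))
    fc_methods: list[str] = field(default_factory=lambda: list(ALL_METHODS))
    n_perm: int = 1000
    primary_p: float = 0.05
    erosion_iters: int = 2
    delta_std_threshold_pct: float = 25.0
    gm_threshold_fraction: float = 0.20
    n_components: int | str = DEFAULT_N_COMPONENTS
    seed: int = 0
    out_dir: str = "benchmark_out"

    def __post_init__(self) -> None:
        for m in self.cleanup_modes:
            try:
                CleanupMode(m)
            except ValueError as exc:
                raise ConfigurationError(f"unknown cleanup mode {m!r}") from exc
        for m in self.fc_methods:
            if m not in ALL_METHODS:
                raise ConfigurationError(f"unknown FC method {m!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "simulation" in d:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "preprocess" in d:
            d["preprocess"] = PreprocessConfig(**d["preprocess"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class CohortAnalysis:
    """Per-subject summaries retained from a cohort run.

    Map stacks are arrays of shape ``(n_subjects, x, y, z)`` keyed by
    cleanup mode (and FC method where relevant).
    """

    subject_ids: list[str]
    groups: list[str]
    gm_volumes: np.ndarray
    masks: object
    dmn_index: int
    tsnr: pd.DataFrame  # columns: subject_id, group, mode, median_tsnr
    temporal_variance: dict[str, np.ndarray]  # mode -> (S, x, y, z)
    delta_std: dict[str, np.ndarray]  # mode (cleaned only) -> (S, x, y, z)
    fc_maps: dict[tuple[str, str], np.ndarray]  # (method, mode) -> (S, x, y, z)
    roi_pe: pd.DataFrame  # subject_id, group, method, mode, roi_mean
    label_agreement: float | None = None


def analyze_cohort(
    cohort: CohortDataset,
    truth: GroundTruth | None,
    preproc: PreprocessConfig | None = None,
    tr_s: float = 2.5,
    modes: list[str] | None = None,
    methods: list[str] | None = None,
    erosion_iters: int = 2,
    n_components: int | str | None = None,
    ica_seed: int = 0,
    templates: np.ndarray | None = None,
    dmn_index: int | None = None,
    compare_labelers: bool = False,
) -> CohortAnalysis:
    """Run preprocessing, cleanup variants and FC estimation per subject.

    In simulation mode ``truth`` supplies the dual-regression templates,
    the DMN index and the oracle component labels; with ``truth=None``,
    ``templates``/``dmn_index`` must be given and components are labeled by
    the rule-based classifier.
    """
    preproc = preproc or PreprocessConfig()
    modes = list(modes or ALL_MODES)
    methods = list(methods or ALL_METHODS)
    masks = cohort.masks
    if truth is not None:
        templates = truth.template_maps if templates is None else templates
        dmn_index = truth.dmn_index if dmn_index is None else dmn_index
    if "dualreg" in methods and (templates is None or dmn_index is None):
        raise ValueError("dual regression needs templates and a DMN index")

    S = len(cohort.subjects)
    grid = cohort.grid_shape
    need_ica = any(m in ("compsoft", "compagg") for m in modes)

    tsnr_rows, roi_rows = [], []
    var_stacks = {m: np.empty((S,) + grid) for m in modes}
    dstd_stacks = {m: np.empty((S,) + grid) for m in modes if m != "none"}
    fc_stacks = {(meth, m): np.empty((S,) + grid) for meth in methods for m in modes}
    agreements = []

    for i, subj in enumerate(cohort.subjects):
        t0 = time.perf_counter()
        pre = preprocess_subject(subj.data, preproc, cohort.voxel_size_mm, tr_s)
        decomp = None
        if need_ica:
            decomp = _ica_with_fallback(
                pre, masks.brain, n_components, seed=ica_seed + 7919 * i
            )
            if truth is not None:
                label_by_ground_truth(decomp, truth)
                if compare_labelers:
                    gt = list(decomp.labels)
                    rules = label_by_rules(decomp, masks, expand_motion_24(subj.motion6), tr_s=tr_s)
                    # "unlabeled" is treated as signal downstream
                    gt_eff = ["noise" if l == "noise" else "signal" for l in gt]
                    agreements.append(np.mean([a == b for a, b in zip(gt_eff, rules)]))
                    decomp.labels = gt
            else:
                label_by_rules(decomp, masks, expand_motion_24(subj.motion6), tr_s=tr_s)

        for mode in modes:
            cleaned = clean(pre, subj.motion6, masks, decomp, mode)
            var_stacks[mode][i] = cleaned.var(axis=-1, ddof=1)
            res = temporal_snr(cleaned, masks.brain, erosion_iters)
            tsnr_rows.append(
                {
                    "subject_id": subj.subject_id,
                    "group": subj.group,
                    "mode": mode,
                    "median_tsnr": res.median_tsnr,
                }
            )
            if mode != "none":
                dstd_stacks[mode][i] = delta_std_map(pre, cleaned, subj.subject_id, mode).values
            if "seed" in methods:
                z = seed_fc_zmap(cleaned, masks.seed_sphere, masks.brain, subj.subject_id)
                fc_stacks[("seed", mode)][i] = z.values
                roi_rows.append(
                    {
                        "subject_id": subj.subject_id,
                        "group": subj.group,
                        "method": "seed",
                        "mode": mode,
                        "roi_mean": roi_mean_pe(z, masks.posterior_roi),
                    }
                )
            if "dualreg" in methods:
                _, pe = dual_regression(cleaned, templates, masks.brain)
                dmn_pe = select_dmn_map(pe, dmn_index, subj.subject_id)
                fc_stacks[("dualreg", mode)][i] = dmn_pe.values
                roi_rows.append(
                    {
                        "subject_id": subj.subject_id,
                        "group": subj.group,
                        "method": "dualreg",
                        "mode": mode,
                        "roi_mean": roi_mean_pe(dmn_pe, masks.posterior_roi),
                    }
                )
        logger.debug("subject %s analysed in %.2fs", subj.subject_id, time.perf_counter() - t0)

    return CohortAnalysis(
        subject_ids=[s.subject_id for s in cohort.subjects],
        groups=[s.group for s in cohort.subjects],
        gm_volumes=np.array([s.gm_volume for s in cohort.subjects]),
        masks=masks,
        dmn_index=dmn_index if dmn_index is not None else -1,
        tsnr=pd.DataFrame(tsnr_rows),
        temporal_variance=var_stacks,
        delta_std=dstd_stacks,
        fc_maps=fc_stacks,
        roi_pe=pd.DataFrame(roi_rows),
        label_agreement=float(np.mean(agreements)) if agreements else None,
    )


def roi_group_table(analysis: CohortAnalysis) -> pd.DataFrame:
    """Table-shaped ROI statistics: per (method, mode), group means/SDs and
    the pooled two-sample t for HC - AD."""
    rows = []
    df = analysis.roi_pe
    for (method, mode), sub in df.groupby(["method", "mode"], sort=False):
        hc = sub[sub.group == "HC"]["roi_mean"]
        ad = sub[sub.group == "AD"]["roi_mean"]
        t, dof, p = two_sample_t_summary(
            SummaryStats(hc.mean(), hc.std(ddof=1), len(hc)),
            SummaryStats(ad.mean(), ad.std(ddof=1), len(ad)),
        )
        rows.append(
            {
                "method": method,
                "mode": mode,
                "hc_mean": hc.mean(),
                "hc_sd": hc.std(ddof=1),
                "hc_n": len(hc),
                "ad_mean": ad.mean(),
                "ad_sd": ad.std(ddof=1),
                "ad_n": len(ad),
                "t": t,
                "df": dof,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def run_full_benchmark(config: RunConfig) -> dict:
    """Run the whole comparison and write the report bundle.

    Produces per (cleanup x FC method): median tSNR per subject, %dSTD
    exceedance maps per group, consistency maps with paired-t comparisons
    against uncleaned, a ROI statistics table, and permutation cluster
    tables, all under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, truth = generate_cohort(config.simulation)
    analysis = analyze_cohort(
        cohort,
        truth,
        preproc=config.preprocess,
        tr_s=config.simulation.tr_s,
        modes=config.cleanup_modes,
        methods=config.fc_methods,
        erosion_iters=config.erosion_iters,
        n_components=config.n_components,
        ica_seed=config.seed,
    )
    affine = cohort.affine
    masks = cohort.masks
    groups = np.asarray(analysis.groups)

    analysis.tsnr.to_csv(out / "tsnr.tsv", sep="\t", index=False, float_format="%.6g")
    roi_table = roi_group_table(analysis)
    roi_table.to_csv(out / "roi_stats.tsv", sep="\t", index=False, float_format="%.6g")

    from .io import save_map  # local import to keep nibabel optional at import time

    # %dSTD exceedance probability maps per group and mode
    for mode, stack in analysis.delta_std.items():
        for grp in ("HC", "AD"):
            sel = stack[groups == grp]
            pmap = exceedance_probability_map(list(sel), config.delta_std_threshold_pct)
            save_map(pmap, affine, out / f"exceedance_{mode}_{grp}.nii")

    # within-group consistency + paired t vs uncleaned
    cons_rows = []
    for (method, mode), stack in analysis.fc_maps.items():
        for grp in ("HC", "AD"):
            cm = consistency_map(list(stack[groups == grp]), masks.brain, grp, method, mode)
            save_map(cm.values, affine, out / f"consistency_{method}_{mode}_{grp}.nii")
            row = {
                "method": method,
                "mode": mode,
                "group": grp,
                "mean_sd": float(cm.values[masks.brain].mean()),
            }
            if mode != "none" and "none" in config.cleanup_modes:
                base = consistency_map(
                    list(analysis.fc_maps[(method, "none")][groups == grp]), masks.brain, grp, method, "none"
                )
                t, dof, p = paired_t_over_voxels(base.values, cm.values, masks.brain)
                row.update({"paired_t_vs_uncleaned": t, "paired_df": dof, "paired_p": p})
            cons_rows.append(row)
    pd.DataFrame(cons_rows).to_csv(out / "consistency.tsv", sep="\t", index=False, float_format="%.6g")

    # voxelwise permutation GLM with GM covariate, cluster corrected
    gm_mask = build_group_gm_mask(
        [masks.gm.astype(float)] * len(analysis.subject_ids), config.gm_threshold_fraction
    )
    cluster_rows = []
    for (method, mode), stack in analysis.fc_maps.items():
        result = permutation_group_glm(
            list(stack),
            analysis.groups,
            analysis.gm_volumes,
            gm_mask,
            n_perm=config.n_perm,
            seed=config.seed,
            positive_group="HC",
        )
        result = cluster_correct(result, primary_p=config.primary_p)
        save_map(result.t_map, affine, out / f"tmap_{method}_{mode}.nii")
        for row in result.cluster_table:
            cluster_rows.append({"method": method, "mode": mode, **{k: v for k, v in row.items()}})
    cols = ["method", "mode", "cluster_id", "size_voxels", "corrected_p", "peak", "peak_t", "significant"]
    pd.DataFrame(cluster_rows, columns=cols).to_csv(
        out / "clusters.tsv", sep="\t", index=False, float_format="%.6g"
    )

    config.to_yaml(out / "run_config.yaml")
    return {
        "analysis": analysis,
        "roi_table": roi_table,
        "consistency": pd.DataFrame(cons_rows),
        "clusters": pd.DataFrame(cluster_rows, columns=cols),
        "out_dir": str(out),
    }
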