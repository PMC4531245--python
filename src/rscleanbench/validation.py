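"""Replicate-cohort experiments: detection power and permutation calibration.

These harnesses drive the package's own components over many simulated
cohorts. They are used by the test suite and the acceptance script, and
are part of the public API so users can rerun the calibration at other
settings.

Problem sizes: the power experiment runs cohorts at a reduced grid
(20 x 24 x 18 voxels, 120 volumes) with the full 20 + 21 subjects, the
default artifact amplitudes and the default planted deficit -- small
enough that 50 replicates complete on one CPU in a few minutes while the
ICA separation of the planted sources still succeeds. The permutation
calibration uses direct map-level null cohorts (i.i.d. Gaussian statistic
maps, group-dependent covariate), which is the regime where the
Freedman-Lane permutation test's validity can be measured exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cleaning import clean
from .connectivity import dual_regression
from .ica import label_by_ground_truth
from .pipeline import _ica_with_fallback
from .preprocess import PreprocessConfig, preprocess_subject
from .simulate import SimulationConfig, generate_cohort
from .stats import (
    SummaryStats,
    cluster_correct,
    permutation_group_glm,
    roi_mean_pe,
    two_sample_t_summary,
)

logger = logging.getLogger(__name__)

__all__ = [
    "power_config",
    "roi_power_experiment",
    "PowerResult",
    "CalibrationResult",
    "permutation_calibration",
    "binomial_interval",
]

POWER_GRID = (20, 24, 18)
POWER_VOLUMES = 120
POWER_COMPONENTS = 16


def power_config(seed: int, **overrides) -> SimulationConfig:
    """Reduced-size cohort configuration used for replicate experiments."""
    kwargs = dict(grid_shape=POWER_GRID, n_volumes=POWER_VOLUMES, random_seed=seed)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@dataclass
class PowerResult:
    power: dict[str, float]  # mode -> fraction of cohorts with p < alpha
    t_values: dict[str, np.ndarray]
    n_cohorts: int
    alpha: float


def roi_power_experiment(
    n_cohorts: int = 50,
    seed: int = 0,
    modes: tuple[str, ...] = ("none", "compsoft", "compagg"),
    alpha: float = 0.05,
    config_overrides: dict | None = None,
) -> PowerResult:
    """Power of the posterior-ROI two-sample test under each cleanup.

    For each replicate cohort every subject is preprocessed, decomposed,
    cleaned and passed through template-based dual regression; the DMN
    parameter estimates averaged over the posterior ROI are compared
    between groups with the pooled two-sample t-test. Power counts
    one-sided detections (HC > AD at two-tailed ``alpha``), matching the
    planted direction of the deficit.
    """
    t_values = {m: np.empty(n_cohorts) for m in modes}
    need_ica = any(m in ("compsoft", "compagg") for m in modes)
    for rep in range(n_cohorts):
        cfg = power_config(seed + 1000 + rep, **(config_overrides or {}))
        cohort, truth = generate_cohort(cfg)
        masks = cohort.masks
        pe_by_mode: dict[str, dict[str, list[float]]] = {m: {"HC": [], "AD": []} for m in modes}
        for i, subj in enumerate(cohort.subjects):
            pre = preprocess_subject(subj.data, PreprocessConfig(), cfg.voxel_size_mm, cfg.tr_s)
            decomp = None
            if need_ica:
                decomp = _ica_with_fallback(
                    pre, masks.brain, POWER_COMPONENTS, seed=seed + 7919 * i + rep
                )
                label_by_ground_truth(decomp, truth)
            for mode in modes:
                cleaned = clean(pre, subj.motion6, masks, decomp, mode)
                _, pe = dual_regression(cleaned, truth.template_maps, masks.brain)
                pe_by_mode[mode][subj.group].append(
                    roi_mean_pe(pe[truth.dmn_index], masks.posterior_roi)
                )
        for mode in modes:
            hc = np.asarray(pe_by_mode[mode]["HC"])
            ad = np.asarray(pe_by_mode[mode]["AD"])
            t, _, _ = two_sample_t_summary(
                SummaryStats(hc.mean(), hc.std(ddof=1), hc.size),
                SummaryStats(ad.mean(), ad.std(ddof=1), ad.size),
            )
            t_values[mode][rep] = t
        logger.debug("power replicate %d done", rep)

    from scipy import stats as sps

    df = cfg.n_hc + cfg.n_ad - 2
    crit = sps.t.isf(alpha / 2.0, df)
    power = {m: float((t_values[m] > crit).mean()) for m in modes}
    return PowerResult(power=power, t_values=t_values, n_cohorts=n_cohorts, alpha=alpha)


@dataclass
class CalibrationResult:
    voxel_rejection_rate: float
    voxel_interval: tuple[float, float]
    fwer: float
    fwer_interval: tuple[float, float]
    n_cohorts: int
    n_voxel_tests: int
    alpha: float


def binomial_interval(p: float, n: int) -> tuple[float, float]:
    """Central 95% normal-approximation interval for a binomial proportion."""
    half = 1.96 * np.sqrt(p * (1.0 - p) / n)
    return (p - half, p + half)


def permutation_calibration(
    n_cohorts: int = 200,
    seed: int = 0,
    shape: tuple[int, int, int] = (6, 8, 5),
    n_hc: int = 20,
    n_ad: int = 21,
    n_perm: int = 199,
    alpha: float = 0.05,
) -> CalibrationResult:
    """Type-I error of the permutation GLM under the null.

    Each null cohort consists of i.i.d. Gaussian statistic maps with a
    group-dependent covariate (so the Freedman-Lane adjustment is actually
    exercised) and no group effect. Measures the voxel-level rejection
    rate at ``p <= alpha`` and the family-wise error rate of the
    cluster-extent correction (any cluster with corrected p < alpha),
    together with the 95% binomial intervals around the nominal level.
    """
    rng = np.random.default_rng(seed)
    mask = np.ones(shape, dtype=bool)
    labels = ["HC"] * n_hc + ["AD"] * n_ad
    n = n_hc + n_ad
    rejections = 0
    voxel_tests = 0
    fw_errors = 0
    for rep in range(n_cohorts):
        maps = [rng.normal(size=shape) for _ in range(n)]
        cov = np.where(
            np.arange(n) < n_hc, rng.normal(0.62, 0.03, n), rng.normal(0.55, 0.04, n)
        )
        res = permutation_group_glm(
            maps, labels, cov, mask, n_perm=n_perm, seed=int(rng.integers(2**31 - 1))
        )
        rejections += int((res.uncorrected_p_map[mask] <= alpha).sum())
        voxel_tests += int(mask.sum())
        corrected = cluster_correct(res, primary_p=alpha)
        fw_errors += int(any(row["corrected_p"] < alpha for row in corrected.cluster_table))
    rate = rejections / voxel_tests
    fwer = fw_errors / n_cohorts
    return CalibrationResult(
        voxel_rejection_rate=float(rate),
        voxel_interval=binomial_interval(alpha, voxel_tests),
        fwer=float(fwer),
        fwer_interval=binomial_interval(alpha, n_cohorts),
        n_cohorts=n_cohorts,
        n_voxel_tests=voxel_tests,
        alpha=alpha,
    )
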