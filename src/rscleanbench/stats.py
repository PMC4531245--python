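"""Between-group inference.

ROI-level two-sample pooled-variance t-tests (including a summary-statistic
form that works from printed group means/SDs), a voxelwise permutation GLM
with a nuisance covariate (Freedman-Lane residual permutation), and
cluster-based multiple-comparison correction using the permutation null
distribution of the maximum supra-threshold cluster extent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "SummaryStats",
    "GroupComparisonResult",
    "two_sample_t_summary",
    "roi_mean_pe",
    "build_group_gm_mask",
    "permutation_group_glm",
    "cluster_correct",
]


@dataclass
class SummaryStats:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def two_sample_t_summary(a: SummaryStats, b: SummaryStats) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test from group summary statistics.

    ``t = (a.mean - b.mean) / (s_p * sqrt(1/n_a + 1/n_b))`` with the pooled
    variance ``s_p^2 = ((n_a-1) a.sd^2 + (n_b-1) b.sd^2) / (n_a+n_b-2)``.
    """
    if a.sd == 0 and b.sd == 0:
        raise ValueError("both groups have zero variance")
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    t = (a.mean - b.mean) / np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)


def roi_mean_pe(stat_map, roi_mask: np.ndarray) -> float:
    """Arithmetic mean of a statistic image over the ROI voxels."""
    values = getattr(stat_map, "values", stat_map)
    roi = roi_mask.astype(bool)
    if not roi.any():
        raise ValueError("empty ROI")
    return float(np.asarray(values)[roi].mean())


def build_group_gm_mask(gm_probability_maps: list, threshold_fraction: float = 0.20) -> np.ndarray:
    """Average per-subject GM probability maps and threshold.

    A voxel is kept when the across-subject mean probability is at least
    ``threshold_fraction``.
    """
    if not gm_probability_maps:
        raise ValueError("need at least one map")
    mean = np.mean([np.asarray(m, dtype=float) for m in gm_probability_maps], axis=0)
    mask = mean >= threshold_fraction
    if not mask.any():
        raise ValueError("group GM mask is empty")
    return mask


@dataclass
class GroupComparisonResult:
    t_map: np.ndarray
    uncorrected_p_map: np.ndarray
    cluster_table: list[dict]
    mask: np.ndarray
    n_permutations: int
    seed: int
    df: int
    positive_group: str
    # retained so cluster correction can re-run the permutation engine
    _Y: np.ndarray = field(repr=False, default=None)
    _X: np.ndarray = field(repr=False, default=None)
    _Z: np.ndarray = field(repr=False, default=None)


def _design(group_labels, covariate, positive_group):
    labels = np.asarray(group_labels)
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {uniq}")
    for u in uniq:
        if (labels == u).sum() < 2:
            raise ValueError(f"group {u!r} has fewer than two subjects")
    if positive_group is None:
        positive_group = uniq[0]
    g = (labels == positive_group).astype(float)
    n = labels.size
    X = [np.ones(n), g - g.mean()]
    Z = [np.ones(n)]
    if covariate is not None:
        c = np.asarray(covariate, dtype=float)
        if c.shape != (n,):
            raise ValueError("covariate length mismatch")
        # drop a covariate that is (nearly) explained by intercept + group
        A = np.column_stack([np.ones(n), g])
        resid = c - A @ np.linalg.lstsq(A, c, rcond=None)[0]
        if resid.std() < 1e-10 * max(c.std(), 1.0) or c.std() < 1e-12:
            warnings.warn(
                "covariate is collinear with the group model and was dropped", RuntimeWarning
            )
        else:
            cc = c - c.mean()
            X.append(cc)
            Z.append(cc)
    return np.column_stack(X), np.column_stack(Z), positive_group


def _t_for_group(Y: np.ndarray, X: np.ndarray, xtx_inv: np.ndarray, pinv: np.ndarray) -> np.ndarray:
    """t statistics for the group column (index 1). Y is (n, V)."""
    n, p = X.shape
    beta = pinv @ Y  # (p, V)
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 1e-300))
    return beta[1] / se


def permutation_group_glm(
    maps: list,
    group_labels,
    covariate,
    mask: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    positive_group: str | None = None,
) -> GroupComparisonResult:
    """Voxelwise group-difference test with Freedman-Lane permutation.

    Model per voxel: ``y = b0 + b1 * group + b2 * covariate``; the observed
    t for the group effect is referred to a null built by permuting the
    residuals of the reduced (covariate-only) model. Uncorrected p-values
    are ``(1 + #{|t*| >= |t|}) / (1 + n_perm)``. Positive t means
    ``positive_group`` larger (default: first group label in sorted order).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    mask = mask.astype(bool)
    Y = np.stack([np.asarray(getattr(m, "values", m))[mask] for m in maps], axis=0)
    X, Z, positive_group = _design(group_labels, covariate, positive_group)
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    pinv = xtx_inv @ X.T

    t_obs = _t_for_group(Y, X, xtx_inv, pinv)

    gamma = np.linalg.lstsq(Z, Y, rcond=None)[0]
    fitted = Z @ gamma
    R = Y - fitted

    rng = np.random.default_rng(seed)
    exceed = np.ones(Y.shape[1])  # counts the identity permutation
    abs_obs = np.abs(t_obs)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        t_star = _t_for_group(fitted + R[perm], X, xtx_inv, pinv)
        exceed += np.abs(t_star) >= abs_obs
    p_unc = exceed / (1.0 + n_perm)

    t_map = np.zeros(mask.shape)
    t_map[mask] = t_obs
    p_map = np.ones(mask.shape)
    p_map[mask] = p_unc
    return GroupComparisonResult(
        t_map=t_map,
        uncorrected_p_map=p_map,
        cluster_table=[],
        mask=mask,
        n_permutations=n_perm,
        seed=seed,
        df=n - p,
        positive_group=positive_group,
        _Y=Y,
        _X=X,
        _Z=Z,
    )


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def _cluster_sizes(supra: np.ndarray) -> tuple[np.ndarray, int, np.ndarray]:
    labels, n = ndimage.label(supra, structure=_CONN26)
    if n == 0:
        return labels, 0, np.zeros(0, dtype=int)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1)).astype(int)
    return labels, n, sizes


def cluster_correct(
    result: GroupComparisonResult,
    primary_p: float = 0.05,
    n_perm: int | None = None,
    seed: int | None = None,
) -> GroupComparisonResult:
    """Cluster-extent correction against the permutation max-size null.

    Clusters are 26-connected groups of voxels whose |t| exceeds the
    two-tailed critical value at ``primary_p``; the corrected p of an
    observed cluster is ``(1 + #{max-size* >= size}) / (1 + n_perm)``.
    """
    if result._Y is None:
        raise ValueError("result does not carry the data needed for permutation")
    n_perm = result.n_permutations if n_perm is None else n_perm
    seed = result.seed if seed is None else seed
    t_crit = sps.t.isf(primary_p / 2.0, result.df)

    mask = result.mask
    supra_obs = np.zeros(mask.shape, dtype=bool)
    supra_obs[mask] = np.abs(result.t_map[mask]) > t_crit
    labels, n_clusters, sizes = _cluster_sizes(supra_obs)

    Y, X, Z = result._Y, result._X, result._Z
    n = X.shape[0]
    xtx_inv = np.linalg.inv(X.T @ X)
    pinv = xtx_inv @ X.T
    gamma = np.linalg.lstsq(Z, Y, rcond=None)[0]
    fitted = Z @ gamma
    R = Y - fitted

    rng = np.random.default_rng(seed)
    max_sizes = np.empty(n_perm + 1, dtype=int)
    max_sizes[0] = sizes.max() if sizes.size else 0  # identity permutation
    supra = np.zeros(mask.shape, dtype=bool)
    for i in range(n_perm):
        perm = rng.permutation(n)
        t_star = _t_for_group(fitted + R[perm], X, xtx_inv, pinv)
        supra[:] = False
        supra[mask] = np.abs(t_star) > t_crit
        _, _, perm_sizes = _cluster_sizes(supra)
        max_sizes[i + 1] = perm_sizes.max() if perm_sizes.size else 0

    table = []
    for cid in range(1, n_clusters + 1):
        in_cluster = labels == cid
        size = int(in_cluster.sum())
        corrected = float((max_sizes >= size).sum() / (1.0 + n_perm))
        abs_t = np.abs(result.t_map) * in_cluster
        peak = np.unravel_index(int(np.argmax(abs_t)), abs_t.shape)
        table.append(
            {
                "cluster_id": cid,
                "size_voxels": size,
                "corrected_p": corrected,
                "peak": tuple(int(v) for v in peak),
                "peak_t": float(result.t_map[peak]),
                "significant": corrected < 0.05,
            }
        )
    table.sort(key=lambda row: row["size_voxels"], reverse=True)
    return GroupComparisonResult(
        t_map=result.t_map,
        uncorrected_p_map=result.uncorrected_p_map,
        cluster_table=table,
        mask=mask,
        n_permutations=n_perm,
        seed=seed,
        df=result.df,
        positive_group=result.positive_group,
        _Y=Y,
        _X=X,
        _Z=Z,
    )
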