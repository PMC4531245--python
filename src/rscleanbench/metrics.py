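"""BOLD-variation metrics and within-group consistency.

Temporal SNR (voxelwise temporal mean / temporal SD, median within an
eroded brain mask), the %dSTD suppression map
``100 * STD_t(uncleaned - cleaned) / STD_t(uncleaned)``, exceedance
probability maps across subjects, across-subject standard-deviation
(consistency) maps, and the voxelwise paired t-test used to compare them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .preprocess import erode_mask

logger = logging.getLogger(__name__)

__all__ = [
    "TsnrResult",
    "DeltaStdMap",
    "ConsistencyMap",
    "temporal_snr",
    "delta_std_map",
    "exceedance_probability_map",
    "consistency_map",
    "paired_t_over_voxels",
]

_STD_EPS = 1e-12


@dataclass
class TsnrResult:
    tsnr_map: np.ndarray  # 3D, zero where undefined
    median_tsnr: float
    eroded_mask: np.ndarray
    n_excluded: int  # zero-variance voxels excluded from the median


@dataclass
class DeltaStdMap:
    values: np.ndarray  # 3D percentages
    subject_id: str | None = None
    mode: str | None = None


@dataclass
class ConsistencyMap:
    values: np.ndarray  # 3D across-subject SD
    group: str | None = None
    method: str | None = None
    mode: str | None = None


def temporal_snr(data: np.ndarray, brain_mask: np.ndarray, erosion_iters: int = 2) -> TsnrResult:
    """Voxelwise mean/SD over time; median within the eroded brain mask."""
    if data.shape[-1] < 2:
        raise ValueError("need at least two volumes")
    eroded = erode_mask(brain_mask, erosion_iters)
    if not eroded.any():
        raise ValueError("eroded mask is empty")
    mean = data.mean(axis=-1)
    sd = data.std(axis=-1, ddof=1)
    tsnr = np.zeros_like(mean)
    ok = sd > _STD_EPS
    tsnr[ok] = mean[ok] / sd[ok]
    inside = eroded & ok
    n_excluded = int(eroded.sum() - inside.sum())
    if n_excluded:
        logger.warning("%d zero-variance voxels excluded from the tSNR median", n_excluded)
    return TsnrResult(
        tsnr_map=tsnr,
        median_tsnr=float(np.median(tsnr[inside])),
        eroded_mask=eroded,
        n_excluded=n_excluded,
    )


def delta_std_map(
    uncleaned: np.ndarray,
    cleaned: np.ndarray,
    subject_id: str | None = None,
    mode: str | None = None,
) -> DeltaStdMap:
    """Percentage of the uncleaned temporal fluctuation removed by cleaning.

    Per voxel: ``100 * STD_t(uncleaned - cleaned) / STD_t(uncleaned)``;
    voxels whose uncleaned series has (near-)zero SD are set to 0.
    """
    if uncleaned.shape != cleaned.shape:
        raise ValueError("uncleaned/cleaned shape mismatch")
    removed_sd = (uncleaned - cleaned).std(axis=-1, ddof=1)
    base_sd = uncleaned.std(axis=-1, ddof=1)
    out = np.zeros_like(base_sd)
    ok = base_sd > _STD_EPS
    n_degen = int((~ok).sum())
    if n_degen:
        logger.debug("%d voxels with zero uncleaned SD set to 0 in %%dSTD", n_degen)
    out[ok] = 100.0 * removed_sd[ok] / base_sd[ok]
    return DeltaStdMap(values=out, subject_id=subject_id, mode=mode)


def exceedance_probability_map(delta_maps: list, threshold_pct: float = 25.0) -> np.ndarray:
    """Per voxel, the fraction of subjects whose %dSTD exceeds the threshold."""
    if not delta_maps:
        raise ValueError("need at least one map")
    arrays = [m.values if isinstance(m, DeltaStdMap) else np.asarray(m) for m in delta_maps]
    stack = np.stack(arrays, axis=0)
    return (stack > threshold_pct).mean(axis=0)


def consistency_map(
    maps: list,
    brain_mask: np.ndarray | None = None,
    group: str | None = None,
    method: str | None = None,
    mode: str | None = None,
) -> ConsistencyMap:
    """Voxelwise sample SD (n-1 denominator) of per-subject statistic maps."""
    if len(maps) < 2:
        raise ValueError("need at least two subjects")
    arrays = [getattr(m, "values", m) for m in maps]
    stack = np.stack([np.asarray(a) for a in arrays], axis=0)
    sd = stack.std(axis=0, ddof=1)
    if brain_mask is not None:
        sd = sd * brain_mask.astype(bool)
    return ConsistencyMap(values=sd, group=group, method=method, mode=mode)


def paired_t_over_voxels(
    map_a: np.ndarray, map_b: np.ndarray, mask: np.ndarray
) -> tuple[float, int, float]:
    """Paired t-test over the mask voxels of (A - B).

    Degrees of freedom are n_voxels - 1 (spatial autocorrelation is
    ignored, matching common practice for this comparison). A
    zero-variance difference yields (0 or nan, df, nan) with a warning.
    """
    mask = mask.astype(bool)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("need at least two mask voxels")
    d = (np.asarray(map_a) - np.asarray(map_b))[mask].astype(float)
    df = n - 1
    sd = d.std(ddof=1)
    if sd < _STD_EPS:
        if abs(d.mean()) < _STD_EPS:
            return 0.0, df, 1.0
        warnings.warn("zero-variance paired difference; p undefined", RuntimeWarning)
        return float(np.sign(d.mean()) * np.inf), df, float("nan")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)
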