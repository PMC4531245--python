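"""Per-subject DMN connectivity maps.

Two estimators: seed-based Pearson correlation against the mean series of
a posterior-cingulate seed sphere (Fisher r-to-z transformed), and
template-based dual regression against a set of network spatial templates
(stage 1: spatial regression of every volume on all templates at once to
get per-network timecourses; stage 2: temporal regression of every voxel
on those timecourses to get per-network parameter-estimate maps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["ZMap", "PEMap", "seed_fc_zmap", "dual_regression", "select_dmn_map"]

_R_CLAMP = 1.0 - 1e-7


@dataclass
class ZMap:
    values: np.ndarray  # 3D Fisher-z image
    subject_id: str | None = None
    method: str = "seed"


@dataclass
class PEMap:
    values: np.ndarray  # 3D parameter-estimate image
    subject_id: str | None = None
    network_index: int = 0


def seed_fc_zmap(
    data: np.ndarray,
    seed_mask: np.ndarray,
    brain_mask: np.ndarray,
    subject_id: str | None = None,
) -> ZMap:
    """Fisher-z map of the correlation of every brain voxel with the seed mean.

    Correlations are clamped to +/-(1 - 1e-7) before atanh; voxels with a
    zero-variance series get z = 0 (their count is logged).
    """
    seed_mask = seed_mask.astype(bool)
    brain = brain_mask.astype(bool)
    if not seed_mask.any():
        raise ValueError("empty seed mask")
    seed_ts = data[seed_mask].mean(axis=0)
    seed_ts = seed_ts - seed_ts.mean()
    seed_norm = np.linalg.norm(seed_ts)
    if seed_norm < 1e-12:
        raise ValueError("seed mean timeseries has zero variance")

    series = data[brain].astype(float)
    series -= series.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(series, axis=1)
    degenerate = norms < 1e-12
    if degenerate.any():
        logger.warning("%d zero-variance voxels set to z=0", int(degenerate.sum()))
    norms[degenerate] = 1.0
    r = (series @ seed_ts) / (norms * seed_norm)
    r[degenerate] = 0.0
    z = np.arctanh(np.clip(r, -_R_CLAMP, _R_CLAMP))
    out = np.zeros(brain.shape)
    out[brain] = z
    return ZMap(values=out, subject_id=subject_id, method="seed")


def dual_regression(
    data: np.ndarray,
    templates: np.ndarray,
    brain_mask: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Template-based dual regression.

    ``templates`` is (K, x, y, z). Stage 1 regresses every volume's voxel
    pattern (within the mask, templates demeaned and variance-normalised
    across voxels, with an intercept) on all templates simultaneously;
    stage 2 regresses every voxel's timeseries on the demeaned stage-1
    timecourses (with an intercept). Returns ``(timecourses (T, K),
    pe_maps (K, x, y, z))``.
    """
    brain = brain_mask.astype(bool)
    K = templates.shape[0]
    X = templates[:, brain].astype(float).T  # (V, K)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd < 1e-12):
        bad = [str(k) for k in np.flatnonzero(sd < 1e-12)]
        raise ValueError(f"templates constant within mask: {', '.join(bad)}")
    X = X / sd
    # collinearity check, naming the offending pair
    C = np.corrcoef(X.T) if K > 1 else np.ones((1, 1))
    for i in range(K):
        for j in range(i + 1, K):
            if abs(C[i, j]) > 1.0 - 1e-10:
                raise ValueError(f"templates {i} and {j} are collinear within the mask")

    Y = data[brain].astype(float)  # (V, T)
    X1 = np.column_stack([np.ones(X.shape[0]), X])
    tcs = (np.linalg.pinv(X1) @ Y)[1:].T  # (T, K)

    D = tcs - tcs.mean(axis=0)
    D1 = np.column_stack([np.ones(D.shape[0]), D])
    betas = np.linalg.pinv(D1) @ Y.T  # (K+1, V)
    pe = np.zeros((K,) + brain.shape)
    pe[:, brain] = betas[1:]
    return tcs, pe


def select_dmn_map(pe_maps: np.ndarray, dmn_index: int, subject_id: str | None = None) -> PEMap:
    """Pick the DMN network's parameter-estimate map out of the stack."""
    if not (0 <= dmn_index < pe_maps.shape[0]):
        raise IndexError(f"dmn_index {dmn_index} out of range for {pe_maps.shape[0]} maps")
    return PEMap(values=pe_maps[dmn_index], subject_id=subject_id, network_index=dmn_index)
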