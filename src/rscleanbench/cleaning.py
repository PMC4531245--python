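"""The five cleanup variants applied to common-preprocessed data.

* ``none``     -- identity (the "uncleaned" dataset).
* ``motreg``   -- OLS removal of the 24-parameter motion expansion.
* ``mwcreg``   -- motion expansion plus WM and CSF mean signals.
* ``compsoft`` -- full removal of motion, then joint regression of the data
  on all ICA component timecourses with subtraction of only the
  noise-labeled components' fitted contribution (their *unique* variance).
* ``compagg``  -- full OLS removal of motion and the noise-labeled
  component timecourses together (their *full* variance).

All confound columns are demeaned and each voxel's temporal mean is
preserved through cleaning (removed before the regression, re-added after),
so temporal SNR remains comparable across variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .preprocess import erode_mask

logger = logging.getLogger(__name__)

__all__ = [
    "CleanupMode",
    "ConfoundMatrix",
    "expand_motion_24",
    "extract_mean_timeseries",
    "regress_out_full",
    "clean",
]


class CleanupMode(str, Enum):
    none = "none"
    motreg = "motreg"
    mwcreg = "mwcreg"
    compsoft = "compsoft"
    compagg = "compagg"


@dataclass
class ConfoundMatrix:
    values: np.ndarray  # (T, K)
    column_names: list[str]
    demeaned: bool = True

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(self.column_names):
            raise ValueError("confound matrix / name length mismatch")


def expand_motion_24(motion6: np.ndarray) -> ConfoundMatrix:
    """24-parameter motion expansion.

    Columns 1-6: the rigid-body traces; 7-12: backward temporal differences
    (first row zero); 13-24: elementwise squares of the first twelve.
    All columns are demeaned afterwards.
    """
    motion6 = np.asarray(motion6, dtype=float)
    if motion6.ndim != 2 or motion6.shape[1] != 6:
        raise ValueError("motion6 must be (T, 6)")
    if motion6.shape[0] < 2:
        raise ValueError("need at least two time points")
    deriv = np.vstack([np.zeros((1, 6)), np.diff(motion6, axis=0)])
    twelve = np.hstack([motion6, deriv])
    X = np.hstack([twelve, twelve**2])
    X = X - X.mean(axis=0)
    names = (
        [f"mot{i + 1}" for i in range(6)]
        + [f"dmot{i + 1}" for i in range(6)]
        + [f"mot{i + 1}_sq" for i in range(6)]
        + [f"dmot{i + 1}_sq" for i in range(6)]
    )
    return ConfoundMatrix(values=X, column_names=names)


def extract_mean_timeseries(data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-volume arithmetic mean over the mask voxels."""
    mask = mask.astype(bool)
    if mask.shape != data.shape[:3]:
        raise ValueError("mask grid does not match the data")
    if not mask.any():
        raise ValueError("empty mask")
    return data[mask].mean(axis=0)


def _drop_duplicate_columns(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    keep: list[int] = []
    for j in range(X.shape[1]):
        dup = False
        for i in keep:
            if np.allclose(X[:, j], X[:, i], atol=1e-12, rtol=0.0):
                logger.warning("dropping duplicate confound column %r (== %r)", names[j], names[i])
                dup = True
                break
        keep.append(j) if not dup else None
    if len(keep) != X.shape[1]:
        return X[:, keep], [names[i] for i in keep]
    return X, names


def _residualise(series: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Least-squares residual of each row of ``series`` (shape (V, T)) on X."""
    beta = np.linalg.pinv(X) @ series.T  # (K, V)
    return series - (X @ beta).T


def regress_out_full(data: np.ndarray, X: ConfoundMatrix | np.ndarray) -> np.ndarray:
    """Remove the full variance of the confound columns from a 4D series.

    Each voxel's temporal mean is removed before and re-added after the
    regression; the demeaned residual is orthogonal to every column.
    """
    values = X.values if isinstance(X, ConfoundMatrix) else np.asarray(X, dtype=float)
    if values.ndim != 2:
        raise ValueError("confound matrix must be 2D")
    T = data.shape[-1]
    if values.shape[0] != T:
        raise ValueError("confound rows do not match the number of volumes")
    if values.shape[1] == 0:
        return data.copy()
    values = values - values.mean(axis=0)
    flat = data.reshape(-1, T).astype(float)
    mean = flat.mean(axis=1, keepdims=True)
    resid = _residualise(flat - mean, values)
    return (resid + mean).reshape(data.shape)


def clean(
    data: np.ndarray,
    motion6: np.ndarray,
    masks,
    decomposition,
    mode: CleanupMode | str,
) -> np.ndarray:
    """Apply one cleanup variant to a common-preprocessed 4D series.

    ``masks`` is a :class:`~rscleanbench.simulate.MaskSet` (only the WM/CSF
    ROIs are used, and only for ``mwcreg``); ``decomposition`` is a
    :class:`~rscleanbench.ica.ComponentDecomposition`, required only for the
    component-based modes.
    """
    mode = CleanupMode(mode)
    if mode is CleanupMode.none:
        return data.copy()

    m24 = expand_motion_24(motion6)
    if mode is CleanupMode.motreg:
        return regress_out_full(data, m24)

    if mode is CleanupMode.mwcreg:
        wm_roi = erode_mask(masks.wm_roi, 1)
        if not wm_roi.any():
            wm_roi = masks.wm_roi.astype(bool)
        csf_roi = erode_mask(masks.ventricle_roi, 1)
        if not csf_roi.any():
            csf_roi = masks.ventricle_roi.astype(bool)
        wm_ts = extract_mean_timeseries(data, wm_roi)
        csf_ts = extract_mean_timeseries(data, csf_roi)
        X = np.column_stack([m24.values, wm_ts - wm_ts.mean(), csf_ts - csf_ts.mean()])
        names = m24.column_names + ["wm_mean", "csf_mean"]
        X, names = _drop_duplicate_columns(X, names)
        return regress_out_full(data, ConfoundMatrix(X, names))

    # component-based modes
    if decomposition is None:
        raise ValueError(f"{mode.value} requires an ICA decomposition")
    if decomposition.labels is None:
        raise ValueError(f"{mode.value} requires labeled components")
    labels = np.asarray(decomposition.labels)
    if labels.size != decomposition.timecourses.shape[1]:
        raise ValueError("decomposition labels are missing or incomplete")
    noise_idx = np.flatnonzero(labels == "noise")

    T = data.shape[-1]
    flat = data.reshape(-1, T).astype(float)
    mean = flat.mean(axis=1, keepdims=True)
    M = m24.values - m24.values.mean(axis=0)

    if mode is CleanupMode.compagg:
        tcs = decomposition.timecourses[:, noise_idx]
        X = np.column_stack([M, tcs - tcs.mean(axis=0)]) if noise_idx.size else M
        names = m24.column_names + [f"ic{j}" for j in noise_idx]
        X, names = _drop_duplicate_columns(X, names)
        resid = _residualise(flat - mean, X)
        return (resid + mean).reshape(data.shape)

    # compsoft: (1) residualise data and all component timecourses on the
    # motion expansion; (2) joint regression of the data on all components,
    # subtracting only the noise components' fitted contribution.
    y_m = _residualise(flat - mean, M)
    C = decomposition.timecourses - decomposition.timecourses.mean(axis=0)
    C_m = C - M @ (np.linalg.pinv(M) @ C)
    # Components whose timecourse is (almost) fully explained by motion
    # carry no information beyond the motion step and would make the joint
    # design numerically singular; they are dropped from the joint fit.
    keep = C_m.std(axis=0) > 0.05 * np.maximum(C.std(axis=0), 1e-300)
    dropped = np.flatnonzero(~keep)
    if dropped.size:
        logger.warning(
            "soft cleanup: dropping %d motion-dominated component(s): %s",
            dropped.size,
            dropped.tolist(),
        )
    noise_idx = np.flatnonzero((labels == "noise") & keep)
    if noise_idx.size == 0:
        return (y_m + mean).reshape(data.shape)
    C_m = C_m[:, keep]
    noise_pos = np.searchsorted(np.flatnonzero(keep), noise_idx)
    beta = np.linalg.pinv(C_m, rcond=1e-3) @ y_m.T  # (n_kept, V) joint fit
    noise_fit = (C_m[:, noise_pos] @ beta[noise_pos]).T
    return (y_m - noise_fit + mean).reshape(data.shape)
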