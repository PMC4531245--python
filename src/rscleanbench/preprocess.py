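"""Common preprocessing shared by every cleanup variant.

Spatial smoothing with an isotropic Gaussian kernel and high-pass temporal
filtering. The high-pass filter is implemented as regression against a
discrete-cosine (DCT-II) drift basis containing every component below the
cutoff frequency: linear, exactly idempotent and easy to reason about.
The voxelwise temporal mean can be re-added after filtering so that
temporal SNR stays well defined downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "PreprocessConfig",
    "fwhm_to_sigma",
    "sigma_to_fwhm",
    "gaussian_smooth",
    "dct_drift_basis",
    "highpass_filter",
    "erode_mask",
    "preprocess_subject",
]

_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class PreprocessConfig:
    fwhm_mm: float = 5.0
    highpass_cutoff_hz: float = 0.01
    keep_temporal_mean: bool = True

    def __post_init__(self) -> None:
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be non-negative")
        if self.highpass_cutoff_hz <= 0:
            raise ValueError("highpass cutoff must be positive")


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """sigma = FWHM / (2 * sqrt(2 * ln 2))."""
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    return fwhm_mm / _FWHM_FACTOR


def sigma_to_fwhm(sigma_mm: float) -> float:
    if sigma_mm < 0:
        raise ValueError("sigma must be non-negative")
    return sigma_mm * _FWHM_FACTOR


def gaussian_smooth(data: np.ndarray, fwhm_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Smooth each volume with an isotropic Gaussian.

    Reflecting boundary handling conserves the spatial sum of each volume.
    Accepts a 3D volume or a 4D (x, y, z, t) series.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return data.copy()
    sigma_vox = fwhm_to_sigma(fwhm_mm) / voxel_size_mm
    if data.ndim == 3:
        return ndimage.gaussian_filter(data, sigma=sigma_vox, mode="reflect")
    if data.ndim != 4:
        raise ValueError("expected a 3D volume or 4D series")
    out = np.empty_like(data, dtype=float)
    for t in range(data.shape[3]):
        out[..., t] = ndimage.gaussian_filter(data[..., t], sigma=sigma_vox, mode="reflect")
    return out


def dct_drift_basis(n_volumes: int, tr_s: float, cutoff_hz: float) -> np.ndarray:
    """DCT-II drift regressors up to the cutoff frequency.

    Component k has frequency k / (2 * T * TR); all k >= 1 with frequency
    at or below the cutoff are included. Columns are unit-norm and
    zero-mean by construction.
    """
    k_max = int(np.floor(2.0 * n_volumes * tr_s * cutoff_hz + 1e-9))
    t = np.arange(n_volumes)
    cols = [
        np.cos(np.pi * k * (t + 0.5) / n_volumes) * np.sqrt(2.0 / n_volumes)
        for k in range(1, max(k_max, 0) + 1)
    ]
    if not cols:
        return np.zeros((n_volumes, 0))
    return np.stack(cols, axis=1)


def highpass_filter(
    x: np.ndarray, cutoff_hz: float, tr_s: float, keep_temporal_mean: bool = True
) -> np.ndarray:
    """Remove slow drifts below ``cutoff_hz`` from the last (time) axis.

    Implemented as least-squares removal of the sub-cutoff DCT drift basis
    (plus the mean); if ``keep_temporal_mean`` the temporal mean of the
    input is re-added.
    """
    T = x.shape[-1]
    if T < 4:
        raise ValueError("need at least 4 time points")
    nyquist = 1.0 / (2.0 * tr_s)
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyquist} Hz")
    B = dct_drift_basis(T, tr_s, cutoff_hz)
    flat = x.reshape(-1, T).astype(float)
    mean = flat.mean(axis=1, keepdims=True)
    centred = flat - mean
    if B.shape[1]:
        coef = centred @ B  # unit-norm orthogonal columns
        centred = centred - coef @ B.T
    out = centred + mean if keep_temporal_mean else centred
    return out.reshape(x.shape)


def erode_mask(mask: np.ndarray, iterations: int) -> np.ndarray:
    """Iterative morphological erosion with the 6-connected structuring element."""
    if iterations < 0:
        raise ValueError("iterations must be non-negative")
    if iterations == 0:
        return mask.astype(bool).copy()
    struct = ndimage.generate_binary_structure(mask.ndim, 1)
    return ndimage.binary_erosion(
        mask.astype(bool), structure=struct, iterations=iterations, border_value=0
    )


def preprocess_subject(
    data: np.ndarray,
    config: PreprocessConfig,
    voxel_size_mm: float,
    tr_s: float,
) -> np.ndarray:
    """Smooth then high-pass filter one subject's 4D series."""
    out = gaussian_smooth(data, config.fwhm_mm, voxel_size_mm)
    return highpass_filter(
        out, config.highpass_cutoff_hz, tr_s, keep_temporal_mean=config.keep_temporal_mean
    )
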