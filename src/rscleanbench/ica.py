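"""Single-subject spatial ICA and component labeling.

Voxels are treated as observations and timepoints as mixtures: the data
matrix (V voxels x T timepoints) is PCA-reduced and a fixed-point ICA
(FastICA) maximises spatial non-Gaussianity, yielding spatial maps and the
matching component timecourses. Dimensionality is either fixed or chosen
as the smallest number of principal components explaining at least 90% of
the (centred) variance, capped at 40.

Two labelers assign signal/noise labels: an oracle that matches component
maps against the planted artifact and network maps of a synthetic cohort,
and a rule-based surrogate (edge fraction, CSF fraction, high-frequency
power, motion correlation) for data without ground truth.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .preprocess import erode_mask

logger = logging.getLogger(__name__)

__all__ = [
    "ComponentDecomposition",
    "RuleConfig",
    "spatial_ica",
    "label_by_ground_truth",
    "label_by_rules",
]

MAX_AUTO_COMPONENTS = 40
VARIANCE_TARGET = 0.90


class IcaConvergenceError(RuntimeError):
    def __init__(self, max_iter: int, attempts: int):
        super().__init__(f"FastICA did not converge within {max_iter} iterations ({attempts} attempts)")
        self.max_iter = max_iter
        self.attempts = attempts


@dataclass
class ComponentDecomposition:
    """Spatial ICA of one subject's 4D series.

    ``spatial_maps`` are full-grid 3D images (zero outside the brain mask,
    unit variance within it); ``timecourses`` is (T, n_comp). The input is
    approximated by ``temporal_mean + spatial_mean_tc + timecourses @ maps``
    with a residual whose variance equals the discarded PCA variance.
    """

    spatial_maps: np.ndarray  # (n_comp, x, y, z)
    timecourses: np.ndarray  # (T, n_comp)
    explained_variance: np.ndarray  # (n_comp,) fractions of centred variance
    mask: np.ndarray
    temporal_mean: np.ndarray  # 3D voxelwise mean over time
    spatial_mean_tc: np.ndarray  # (T,) mean over mask voxels of the demeaned data
    labels: list[str] | None = None  # "signal" | "noise" | "unlabeled"

    @property
    def n_components(self) -> int:
        return self.timecourses.shape[1]

    def reconstruct(self) -> np.ndarray:
        """Low-rank reconstruction of the masked series (V, T)."""
        maps = self.spatial_maps[:, self.mask]  # (k, V)
        recon = (self.timecourses @ maps).T  # (V, T)
        recon += self.temporal_mean[self.mask][:, None]
        recon += self.spatial_mean_tc[None, :]
        return recon


def _choose_dimensionality(sv: np.ndarray, n_components) -> int:
    if n_components != "auto":
        return int(n_components)
    var = sv**2
    frac = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(frac, VARIANCE_TARGET) + 1)
    return min(k, MAX_AUTO_COMPONENTS, sv.size)


def spatial_ica(
    data: np.ndarray,
    brain_mask: np.ndarray,
    n_components: int | str = "auto",
    seed: int = 0,
    max_iter: int = 5000,
    tol: float = 1e-3,
) -> ComponentDecomposition:
    """Spatial ICA of a 4D series within a brain mask.

    Deterministic given ``seed``; up to three FastICA restarts (with seeds
    derived from ``seed``) are attempted before a convergence error is
    raised. Components are ordered by explained variance and sign-fixed so
    every spatial map has non-negative skewness.
    """
    mask = brain_mask.astype(bool)
    T = data.shape[-1]
    V = int(mask.sum())
    M = data[mask].astype(float)  # (V, T)
    temporal_mean = np.zeros(mask.shape)
    temporal_mean[mask] = M.mean(axis=1)
    Mc = M - M.mean(axis=1, keepdims=True)
    spatial_mean_tc = Mc.mean(axis=0)
    Mc -= spatial_mean_tc[None, :]

    sv = np.linalg.svd(Mc, compute_uv=False)
    k = _choose_dimensionality(sv, n_components)
    if not (0 < k < min(T, V)):
        raise ValueError(f"n_components={k} out of range for (T={T}, V={V})")
    total_var = (sv**2).sum()

    sources = None
    for attempt in range(5):
        ica = FastICA(
            n_components=k,
            whiten="unit-variance",
            fun="logcosh",
            max_iter=max_iter,
            tol=tol,
            random_state=seed + 1000 * attempt,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            S = ica.fit_transform(Mc)  # (V, k) spatial sources
            converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
        if converged:
            sources = S
            break
        logger.warning("FastICA restart %d (seed %d) after non-convergence", attempt + 1, seed)
    if sources is None:
        raise IcaConvergenceError(max_iter, attempts=5)

    mixing = ica.mixing_  # (T, k): Mc ~= S @ mixing.T + ica.mean_
    # sklearn centres features (timepoints); the data are already doubly
    # centred so ica.mean_ is numerically zero -- fold it in regardless.
    spatial_mean_tc = spatial_mean_tc + ica.mean_

    # unit-variance maps, variance pushed into the timecourses
    map_sd = sources.std(axis=0, ddof=0)
    map_sd[map_sd < 1e-15] = 1.0
    sources = sources / map_sd
    mixing = mixing * map_sd[None, :]

    # explained variance of component k: var over (V, T) of outer product
    ev = (mixing**2).sum(axis=0) * V / total_var  # maps have unit variance over V
    order = np.argsort(ev)[::-1]
    sources, mixing, ev = sources[:, order], mixing[:, order], ev[order]

    # sign convention: non-negative spatial skewness
    skew = ((sources - sources.mean(axis=0)) ** 3).mean(axis=0)
    flip = np.where(skew < 0, -1.0, 1.0)
    sources *= flip
    mixing *= flip

    maps = np.zeros((k,) + mask.shape)
    maps[:, mask] = sources.T
    return ComponentDecomposition(
        spatial_maps=maps,
        timecourses=mixing,
        explained_variance=ev,
        mask=mask,
        temporal_mean=temporal_mean,
        spatial_mean_tc=spatial_mean_tc,
    )


def _masked_corr(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    x = a[mask].astype(float)
    y = b[mask].astype(float)
    x -= x.mean()
    y -= y.mean()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx < 1e-15 or ny < 1e-15:
        return 0.0
    return float(x @ y / (nx * ny))


def label_by_ground_truth(decomp: ComponentDecomposition, truth, threshold: float = 0.4) -> list[str]:
    """Oracle labeling against the planted artifact and network maps.

    A component is noise if its best absolute spatial correlation with any
    planted artifact map exceeds ``threshold`` and beats its best network
    correlation; signal in the reverse case; unlabeled otherwise.
    """
    mask = decomp.mask
    labels: list[str] = []
    art_maps = [c.spatial_map for c in truth.artifact_components]
    net_maps = list(truth.template_maps)
    for j in range(decomp.n_components):
        comp = decomp.spatial_maps[j]
        best_art = max(abs(_masked_corr(comp, m, mask)) for m in art_maps)
        best_net = max(abs(_masked_corr(comp, m, mask)) for m in net_maps)
        if best_art > threshold and best_art > best_net:
            labels.append("noise")
        elif best_net > threshold and best_net >= best_art:
            labels.append("signal")
        else:
            labels.append("unlabeled")
    decomp.labels = labels
    return labels


@dataclass
class RuleConfig:
    edge_fraction: float = 0.5
    csf_fraction: float = 0.5
    wm_fraction: float = 0.5
    hf_power_ratio: float = 0.5
    motion_correlation: float = 0.6
    hf_cutoff_hz: float = 0.1
    top_weight_quantile: float = 0.95


def label_by_rules(
    decomp: ComponentDecomposition,
    masks,
    motion24,
    rules: RuleConfig | None = None,
    tr_s: float = 2.5,
) -> list[str]:
    """Rule-based surrogate classifier for data without ground truth.

    A component is noise if any rule fires: a large share of its strongest
    weight mass sits in the brain-boundary shell, in CSF or in WM, its
    timecourse is dominated by power above ``hf_cutoff_hz``, or it is well
    explained by the motion expansion (multiple correlation with the
    motion24 design).
    """
    rules = rules or RuleConfig()
    mask = decomp.mask
    shell = mask & ~erode_mask(mask, 1)
    csf = masks.csf.astype(bool)
    wm = masks.wm.astype(bool)
    M = motion24.values if hasattr(motion24, "values") else np.asarray(motion24)
    M = M - M.mean(axis=0)
    Q, _ = np.linalg.qr(M)

    labels: list[str] = []
    for j in range(decomp.n_components):
        w = np.abs(decomp.spatial_maps[j][mask])
        thr = np.quantile(w, rules.top_weight_quantile)
        top = w >= thr
        coords = np.zeros(mask.shape, dtype=bool)
        coords[mask] = top
        # fraction of the top-weight mass (squared weights) in shell / CSF
        w2 = np.zeros(mask.shape)
        w2[mask] = (w * top) ** 2
        mass = max(w2.sum(), 1e-300)
        edge_frac = float(w2[shell].sum() / mass)
        csf_frac = float(w2[csf].sum() / mass)
        wm_frac = float(w2[wm].sum() / mass)

        tc = decomp.timecourses[:, j] - decomp.timecourses[:, j].mean()
        spec = np.abs(np.fft.rfft(tc)) ** 2
        freqs = np.fft.rfftfreq(tc.size, d=tr_s)
        total = spec[1:].sum()
        hf = spec[1:][freqs[1:] > rules.hf_cutoff_hz].sum() / total if total > 0 else 0.0

        tc_norm = np.linalg.norm(tc)
        mot_corr = 0.0
        if tc_norm > 1e-15:
            # multiple correlation with the motion design, adjusted for the
            # chance fit of a 24-column design on a short series
            r2 = float((np.linalg.norm(Q.T @ tc) / tc_norm) ** 2)
            T_len, p_cols = M.shape
            if T_len - p_cols - 1 > 0:
                r2 = 1.0 - (1.0 - r2) * (T_len - 1) / (T_len - p_cols - 1)
            mot_corr = float(np.sqrt(max(r2, 0.0)))

        noisy = (
            edge_frac > rules.edge_fraction
            or csf_frac > rules.csf_fraction
            or wm_frac > rules.wm_fraction
            or hf > rules.hf_power_ratio
            or mot_corr > rules.motion_correlation
        )
        labels.append("noise" if noisy else "signal")
    decomp.labels = labels
    return labels
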