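"""Synthetic two-group rsfMRI cohort generator.

Emulates the study design the benchmark targets: 20 healthy controls (HC)
and 21 patients (AD), 160 volumes at TR = 2.5 s on a ~3 mm grid, ten
spatial network templates whose default-mode network (DMN) has a posterior
node overlapping a posterior-cingulate seed sphere, and a set of planted
artifact sources (motion-driven edge fluctuations, CSF pulsation, WM
drift, a vessel-like component, scanner drift, thermal noise).

The AD group carries a multiplicative reduction of the posterior-DMN
coupling (``dmn_deficit``), which is the planted between-group effect every
downstream stage tries to recover. Motion artifacts are injected as an
exact linear function of the 24-parameter motion expansion so that motion
regression can in principle remove them completely. The vessel component's
timecourse is partially coupled to the DMN timecourse, so that removing
only its unique variance (soft cleanup) leaves behind shared variance that
full (aggressive) removal also takes out.

Everything is deterministic given (config, seed): the master seed is
expanded into independent per-subject substreams with
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage

__all__ = [
    "SimulationConfig",
    "MaskSet",
    "SubjectDataset",
    "CohortDataset",
    "ArtifactComponent",
    "GroundTruth",
    "generate_motion_params",
    "generate_cohort",
    "bandlimited_timecourse",
]

# Geometry fractions (relative to the grid / brain semi-axes). The brain is
# an ellipsoid; CSF (ventricles) and WM are nested central ellipsoids and
# GM is the remaining cortical ribbon. Posterior = +y.
_BRAIN_FRAC = (0.44, 0.46, 0.44)
_WM_FRAC = 0.48
_CSF_FRAC = 0.22
_SEED_OFFSET_FRAC = 0.72  # seed centre along +y, as fraction of brain semi-axis
_SEED_RADIUS_MM = 6.0
_TEMPLATE_SIGMA_VOX = 2.2
_POSTERIOR_Y_FRAC = 0.45
_POSTERIOR_XZ_FRAC = (0.32, 0.40)

ARTIFACT_NAMES = (
    "motion_edge",
    "motion_global",
    "csf_pulsation",
    "wm_drift",
    "vessel",
    "scanner_drift",
)


class ConfigurationError(ValueError):
    """Raised when a simulation configuration cannot be realised."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the emulated acquisition: 24x28x22 voxels of 3 mm,
    160 volumes at TR = 2.5 s, 20 HC / 21 AD, ten network templates and a
    posterior-DMN amplitude factor of 0.6 in the AD group.
    """

    grid_shape: tuple[int, int, int] = (24, 28, 22)
    voxel_size_mm: float = 3.0
    n_volumes: int = 160
    tr_s: float = 2.5
    n_hc: int = 20
    n_ad: int = 21
    n_templates: int = 10
    dmn_deficit: float = 0.6
    artifact_amplitudes: dict[str, float] = field(
        default_factory=lambda: {
            "motion_edge": 3.0,
            "motion_global": 3.5,
            "csf_pulsation": 6.0,
            "wm_drift": 4.0,
            "vessel": 16.0,
            "scanner_drift": 5.0,
        }
    )
    noise_sd: float = 1.0
    random_seed: int = 0
    # Secondary knobs (amplitudes in the same arbitrary signal units).
    baseline: float = 1000.0
    network_amplitude: float = 1.0
    network_amp_subject_sd: float = 0.15  # log-sd of per-subject network gain
    vessel_signal_coupling: float = 0.3  # corr of vessel tc with DMN tc
    motion_mrd_mm: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.07, "AD": 0.09}
    )
    motion_mrd_sd_mm: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.04, "AD": 0.06}
    )
    gm_volume_mean: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.62, "AD": 0.55}
    )
    gm_volume_sd: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.03, "AD": 0.04}
    )

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 4:
            raise ConfigurationError(f"invalid grid_shape {self.grid_shape}")
        if self.n_volumes < 2:
            raise ConfigurationError("n_volumes must be >= 2")
        if not (0.0 <= self.dmn_deficit <= 1.0):
            raise ConfigurationError("dmn_deficit must lie in [0, 1]")
        if self.voxel_size_mm <= 0 or self.tr_s <= 0:
            raise ConfigurationError("voxel_size_mm and tr_s must be positive")
        if self.noise_sd < 0 or self.network_amplitude < 0:
            raise ConfigurationError("amplitudes must be non-negative")
        for name, amp in self.artifact_amplitudes.items():
            if amp < 0:
                raise ConfigurationError(f"artifact amplitude {name!r} is negative")
        if self.n_hc < 1 or self.n_ad < 1:
            raise ConfigurationError("both groups need at least one subject")
        if self.n_templates < 2:
            raise ConfigurationError("need at least two network templates")

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class MaskSet:
    """Binary tissue/ROI masks on the cohort grid.

    All masks are subsets of ``brain``; gm/wm/csf partition the brain;
    ``seed_sphere`` is contained in ``posterior_roi`` which lies in gm.
    """

    brain: np.ndarray
    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    ventricle_roi: np.ndarray
    wm_roi: np.ndarray
    seed_sphere: np.ndarray
    posterior_roi: np.ndarray

    def validate(self) -> None:
        for name in ("gm", "wm", "csf", "ventricle_roi", "wm_roi", "seed_sphere", "posterior_roi"):
            m = getattr(self, name)
            if m.shape != self.brain.shape:
                raise ConfigurationError(f"mask {name} is on a different grid")
            if np.any(m & ~self.brain):
                raise ConfigurationError(f"mask {name} leaves the brain mask")
        if np.any(self.gm & self.wm) or np.any(self.gm & self.csf) or np.any(self.wm & self.csf):
            raise ConfigurationError("gm/wm/csf overlap")
        if np.any(self.seed_sphere & ~self.posterior_roi):
            raise ConfigurationError("seed sphere leaves the posterior ROI")
        if np.any(self.posterior_roi & ~self.gm):
            raise ConfigurationError("posterior ROI leaves gray matter")
        for name in ("ventricle_roi", "wm_roi", "seed_sphere", "posterior_roi"):
            if not getattr(self, name).any():
                raise ConfigurationError(f"mask {name} is empty (grid too small)")


@dataclass
class SubjectDataset:
    subject_id: str
    group: str  # "HC" or "AD"
    data: np.ndarray  # (x, y, z, t)
    motion6: np.ndarray  # (t, 6): 3 translations [mm], 3 rotations [rad]
    gm_volume: float

    def validate(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"{self.subject_id}: non-finite data")
        if self.motion6.shape != (self.data.shape[3], 6):
            raise ValueError(f"{self.subject_id}: motion6 shape mismatch")


@dataclass
class CohortDataset:
    subjects: list[SubjectDataset]
    masks: MaskSet
    grid_shape: tuple[int, int, int]
    voxel_size_mm: float

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        return aff

    def by_group(self, group: str) -> list[SubjectDataset]:
        return [s for s in self.subjects if s.group == group]


@dataclass
class ArtifactComponent:
    name: str
    spatial_map: np.ndarray  # 3D, zero outside its tissue support
    timecourses: dict[str, np.ndarray]  # subject_id -> (T,)


@dataclass
class GroundTruth:
    """Everything that was planted, for oracle-style evaluation."""

    template_maps: np.ndarray  # (K, x, y, z), unit peak, non-negative
    dmn_index: int
    dmn_posterior_map: np.ndarray
    dmn_anterior_map: np.ndarray
    network_timecourses: dict[str, np.ndarray]  # subject_id -> (K, T)
    artifact_components: list[ArtifactComponent]
    masks: MaskSet
    gm_volume: dict[str, float]
    planted_effect: dict[str, float]  # posterior-DMN gain actually applied
    baseline_map: np.ndarray

    def subject_network_map(self, subject_id: str, k: int) -> np.ndarray:
        """Effective spatial map of network ``k`` for one subject.

        For the DMN the posterior node is scaled by the planted effect.
        """
        if k == self.dmn_index:
            eff = self.planted_effect[subject_id]
            return self.dmn_anterior_map + eff * self.dmn_posterior_map
        return self.template_maps[k]

    def noiseless_signal(self, subject_id: str) -> np.ndarray:
        """Baseline + sum of network contributions for one subject (no artifacts)."""
        tcs = self.network_timecourses[subject_id]
        out = np.repeat(self.baseline_map[..., None], tcs.shape[1], axis=3).astype(float)
        for k in range(tcs.shape[0]):
            out += self.subject_network_map(subject_id, k)[..., None] * tcs[k]
        return out


# ---------------------------------------------------------------------------
# building blocks


def bandlimited_timecourse(
    rng: np.random.Generator, n_volumes: int, tr_s: float, f_lo: float, f_hi: float
) -> np.ndarray:
    """Unit-variance zero-mean timecourse with support in [f_lo, f_hi] Hz.

    Built from random complex Fourier coefficients on the rfft grid; the DC
    term is always excluded.
    """
    freqs = np.fft.rfftfreq(n_volumes, d=tr_s)
    keep = (freqs >= f_lo) & (freqs <= f_hi) & (freqs > 0)
    if not keep.any():
        # band falls between rfft bins; take the closest non-DC bin
        keep = np.zeros_like(freqs, dtype=bool)
        keep[max(1, int(np.argmin(np.abs(freqs - 0.5 * (f_lo + f_hi)))))] = True
    coef = np.zeros(freqs.shape, dtype=complex)
    coef[keep] = rng.normal(size=keep.sum()) + 1j * rng.normal(size=keep.sum())
    x = np.fft.irfft(coef, n=n_volumes)
    x -= x.mean()
    sd = x.std()
    if sd < 1e-15:  # pragma: no cover - degenerate band
        raise ValueError("degenerate band-limited timecourse")
    return x / sd


def generate_motion_params(
    n_volumes: int, amplitude: float, seed: int | np.random.Generator
) -> tuple[np.ndarray, float]:
    """Smooth random-walk rigid-body motion traces.

    ``amplitude`` is the target mean relative displacement (mean over t of
    the Euclidean norm of the frame-to-frame translation difference, in mm);
    the realised traces are rescaled to hit it exactly. Rotations follow the
    same walks scaled to radians assuming a 50 mm lever arm. Returns
    ``(motion6, mean_relative_displacement)``.
    """
    if n_volumes < 2:
        raise ValueError("n_volumes must be >= 2")
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    steps = rng.normal(size=(n_volumes, 6))
    walk = np.cumsum(steps, axis=0)
    walk = ndimage.gaussian_filter1d(walk, sigma=2.0, axis=0, mode="nearest")
    walk -= walk[0]
    if amplitude == 0:
        return np.zeros((n_volumes, 6)), 0.0
    disp = np.linalg.norm(np.diff(walk[:, :3], axis=0), axis=1)
    mrd = disp.mean()
    if mrd < 1e-15:  # pragma: no cover - measure-zero event
        raise ValueError("degenerate motion realisation")
    scale = amplitude / mrd
    motion6 = walk * scale
    motion6[:, 3:] /= 50.0  # mm of arc at 50 mm radius -> rad
    realised = np.linalg.norm(np.diff(motion6[:, :3], axis=0), axis=1).mean()
    return motion6, float(realised)


def _ellipsoid(shape, center, semi) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    u = sum(((idx[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    return u <= 1.0


def build_masks(config: SimulationConfig) -> MaskSet:
    """Deterministic nested-ellipsoid head geometry for a given grid."""
    shape = config.grid_shape
    center = tuple((s - 1) / 2.0 for s in shape)
    brain_semi = tuple(_BRAIN_FRAC[i] * shape[i] for i in range(3))
    brain = _ellipsoid(shape, center, brain_semi)
    wm_outer = _ellipsoid(shape, center, tuple(_WM_FRAC * s for s in brain_semi))
    csf = _ellipsoid(shape, center, tuple(_CSF_FRAC * s for s in brain_semi)) & brain
    wm = wm_outer & ~csf & brain
    gm = brain & ~wm_outer

    struct = ndimage.generate_binary_structure(3, 1)
    vent = ndimage.binary_erosion(csf, structure=struct, border_value=0)
    if not vent.any():
        vent = csf
    wm_roi = ndimage.binary_erosion(wm, structure=struct, border_value=0)
    if not wm_roi.any():
        wm_roi = wm

    seed_center = (
        int(np.floor(center[0] + 0.5)),
        int(np.floor(center[1] + _SEED_OFFSET_FRAC * brain_semi[1] + 0.5)),
        int(np.floor(center[2] + 0.5)),
    )
    radius_vox = _SEED_RADIUS_MM / config.voxel_size_mm
    idx = np.indices(shape, dtype=float)
    d2 = sum((idx[i] - seed_center[i]) ** 2 for i in range(3))
    seed_sphere = d2 <= radius_vox**2

    # box half-widths never shrink below the seed radius, so the sphere
    # stays inside the ROI on small grids
    half_x = max(_POSTERIOR_XZ_FRAC[0] * brain_semi[0], radius_vox + 0.55)
    half_z = max(_POSTERIOR_XZ_FRAC[1] * brain_semi[2], radius_vox + 0.55)
    post = (
        gm
        & (idx[1] >= center[1] + _POSTERIOR_Y_FRAC * brain_semi[1])
        & (np.abs(idx[0] - seed_center[0]) <= half_x)
        & (np.abs(idx[2] - seed_center[2]) <= half_z)
    )

    masks = MaskSet(
        brain=brain,
        gm=gm,
        wm=wm,
        csf=csf,
        ventricle_roi=vent,
        wm_roi=wm_roi,
        seed_sphere=seed_sphere,
        posterior_roi=post,
    )
    if np.any(seed_sphere & ~gm):
        raise ConfigurationError("grid too small: seed sphere does not fit in gray matter")
    masks.validate()
    return masks


def _gaussian_blob(shape, center, sigma) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    d2 = sum((idx[i] - center[i]) ** 2 for i in range(3))
    return np.exp(-d2 / (2.0 * sigma**2))


def _golden_spiral_directions(n: int) -> np.ndarray:
    """Approximately uniform unit directions on the sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.cos(phi), np.sin(phi) * np.sin(theta)], axis=1
    )


def build_templates(config: SimulationConfig, masks: MaskSet):
    """Network templates: the DMN (posterior + anterior node) plus blobs
    spread over the cortical ribbon. Unit peak, non-negative, brain-masked.
    """
    shape = config.grid_shape
    center = tuple((s - 1) / 2.0 for s in shape)
    brain_semi = tuple(_BRAIN_FRAC[i] * shape[i] for i in range(3))
    sigma = _TEMPLATE_SIGMA_VOX * min(1.0, shape[1] / 28.0 + 0.25)

    seed_center = np.array(np.nonzero(masks.seed_sphere)).mean(axis=1)
    post_map = _gaussian_blob(shape, seed_center, sigma) * masks.brain
    ant_center = (
        center[0],
        center[1] - _SEED_OFFSET_FRAC * brain_semi[1],
        center[2],
    )
    ant_map = _gaussian_blob(shape, ant_center, sigma) * masks.brain
    dmn = post_map + ant_map
    peak = dmn.max()
    post_map /= peak
    ant_map /= peak

    # remaining templates on a spherical spiral at 0.78 of the brain radius,
    # excluding a cone around +/-y so they stay clear of the DMN nodes
    n_other = config.n_templates - 1
    dirs = _golden_spiral_directions(max(3 * n_other, 12))
    keep = np.abs(dirs[:, 1]) < np.cos(np.deg2rad(25.0))
    dirs = dirs[keep]
    if dirs.shape[0] < n_other:
        raise ConfigurationError("grid too small to place the requested templates")
    maps = [post_map + ant_map]
    for j in range(n_other):
        d = dirs[j]
        c = tuple(center[i] + 0.78 * brain_semi[i] * d[i] for i in range(3))
        m = _gaussian_blob(shape, c, sigma) * masks.brain
        if m.max() < 1e-3:
            raise ConfigurationError("template blob fell outside the brain")
        maps.append(m / m.max())
    template_maps = np.stack(maps, axis=0)
    return template_maps, 0, post_map, ant_map


def _build_artifact_maps(config: SimulationConfig, masks: MaskSet) -> dict[str, np.ndarray]:
    shape = config.grid_shape
    center = tuple((s - 1) / 2.0 for s in shape)
    struct = ndimage.generate_binary_structure(3, 1)
    shell = masks.brain & ~ndimage.binary_erosion(masks.brain, structure=struct, border_value=0)

    csf_centroid = np.array(np.nonzero(masks.csf)).mean(axis=1)
    csf_map = _gaussian_blob(shape, csf_centroid, 3.0) * masks.csf
    if csf_map.max() > 0:
        csf_map /= csf_map.max()
    wm_map = _gaussian_blob(shape, center, 4.0) * masks.wm
    if wm_map.max() > 0:
        wm_map /= wm_map.max()

    # thin elongated tube along y, offset laterally, crossing posterior GM
    x0 = int(np.floor(center[0] + 0.5)) + 2  # lateral offset: tube skirts the posterior node
    z0 = int(np.floor(center[2] + 0.5)) + 1
    idx = np.indices(shape, dtype=float)
    d2 = (idx[0] - x0) ** 2 + (idx[2] - z0) ** 2
    vessel = np.exp(-d2 / 1.5) * (d2 <= 1.0 + 1e-9) * masks.brain

    # smooth signed field across the whole brain: the widespread component
    # of motion-related intensity change (spin-history / through-plane)
    grad = ((idx[2] - center[2]) / (_BRAIN_FRAC[2] * shape[2])) * masks.brain
    grad += 0.5 * ((idx[1] - center[1]) / (_BRAIN_FRAC[1] * shape[1])) * masks.brain
    grad /= np.abs(grad).max()

    return {
        "motion_edge": shell.astype(float),
        "motion_global": grad,
        "csf_pulsation": csf_map,
        "wm_drift": wm_map,
        "vessel": vessel,
        "scanner_drift": masks.brain.astype(float),
    }


def _expand_motion_24_raw(motion6: np.ndarray) -> np.ndarray:
    """Raw 24-parameter expansion (no demeaning): used only to synthesise
    motion artifacts; the cleaning module owns the demeaned version."""
    deriv = np.vstack([np.zeros((1, 6)), np.diff(motion6, axis=0)])
    twelve = np.hstack([motion6, deriv])
    return np.hstack([twelve, twelve**2])


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(config: SimulationConfig) -> tuple[CohortDataset, GroundTruth]:
    """Generate the full two-group cohort and its ground truth.

    Each subject's data is
    ``baseline + sum_k map_k * tc_k + sum_j artifact_j * atc_j + noise``,
    with the AD posterior-DMN contribution scaled by ``config.dmn_deficit``.
    """
    masks = build_masks(config)
    template_maps, dmn_index, post_map, ant_map = build_templates(config, masks)
    artifact_maps = _build_artifact_maps(config, masks)

    baseline_map = config.baseline * (
        1.0 * masks.gm + 0.95 * masks.wm + 0.90 * masks.csf
    )

    master = np.random.SeedSequence(config.random_seed)
    cohort_ss, *subj_ss = master.spawn(1 + config.n_hc + config.n_ad)
    cohort_rng = np.random.default_rng(cohort_ss)

    # one fixed mixing vector per cohort: motion artifact timecourse is an
    # exact linear combination of the (raw) 24-parameter expansion
    w24 = cohort_rng.normal(size=24)
    w24[12:] *= 0.3  # squares contribute less
    w24b = cohort_rng.normal(size=24)
    w24b[12:] *= 0.3

    groups = ["HC"] * config.n_hc + ["AD"] * config.n_ad
    amps = config.artifact_amplitudes
    T = config.n_volumes

    subjects: list[SubjectDataset] = []
    network_tcs: dict[str, np.ndarray] = {}
    artifact_tcs: dict[str, dict[str, np.ndarray]] = {n: {} for n in ARTIFACT_NAMES}
    gm_vol: dict[str, float] = {}
    planted: dict[str, float] = {}

    nyq = 1.0 / (2.0 * config.tr_s)
    for i, group in enumerate(groups):
        sid = f"sub-{i + 1:03d}"
        rng = np.random.default_rng(subj_ss[i])

        # motion: per-subject target displacement drawn from the group law
        target = rng.normal(config.motion_mrd_mm[group], config.motion_mrd_sd_mm[group])
        target = max(target, 0.01)
        motion6, _ = generate_motion_params(T, target, rng)

        gain = config.network_amplitude * float(
            np.exp(rng.normal(0.0, config.network_amp_subject_sd))
        )
        tcs = np.stack(
            [bandlimited_timecourse(rng, T, config.tr_s, 0.01, 0.1) for _ in range(config.n_templates)]
        )
        tcs *= gain
        eff = config.dmn_deficit if group == "AD" else 1.0

        data = np.repeat(baseline_map[..., None], T, axis=3).astype(float)
        for k in range(config.n_templates):
            m = (ant_map + eff * post_map) if k == dmn_index else template_maps[k]
            data += m[..., None] * tcs[k]

        # artifacts
        atc = {}
        # Motion artifact waveforms are exact linear functions of the
        # 24-parameter expansion (so motion regression can remove them
        # fully); the per-subject load is a separate susceptibility factor,
        # identically distributed in both groups.
        m24raw = _expand_motion_24_raw(motion6)
        for name, w in (("motion_edge", w24), ("motion_global", w24b)):
            raw = m24raw @ w
            sd = raw.std()
            raw = raw / sd if sd > 0 else raw
            atc[name] = amps[name] * np.exp(rng.normal(0.0, 0.8)) * raw
        atc["csf_pulsation"] = (
            amps["csf_pulsation"]
            * np.exp(rng.normal(0.0, 0.6))
            * bandlimited_timecourse(rng, T, config.tr_s, 0.06, min(0.19, 0.95 * nyq))
        )
        atc["wm_drift"] = (
            amps["wm_drift"]
            * np.exp(rng.normal(0.0, 0.6))
            * bandlimited_timecourse(rng, T, config.tr_s, 0.005, 0.025)
        )
        rho = config.vessel_signal_coupling
        vbase = bandlimited_timecourse(rng, T, config.tr_s, 0.07, min(0.19, 0.95 * nyq))
        dmn_tc = tcs[dmn_index]
        dmn_unit = dmn_tc / dmn_tc.std() if dmn_tc.std() > 0 else dmn_tc
        atc["vessel"] = (
            amps["vessel"]
            * np.exp(rng.normal(0.0, 0.6))
            * (rho * dmn_unit + np.sqrt(max(0.0, 1.0 - rho**2)) * vbase)
        )
        ramp = np.linspace(-1, 1, T)
        slow = np.sin(2 * np.pi * 0.003 * config.tr_s * np.arange(T) + rng.uniform(0, 2 * np.pi))
        drift = ramp + 0.5 * slow
        drift = (drift - drift.mean()) / drift.std()
        atc["scanner_drift"] = amps["scanner_drift"] * np.exp(rng.normal(0.0, 0.5)) * drift

        for name in ARTIFACT_NAMES:
            data += artifact_maps[name][..., None] * atc[name]
            artifact_tcs[name][sid] = atc[name]

        if config.noise_sd > 0:
            noise = rng.normal(0.0, config.noise_sd, size=data.shape)
            data += noise * masks.brain[..., None]

        gmv = float(rng.normal(config.gm_volume_mean[group], config.gm_volume_sd[group]))
        subj = SubjectDataset(subject_id=sid, group=group, data=data, motion6=motion6, gm_volume=gmv)
        subj.validate()
        subjects.append(subj)
        network_tcs[sid] = tcs
        gm_vol[sid] = gmv
        planted[sid] = eff

    cohort = CohortDataset(
        subjects=subjects,
        masks=masks,
        grid_shape=config.grid_shape,
        voxel_size_mm=config.voxel_size_mm,
    )
    truth = GroundTruth(
        template_maps=template_maps,
        dmn_index=dmn_index,
        dmn_posterior_map=post_map,
        dmn_anterior_map=ant_map,
        network_timecourses=network_tcs,
        artifact_components=[
            ArtifactComponent(name, artifact_maps[name], artifact_tcs[name])
            for name in ARTIFACT_NAMES
        ],
        masks=masks,
        gm_volume=gm_vol,
        planted_effect=planted,
        baseline_map=baseline_map,
    )

    # planted-truth invariants
    sphere = masks.seed_sphere
    overlap = (template_maps[dmn_index][sphere] > 0.25).mean()
    if overlap <= 0.5:
        raise ConfigurationError("DMN template does not overlap the seed sphere")
    for comp in truth.artifact_components:
        if np.any((comp.spatial_map != 0) & ~masks.brain):
            raise ConfigurationError(f"artifact {comp.name} leaves the brain mask")
    return cohort, truth
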