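"""On-disk formats: NIfTI images, 6-column motion text files, TSV tables.

A written cohort round-trips bit-exactly: 4D data and masks as NIfTI-1
(float64 / uint8), motion parameters as whitespace-delimited text
(3 translations in mm then 3 rotations in rad, one row per volume), and
the per-subject covariate table as TSV.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .simulate import CohortDataset, MaskSet, SubjectDataset

__all__ = [
    "read_motion_par",
    "write_motion_par",
    "write_cohort",
    "read_cohort",
    "save_map",
]

_MASK_NAMES = ("brain", "gm", "wm", "csf", "ventricle_roi", "wm_roi", "seed_sphere", "posterior_roi")


def write_motion_par(motion6: np.ndarray, path) -> None:
    motion6 = np.asarray(motion6)
    if motion6.ndim != 2 or motion6.shape[1] != 6:
        raise ValueError("motion6 must be (T, 6)")
    np.savetxt(path, motion6, fmt="%.6e")


def read_motion_par(path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 columns, got {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric value") from exc
    if not rows:
        raise ValueError(f"{path}: empty motion file")
    return np.asarray(rows)


def save_map(values: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a 3D/4D array as NIfTI-1."""
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float64), affine)
    nib.save(img, str(path))


def write_cohort(cohort: CohortDataset, directory) -> pd.DataFrame:
    """Write one 4D NIfTI + motion file per subject, all masks, and a
    covariate TSV. Returns the file manifest (also written as TSV)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = cohort.affine
    rows = []
    for subj in cohort.subjects:
        img_path = directory / f"{subj.subject_id}_bold.nii"
        save_map(subj.data, affine, img_path)
        mot_path = directory / f"{subj.subject_id}_motion.par"
        write_motion_par(subj.motion6, mot_path)
        rows.append(
            {
                "subject_id": subj.subject_id,
                "group": subj.group,
                "image": img_path.name,
                "motion": mot_path.name,
                "gm_volume": subj.gm_volume,
            }
        )
    mask_dir = directory / "masks"
    mask_dir.mkdir(exist_ok=True)
    for name in _MASK_NAMES:
        arr = getattr(cohort.masks, name).astype(np.uint8)
        nib.save(nib.Nifti1Image(arr, affine), str(mask_dir / f"{name}.nii"))
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "participants.tsv", sep="\t", index=False)
    return manifest


def read_cohort(directory) -> CohortDataset:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "participants.tsv", sep="\t")
    masks = {}
    for name in _MASK_NAMES:
        img = nib.load(str(directory / "masks" / f"{name}.nii"))
        masks[name] = np.asarray(img.dataobj).astype(bool)
    maskset = MaskSet(**masks)
    subjects = []
    voxel = None
    for _, row in manifest.iterrows():
        img = nib.load(str(directory / row["image"]))
        data = np.asarray(img.dataobj, dtype=np.float64)
        voxel = float(img.header.get_zooms()[0])
        subjects.append(
            SubjectDataset(
                subject_id=row["subject_id"],
                group=row["group"],
                data=data,
                motion6=read_motion_par(directory / row["motion"]),
                gm_volume=float(row["gm_volume"]),
            )
        )
    grid = subjects[0].data.shape[:3]
    return CohortDataset(subjects=subjects, masks=maskset, grid_shape=grid, voxel_size_mm=voxel)
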