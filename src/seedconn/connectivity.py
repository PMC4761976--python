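"""Seed time courses, voxelwise correlation maps and the Fisher transform."""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import BrainMask, Image4D, ROIAtlas

__all__ = [
    "SubjectCorrMap",
    "roi_timecourse",
    "corr_map",
    "fisher_z",
    "inverse_fisher",
]

# |r| is clipped here before atanh so numerically perfect correlations
# (e.g. the seed voxels against themselves) stay finite in z-space.
_R_CLIP = 1.0 - 1e-7


def fisher_z(r):
    """Fisher z-transform, z = atanh(r), with |r| clipped to 1 - 1e-7.

    Accepts scalars or arrays; raises if any |r| > 1.
    """
    r = np.asarray(r, dtype=np.float64)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("correlations must satisfy |r| <= 1")
    out = np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))
    return float(out) if out.ndim == 0 else out


def inverse_fisher(z):
    """Inverse Fisher transform, r = tanh(z); maps the real line into (-1, 1)."""
    out = np.tanh(np.asarray(z, dtype=np.float64))
    return float(out) if out.ndim == 0 else out


@dataclass
class SubjectCorrMap:
    """Per-subject voxelwise seed-correlation map.

    ``valid_mask`` marks voxels where the correlation is defined (in-mask
    and nonzero variance); ``r_map``/``z_map`` are undefined (0) elsewhere.
    """

    r_map: np.ndarray
    z_map: np.ndarray
    valid_mask: np.ndarray
    seed_name: str = "seed"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.r_map.shape != self.valid_mask.shape:
            raise ValueError("r_map and valid_mask shapes differ")
        r_valid = self.r_map[self.valid_mask]
        if r_valid.size and np.any(np.abs(r_valid) > 1 + 1e-9):
            raise ValueError("r_map contains values outside [-1, 1]")

    @classmethod
    def from_r(cls, r_map, valid_mask, seed_name="seed", subject_id=""):
        r_map = np.asarray(r_map, dtype=np.float64)
        valid = np.asarray(valid_mask, dtype=bool)
        z = np.zeros_like(r_map)
        z[valid] = fisher_z(r_map[valid])
        return cls(r_map, z, valid, seed_name, subject_id)

    def save(self, out_dir: str | Path, voxel_dims=(0.469, 0.469, 1.0)) -> None:
        import nibabel as nib

        out_dir = Path(out_dir)
        affine = np.diag([*voxel_dims, 1.0])
        stem = f"{self.subject_id or 'subject'}_{self.seed_name}"
        for suffix, vol in (("r", self.r_map), ("z", self.z_map)):
            nib.save(
                nib.Nifti1Image(vol.astype(np.float32), affine),
                str(out_dir / f"{stem}_{suffix}.nii.gz"),
            )


def roi_timecourse(
    img: Image4D, atlas: ROIAtlas, roi: str, mask: BrainMask | None = None
) -> np.ndarray:
    """Unweighted mean time course over an ROI's (in-mask) voxels."""
    roi_mask = atlas.roi_mask(roi)
    if mask is not None:
        roi_mask = roi_mask & mask.data
    if not roi_mask.any():
        raise ValueError(f"ROI {roi!r} has no voxels inside the brain mask")
    return img.data[roi_mask].mean(axis=0, dtype=np.float64)


def corr_map(
    img: Image4D,
    seed_ts: np.ndarray,
    mask: BrainMask,
    seed_name: str = "seed",
    subject_id: str = "",
) -> SubjectCorrMap:
    """Pearson correlation of every in-mask voxel series with the seed.

    Voxels with zero temporal variance are excluded from ``valid_mask``
    rather than assigned r = 0: the correlation is undefined there, and
    excluding them keeps them out of any downstream network map.
    """
    seed_ts = np.asarray(seed_ts, dtype=np.float64)
    if seed_ts.ndim != 1 or seed_ts.size != img.n_volumes:
        raise ValueError("seed series length must match the image time axis")
    seed_c = seed_ts - seed_ts.mean()
    seed_ss = float(seed_c @ seed_c)
    if seed_ss <= 0:
        raise ValueError("seed time course has zero variance")

    vox = np.asarray(img.data, dtype=np.float64)[mask.data]  # (n, T)
    vox_c = vox - vox.mean(axis=1, keepdims=True)
    vox_ss = np.einsum("ij,ij->i", vox_c, vox_c)
    nonzero = vox_ss > 0
    r_flat = np.zeros(vox.shape[0])
    r_flat[nonzero] = (vox_c[nonzero] @ seed_c) / np.sqrt(vox_ss[nonzero] * seed_ss)
    np.clip(r_flat, -1.0, 1.0, out=r_flat)

    r_map = np.zeros(img.spatial_shape)
    valid = np.zeros(img.spatial_shape, dtype=bool)
    r_map[mask.data] = r_flat
    valid[mask.data] = nonzero
    r_map[~valid] = 0.0
    return SubjectCorrMap.from_r(r_map, valid, seed_name, subject_id)
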