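"""Core containers: 4D functional images, brain masks and ROI atlases.

These are thin wrappers around numpy arrays that carry the acquisition
geometry (voxel dimensions in mm, repetition time in s) needed by the
preprocessing and connectivity stages, plus NIfTI-1 round-tripping via
nibabel.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["AcquisitionSpec", "Image4D", "BrainMask", "ROIAtlas"]


@dataclass(frozen=True)
class AcquisitionSpec:
    """EPI acquisition geometry: grid, repetition time and voxel size.

    Defaults follow a rodent resting-state protocol: a 64x64 in-plane
    matrix, 11 coronal slices, 300 volumes at TR = 1 s, and
    0.469 x 0.469 x 1.0 mm voxels.
    """

    nx: int = 64
    ny: int = 64
    nz: int = 11
    n_volumes: int = 300
    tr: float = 1.0
    voxel_dims: tuple[float, float, float] = (0.469, 0.469, 1.0)

    def __post_init__(self) -> None:
        for name in ("nx", "ny", "nz", "n_volumes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.tr <= 0:
            raise ValueError(f"tr must be > 0, got {self.tr}")
        if any(d <= 0 for d in self.voxel_dims):
            raise ValueError(f"voxel_dims must be positive, got {self.voxel_dims}")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return (self.nx, self.ny, self.nz, self.n_volumes)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def nyquist(self) -> float:
        return 0.5 / self.tr


@dataclass
class Image4D:
    """A 4D BOLD-like volume: (nx, ny, nz, T) with voxel size and TR."""

    data: np.ndarray
    voxel_dims: tuple[float, float, float] = (0.469, 0.469, 1.0)
    tr: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 time points")
        if self.tr <= 0:
            raise ValueError(f"tr must be > 0, got {self.tr}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def to_nifti(self) -> nib.Nifti1Image:
        dx, dy, dz = self.voxel_dims
        affine = np.diag([dx, dy, dz, 1.0])
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), affine)
        img.header.set_zooms((dx, dy, dz, self.tr))
        img.header.set_xyzt_units(xyz="mm", t="sec")
        return img

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "Image4D":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()
        data = np.asanyarray(img.dataobj, dtype=np.float32)
        if data.ndim != 4:
            raise ValueError(f"{path}: expected a 4D image, got shape {data.shape}")
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
        return cls(data=data, voxel_dims=tuple(float(z) for z in zooms[:3]), tr=tr)


@dataclass
class BrainMask:
    """Boolean in-brain mask on the functional grid."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D mask, got shape {self.data.shape}")
        if self.n_voxels < 1:
            raise ValueError("brain mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def save(self, path: str | Path, voxel_dims=(0.469, 0.469, 1.0)) -> None:
        affine = np.diag([*voxel_dims, 1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), affine), str(path))


@dataclass
class ROIAtlas:
    """Integer label volume plus a label -> name table.

    Label 0 is background (non-brain or unlabeled); labels 1..K are the
    regions of interest. ``brain_mask`` marks the full brain extent, which
    is a superset of the labeled voxels; if absent it falls back to
    ``labels > 0``.
    """

    labels: np.ndarray
    names: list[str]
    brain_mask: np.ndarray | None = None
    voxel_dims: tuple[float, float, float] = (0.469, 0.469, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected 3D label volume, got {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label volume must be integer-valued")
        present = set(np.unique(self.labels)) - {0}
        if present - set(range(1, len(self.names) + 1)):
            raise ValueError("label volume contains labels without a name entry")
        if self.brain_mask is not None:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.labels.shape:
                raise ValueError("brain_mask grid does not match label grid")
            if np.any((self.labels > 0) & ~self.brain_mask):
                raise ValueError("labeled voxels must lie inside the brain mask")

    @property
    def n_rois(self) -> int:
        return len(self.names)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def label_of(self, name: str) -> int:
        try:
            return self.names.index(name) + 1
        except ValueError:
            raise KeyError(
                f"ROI {name!r} not in atlas (known: {', '.join(self.names)})"
            ) from None

    def roi_mask(self, name: str) -> np.ndarray:
        return self.labels == self.label_of(name)

    def brain(self) -> np.ndarray:
        if self.brain_mask is not None:
            return self.brain_mask
        return self.labels > 0

    def roi_sizes(self) -> dict[str, int]:
        counts = np.bincount(self.labels.ravel(), minlength=self.n_rois + 1)
        return {name: int(counts[i + 1]) for i, name in enumerate(self.names)}

    def save(self, path: str | Path, names_path: str | Path | None = None) -> None:
        """Write labels (and brain mask) as NIfTI-1 and names as TSV."""
        path = Path(path)
        affine = np.diag([*self.voxel_dims, 1.0])
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), affine), str(path))
        if self.brain_mask is not None:
            mask_path = path.parent / (path.name.replace(".nii", "_brainmask.nii"))
            nib.save(
                nib.Nifti1Image(self.brain_mask.astype(np.uint8), affine),
                str(mask_path),
            )
        if names_path is None:
            names_path = path.parent / (path.name.split(".nii")[0] + "_names.tsv")
        table = pd.DataFrame(
            {"label": np.arange(1, self.n_rois + 1), "name": self.names}
        )
        table.to_csv(names_path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path, names_path: str | Path | None = None) -> "ROIAtlas":
        path = Path(path)
        img = nib.load(str(path))
        labels = np.asanyarray(img.dataobj).astype(np.int32)
        zooms = img.header.get_zooms()[:3]
        if names_path is None:
            names_path = path.parent / (path.name.split(".nii")[0] + "_names.tsv")
        table = pd.read_csv(names_path, sep="\t").sort_values("label")
        names = [str(n) for n in table["name"]]
        mask_path = path.parent / (path.name.replace(".nii", "_brainmask.nii"))
        brain = None
        if mask_path.exists():
            brain = np.asanyarray(nib.load(str(mask_path)).dataobj).astype(bool)
        return cls(
            labels=labels,
            names=names,
            brain_mask=brain,
            voxel_dims=tuple(float(z) for z in zooms),
        )
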