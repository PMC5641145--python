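"""NIfTI volume/mask I/O and CSV feature tables.

Volumes and masks live on one shared voxel grid (the data are co-registered
upstream), so world coordinates are never needed: voxel indices are 0-based
and physical spacing (mm per axis, possibly anisotropic — e.g. 4 mm slices)
enters only the shape features.  No resampling or intensity normalization is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .names import canonical_rank


@dataclass
class VolumeImage:
    """A 3D scalar intensity grid with physical voxel spacing."""

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    modality: str

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.intensities.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive numbers, got {self.spacing}")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("volume contains non-finite intensities")


@dataclass
class TumorMask:
    """Binary region-of-interest grid aligned to a VolumeImage."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"mask must be 3D, got {self.voxels.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if not self.voxels.any():
            raise ValueError("empty region of interest")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


def _load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got {data.ndim}D in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def read_volume(path, modality: str) -> VolumeImage:
    """Load a 3D NIfTI volume; spacing is taken from the file header."""
    data, spacing = _load_nifti(path)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"volume {path} contains non-finite voxels")
    return VolumeImage(data, spacing, modality)


def write_volume(volume: VolumeImage, path) -> None:
    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.intensities.astype(np.float64), affine), str(path))


def read_mask(path, reference: VolumeImage) -> TumorMask:
    """Load a binary mask and check alignment with its reference volume.

    Any nonzero voxel value is treated as foreground.
    """
    data, spacing = _load_nifti(path)
    if data.shape != reference.intensities.shape:
        raise ValueError(
            f"mask grid {data.shape} does not match reference grid "
            f"{reference.intensities.shape}"
        )
    if not np.allclose(spacing, reference.spacing, rtol=1e-4):
        raise ValueError(
            f"mask spacing {spacing} does not match reference spacing {reference.spacing}"
        )
    binary = data != 0
    if not binary.any():
        raise ValueError("empty region of interest")
    return TumorMask(binary, reference.spacing)


def write_mask(mask: TumorMask, path) -> None:
    affine = np.diag(list(mask.spacing) + [1.0])
    nib.save(nib.Nifti1Image(mask.voxels.astype(np.uint8), affine), str(path))


def write_feature_table(records, path) -> pd.DataFrame:
    """Write one row per patient with feature columns in canonical order.

    ``records`` is a list of ``(patient_id, {feature_name: value})`` pairs;
    every record must share an identical feature-name set.  Column order is
    determined by the canonical feature dictionary, never by input order.
    """
    records = list(records)
    if records:
        keys0 = set(records[0][1])
        for pid, feats in records[1:]:
            if set(feats) != keys0:
                raise ValueError(f"inconsistent feature set for patient {pid!r}")
        columns = sorted(keys0, key=canonical_rank)
    else:
        columns = []
    df = pd.DataFrame(
        [[feats[c] for c in columns] for _, feats in records],
        columns=columns,
        index=pd.Index([pid for pid, _ in records], name="id"),
    )
    df.to_csv(path, float_format="%.12g")
    return df


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="id")
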