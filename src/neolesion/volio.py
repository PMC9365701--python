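"""NIfTI volume I/O and longitudinal case handling.

Volumes are reoriented to the closest canonical (RAS) axis order on load so
that plane names are deterministic: axis 0 is the sagittal slicing axis,
axis 1 coronal, axis 2 axial. Baseline and follow-up scans of a case must
already be rigidly co-registered onto a common grid; this module verifies
that but performs no registration itself.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import (DimensionalityError, GridMismatchError, LayoutError,
                     MaskValueError, RegistrationError)

BASELINE_NAME = "flair_time01.nii.gz"
FOLLOWUP_NAME = "flair_time02.nii.gz"
GROUND_TRUTH_NAME = "ground_truth.nii.gz"


@dataclasses.dataclass
class Volume:
    """A 3D scalar grid with voxel spacing (mm) and voxel-to-world affine."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise DimensionalityError(
                f"expected a 3D volume, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats: {self.spacing}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing, self.affine.copy())


@dataclasses.dataclass
class BinaryMask:
    """A {0,1}-valued mask on the same grid as its companion volume."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D mask, got shape {self.data.shape}")
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise MaskValueError(
                f"mask values outside {{0,1}}: {vals[:10]}")
        self.data = self.data.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclasses.dataclass
class LongitudinalCase:
    """A registered (baseline, follow-up) pair with optional new-lesion GT."""

    patient_id: str
    baseline: Volume
    followup: Volume
    gt_new_lesions: BinaryMask | None = None

    def __post_init__(self):
        if self.baseline.shape != self.followup.shape:
            raise RegistrationError(
                f"baseline shape {self.baseline.shape} != follow-up "
                f"shape {self.followup.shape}")
        if not np.allclose(self.baseline.spacing, self.followup.spacing):
            raise RegistrationError(
                f"baseline spacing {self.baseline.spacing} != follow-up "
                f"spacing {self.followup.spacing}")
        if self.gt_new_lesions is not None:
            if self.gt_new_lesions.shape != self.followup.shape:
                raise GridMismatchError(
                    "ground-truth grid differs from follow-up grid")


def canonicalize(img: nib.Nifti1Image) -> nib.Nifti1Image:
    """Reorient to the closest canonical (RAS) axis order. Idempotent."""
    return nib.as_closest_canonical(img)


def read_volume(path) -> Volume:
    """Read a NIfTI file into a canonically oriented :class:`Volume`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = canonicalize(nib.load(str(path)))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path} has {data.ndim} dimensions; expected 3")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(np.asarray(data, dtype=np.float32), spacing, img.affine)


def read_mask(path) -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask(vol.data, vol.spacing, vol.affine)


def write_volume(vol: Volume, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def write_mask(mask: BinaryMask, path) -> None:
    """Write a binary mask as NIfTI; read_mask recovers data and spacing."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def load_case(case_dir) -> LongitudinalCase:
    """Load one patient directory (time-01/time-02 FLAIR, optional GT)."""
    case_dir = Path(case_dir)
    if not case_dir.is_dir():
        raise LayoutError(f"not a directory: {case_dir}")
    base_path = case_dir / BASELINE_NAME
    fup_path = case_dir / FOLLOWUP_NAME
    if not base_path.exists() or not fup_path.exists():
        raise LayoutError(
            f"{case_dir} must contain {BASELINE_NAME} and {FOLLOWUP_NAME}")
    baseline = read_volume(base_path)
    followup = read_volume(fup_path)
    gt_path = case_dir / GROUND_TRUTH_NAME
    gt = read_mask(gt_path) if gt_path.exists() else None
    return LongitudinalCase(case_dir.name, baseline, followup, gt)


def write_case(case: LongitudinalCase, out_dir) -> Path:
    """Write a case as an MSSEG-2-style patient directory."""
    out_dir = Path(out_dir) / case.patient_id
    write_volume(case.baseline, out_dir / BASELINE_NAME)
    write_volume(case.followup, out_dir / FOLLOWUP_NAME)
    if case.gt_new_lesions is not None:
        write_mask(case.gt_new_lesions, out_dir / GROUND_TRUTH_NAME)
    return out_dir
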