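"""Volume/mask I/O, SUV conversion and VOI geometry utilities.

Volumes are plain 3D numpy arrays indexed ``(x, y, z)`` with an anisotropic
voxel spacing in millimetres (PET-native grids; the default emulates a
5.3 x 5.3 x 5.0 mm reconstruction). Masks must share the grid of their parent
volume -- no resampling happens anywhere in this package. Voxel values are
either standardized uptake values (SUV) or activity concentrations in kBq/ml
prior to :func:`suv_convert`.

VOI extraction uses a fixed raster order (x varying fastest, then y, then z)
so that downstream feature values are reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "PETVolume",
    "VOIMask",
    "VOISample",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "suv_convert",
    "extract_voi",
    "volume_to_voxels",
]

VALID_UNITS = ("SUV", "kBq/ml")
VALID_SITES = ("bone", "lymph_node", "other")


@dataclass
class PETVolume:
    """A 3D PET image: scalar grid plus geometry and a unit tag."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: str = "SUV"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(
                f"expected a 3D volume, got a {self.values.ndim}D array"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing_mm}")
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")

    @property
    def voxel_volume_cm3(self) -> float:
        return math.prod(self.spacing_mm) / 1000.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class VOIMask:
    """Binary lesion mask congruent with its parent volume, plus metadata."""

    mask: np.ndarray
    patient_id: str
    site: str
    lesion_id: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError(f"expected a 3D mask, got a {self.mask.ndim}D array")
        if not self.mask.any():
            raise ValueError("mask has no foreground voxel")
        if self.site not in VALID_SITES:
            raise ValueError(f"site must be one of {VALID_SITES}, got {self.site!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class VOISample:
    """The SUVs of one lesion's voxels, in raster order (x fastest)."""

    suv_values: np.ndarray
    voxel_volume_cm3: float

    def __post_init__(self) -> None:
        self.suv_values = np.asarray(self.suv_values, dtype=np.float64).ravel()
        if self.suv_values.size < 1:
            raise ValueError("VOI sample must contain at least one voxel")
        if self.voxel_volume_cm3 <= 0:
            raise ValueError("voxel volume must be positive")

    @property
    def n_voxels(self) -> int:
        return int(self.suv_values.size)

    @property
    def volume_cm3(self) -> float:
        return self.n_voxels * self.voxel_volume_cm3


def _affine(spacing_mm, origin_mm) -> np.ndarray:
    aff = np.diag([*spacing_mm, 1.0])
    aff[:3, 3] = origin_mm
    return aff


def write_volume(volume: PETVolume, path: str | Path) -> Path:
    """Write a volume to NIfTI-1; the unit tag goes into the descrip field."""
    path = Path(path)
    img = nib.Nifti1Image(volume.values, _affine(volume.spacing_mm, volume.origin_mm))
    img.header["descrip"] = f"unit={volume.unit}".encode()
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, path)
    return path


def read_volume(path: str | Path) -> PETVolume:
    """Read a 3D NIfTI-1 volume; rejects non-3D payloads explicitly."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[3] == 1 else data
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D volume, file holds a {data.ndim}D payload"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    descrip = bytes(img.header["descrip"].tobytes()).split(b"\x00")[0].decode(errors="replace")
    unit = descrip.removeprefix("unit=") if descrip.startswith("unit=") else "SUV"
    return PETVolume(values=data, spacing_mm=spacing, origin_mm=origin, unit=unit)


def write_mask(mask: VOIMask, path: str | Path, spacing_mm=(1.0, 1.0, 1.0)) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), _affine(spacing_mm, (0, 0, 0)))
    img.header.set_zooms(spacing_mm)
    nib.save(img, path)
    return path


def read_mask(path: str | Path, patient_id: str, site: str, lesion_id: str) -> VOIMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask, file holds a {data.ndim}D payload")
    return VOIMask(mask=data > 0, patient_id=patient_id, site=site, lesion_id=lesion_id)


def suv_convert(
    volume: PETVolume, body_weight_g: float, injected_activity_mbq: float
) -> PETVolume:
    """Convert an activity-concentration volume (kBq/ml) to SUV.

    SUV = concentration[Bq/ml] * body weight[g] / injected activity[Bq];
    decay correction is assumed to have been applied upstream.
    """
    if volume.unit != "kBq/ml":
        raise ValueError(f"volume unit must be 'kBq/ml', got {volume.unit!r}")
    if body_weight_g <= 0:
        raise ValueError(f"body weight must be positive, got {body_weight_g}")
    if injected_activity_mbq <= 0:
        raise ValueError(f"injected activity must be positive, got {injected_activity_mbq}")
    suv = volume.values * 1e3 * body_weight_g / (injected_activity_mbq * 1e6)
    return PETVolume(
        values=suv, spacing_mm=volume.spacing_mm, origin_mm=volume.origin_mm, unit="SUV"
    )


def extract_voi(volume: PETVolume, mask: VOIMask) -> VOISample:
    """Pull the foreground voxel SUVs of one lesion out of a volume.

    Values come out in raster order with x varying fastest, so repeated
    extraction of the same lesion is bit-identical.
    """
    if volume.values.shape != mask.mask.shape:
        raise ValueError(
            f"volume shape {volume.values.shape} != mask shape {mask.mask.shape}"
        )
    if not mask.mask.any():
        raise ValueError("mask has no foreground voxel")
    # transpose to (z, y, x) so C-order flattening makes x the fastest axis
    vals = np.transpose(volume.values, (2, 1, 0))[np.transpose(mask.mask, (2, 1, 0))]
    return VOISample(suv_values=vals, voxel_volume_cm3=volume.voxel_volume_cm3)


def volume_to_voxels(volume_cm3: float, spacing_mm) -> int:
    """How many whole voxels fit in a given volume (floor division).

    At 5 mm isotropic spacing the 7.8 cm^3 smallest-lesion bound corresponds
    to 62 voxels.
    """
    if volume_cm3 <= 0:
        raise ValueError(f"volume must be positive, got {volume_cm3}")
    spacing = tuple(float(s) for s in spacing_mm)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive values, got {spacing_mm}")
    voxel_volume_cm3 = math.prod(spacing) / 1000.0
    return int(math.floor(volume_cm3 / voxel_volume_cm3))
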