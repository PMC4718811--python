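"""3D brain volumes, masks, cohorts, and the preprocessing primitives.

A :class:`BrainVolume` is a scalar grid with anisotropic voxel spacing and a
bregma-anchored origin, the unit of all image math in this package.  Axis
convention: ``x`` = medial-lateral (+ right), ``y`` = anterior-posterior
(+ anterior), ``z`` = dorsal-ventral stored as positive depth below bregma.
All coordinates live in the x10-scaled millimeter frame conventionally used
for rodent PET (raw 0.3875 x 0.3875 x 0.775 mm voxels become 3.875 x 3.875 x
7.75 mm), so that human-brain tooling defaults apply.

Preprocessing mirrors the standard small-animal FDG pipeline: voxel-size
scaling, Gaussian smoothing (FWHM given in mm), brain masking, and division
by the global in-mask mean ("global normalization").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "BrainVolume",
    "BrainMask",
    "ScanSet",
    "scale_voxels",
    "gaussian_smooth",
    "global_normalize",
    "read_volume",
    "write_volume",
]

#: FWHM of a Gaussian = sigma * sqrt(8 ln 2); this is the inverse factor.
FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


@dataclass(frozen=True)
class BrainVolume:
    """A 3D scalar image with voxel spacing (mm) and bregma-anchored origin."""

    values: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ValueError("volume contains non-finite values")
        spacing = tuple(float(s) for s in self.voxel_spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"voxel spacing must be 3 positive reals, got {spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "voxel_spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin_mm[axis] + self.voxel_spacing_mm[axis] * np.arange(n)

    def with_values(self, values: np.ndarray) -> "BrainVolume":
        """Same lattice, new data."""
        return BrainVolume(values, self.voxel_spacing_mm, self.origin_mm)


@dataclass(frozen=True)
class BrainMask:
    """A binary grid on the same lattice as its associated volumes."""

    values: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values).astype(bool)
        if values.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={values.ndim}")
        if not values.any():
            raise ValueError("mask is empty")
        object.__setattr__(self, "values", values)
        object.__setattr__(
            self, "voxel_spacing_mm", tuple(float(s) for s in self.voxel_spacing_mm)
        )
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


@dataclass
class ScanSet:
    """Ordered cohort of subject volumes sharing one lattice.

    ``subject_ids`` and ``volumes`` are parallel; ``group`` labels the age
    group (e.g. ``"5wk"``).
    """

    subject_ids: list[str]
    volumes: list[BrainVolume]
    group: str = ""

    def __post_init__(self) -> None:
        if len(self.subject_ids) != len(self.volumes):
            raise ValueError("subject_ids and volumes length mismatch")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject IDs")
        shapes = {v.shape for v in self.volumes}
        if len(shapes) > 1:
            raise ValueError(f"volumes on different grids: {shapes}")

    def __len__(self) -> int:
        return len(self.volumes)

    def __iter__(self) -> Iterator[tuple[str, BrainVolume]]:
        return iter(zip(self.subject_ids, self.volumes))

    def stack(self) -> np.ndarray:
        """(n_subjects, nx, ny, nz) array of the cohort."""
        return np.stack([v.values for v in self.volumes])

    def map(self, fn) -> "ScanSet":
        """Apply ``fn`` to every volume, preserving order and IDs."""
        return ScanSet(list(self.subject_ids), [fn(v) for v in self.volumes], self.group)


def scale_voxels(volume: BrainVolume, factor: float) -> BrainVolume:
    """Multiply the voxel spacing (and origin) by ``factor``; data untouched.

    This is the metadata-only x10 rescaling that maps rodent brains into the
    human-sized coordinate frame expected by neuroimaging defaults.
    """
    if factor <= 0:
        raise ValueError(f"scale factor must be positive, got {factor}")
    spacing = tuple(s * factor for s in volume.voxel_spacing_mm)
    origin = tuple(o * factor for o in volume.origin_mm)
    return BrainVolume(volume.values, spacing, origin)


def gaussian_smooth(volume: BrainVolume, fwhm_mm: float) -> BrainVolume:
    """Separable Gaussian smoothing with an isotropic FWHM given in mm.

    Per-axis sigma in voxels is ``fwhm * FWHM_TO_SIGMA / spacing``; outside
    the grid the image is treated as zero (zero-padding boundary).
    """
    if fwhm_mm < 0:
        raise ValueError(f"FWHM must be non-negative, got {fwhm_mm}")
    if fwhm_mm == 0:
        return volume
    sigmas = [fwhm_mm * FWHM_TO_SIGMA / s for s in volume.voxel_spacing_mm]
    smoothed = ndimage.gaussian_filter(volume.values, sigma=sigmas, mode="constant")
    return volume.with_values(smoothed)


def global_normalize(volume: BrainVolume, mask: BrainMask) -> BrainVolume:
    """Divide every voxel by the mean over the brain mask.

    After the operation the in-mask mean is exactly 1, making subjects with
    different injected doses / global uptake comparable voxel-by-voxel.
    """
    if mask.shape != volume.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {volume.shape}")
    g = float(volume.values[mask.values].mean())
    if g <= 0:
        raise ValueError(f"in-mask mean must be positive to normalize, got {g:.6g}")
    return volume.with_values(volume.values / g)


def _affine(spacing: Sequence[float], origin: Sequence[float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(volume: BrainVolume | BrainMask, path: str | Path) -> Path:
    """Write a volume or mask as NIfTI-1 (float64 / uint8)."""
    path = Path(path)
    data = volume.values
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, _affine(volume.voxel_spacing_mm, volume.origin_mm))
    img.header.set_zooms(volume.voxel_spacing_mm)
    nib.save(img, path)
    return path


def read_volume(path: str | Path, as_mask: bool = False) -> BrainVolume | BrainMask:
    """Read a NIfTI-1 volume written by :func:`write_volume`."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    if as_mask:
        return BrainMask(data > 0.5, spacing, origin)
    return BrainVolume(data, spacing, origin)
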