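"""Spherical volumes of interest (VOIs) at stereotaxic coordinates.

The eight network nodes are spheres of radius 8 mm (in the x10-scaled frame;
0.8 mm physical) centered on stereotaxic (ML, DV, AP) coordinates relative
to bregma, three on the anterior default-mode component (bilateral dorsal
hippocampus, medial prefrontal cortex), one on the posterior default-mode
component (retrosplenial cortex), and bilateral pairs on the motor and
somatosensory components.

Coordinate mapping: world x = ML, y = AP, z = DV stored as positive depth,
with stereotaxic mm multiplied by 10 to address the scaled grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .volume import BrainMask, BrainVolume, ScanSet

__all__ = [
    "VOISpec",
    "VOIMatrix",
    "default_vois",
    "read_voi_table",
    "make_voi_mask",
    "extract_voi_means",
]

#: Stereotaxic-to-grid scale: atlas mm -> scaled-frame mm.
ATLAS_SCALE = 10.0

#: Default sphere radius in the scaled frame (0.8 mm physical).
DEFAULT_RADIUS_MM = 8.0


@dataclass(frozen=True)
class VOISpec:
    """One named spherical region: atlas coordinates are UNscaled mm."""

    name: str
    abbreviation: str
    ml_mm: float
    dv_mm: float
    ap_mm: float
    component: str = ""
    radius_mm: float = DEFAULT_RADIUS_MM

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError(f"VOI radius must be positive, got {self.radius_mm}")

    @property
    def center_mm(self) -> tuple[float, float, float]:
        """Sphere center in the scaled world frame (x=ML, y=AP, z=DV depth)."""
        return (
            self.ml_mm * ATLAS_SCALE,
            self.ap_mm * ATLAS_SCALE,
            self.dv_mm * ATLAS_SCALE,
        )


@dataclass
class VOIMatrix:
    """subjects x VOIs matrix of mean normalized uptake for one age group."""

    values: np.ndarray
    subject_ids: list[str]
    voi_names: list[str]
    group: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("VOIMatrix must be 2D (subjects x VOIs)")
        if self.values.shape != (len(self.subject_ids), len(self.voi_names)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.subject_ids)} subjects x {len(self.voi_names)} VOIs"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("VOIMatrix contains non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_vois(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.voi_names)


def read_voi_table(path: str | Path) -> list[VOISpec]:
    """Read a TSV with columns name, abbreviation, ml_mm, dv_mm, ap_mm, component."""
    df = pd.read_csv(path, sep="\t")
    required = {"name", "abbreviation", "ml_mm", "dv_mm", "ap_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"VOI table missing columns: {sorted(missing)}")
    specs = []
    for row in df.itertuples(index=False):
        specs.append(
            VOISpec(
                name=row.name,
                abbreviation=row.abbreviation,
                ml_mm=float(row.ml_mm),
                dv_mm=float(row.dv_mm),
                ap_mm=float(row.ap_mm),
                component=getattr(row, "component", ""),
            )
        )
    return specs


def default_vois() -> list[VOISpec]:
    """The eight canonical network-node VOIs."""
    with resources.as_file(
        resources.files("metconn.data").joinpath("voi_table.tsv")
    ) as p:
        return read_voi_table(p)


def make_voi_mask(spec: VOISpec, grid: BrainVolume | BrainMask) -> BrainMask:
    """Mark voxels whose centers lie within ``radius_mm`` of the VOI center.

    Distances are Euclidean in physical mm, so anisotropic spacing is
    respected. Raises if the center falls outside the grid bounds or the
    resulting mask is empty.
    """
    cx, cy, cz = spec.center_mm
    xs = grid.origin_mm[0] + grid.voxel_spacing_mm[0] * np.arange(grid.shape[0])
    ys = grid.origin_mm[1] + grid.voxel_spacing_mm[1] * np.arange(grid.shape[1])
    zs = grid.origin_mm[2] + grid.voxel_spacing_mm[2] * np.arange(grid.shape[2])
    half = np.array(grid.voxel_spacing_mm) / 2.0
    lo = (xs[0] - half[0], ys[0] - half[1], zs[0] - half[2])
    hi = (xs[-1] + half[0], ys[-1] + half[1], zs[-1] + half[2])
    if not (lo[0] <= cx <= hi[0] and lo[1] <= cy <= hi[1] and lo[2] <= cz <= hi[2]):
        raise ValueError(
            f"VOI {spec.abbreviation!r} center {spec.center_mm} outside grid "
            f"bounds {lo}..{hi}"
        )
    d2 = (
        (xs - cx)[:, None, None] ** 2
        + (ys - cy)[None, :, None] ** 2
        + (zs - cz)[None, None, :] ** 2
    )
    inside = d2 <= spec.radius_mm**2
    if not inside.any():
        raise ValueError(
            f"VOI {spec.abbreviation!r}: no voxel center within "
            f"{spec.radius_mm} mm of {spec.center_mm}"
        )
    return BrainMask(inside, grid.voxel_spacing_mm, grid.origin_mm)


def extract_voi_means(scans: ScanSet, masks: dict[str, BrainMask]) -> VOIMatrix:
    """Mean uptake of each subject over each VOI mask, in manifest order."""
    names = list(masks.keys())
    first = next(iter(masks.values()))
    if scans.volumes and scans.volumes[0].shape != first.shape:
        raise ValueError(
            f"scan grid {scans.volumes[0].shape} != mask grid {first.shape}"
        )
    flat = [masks[n].values for n in names]
    out = np.empty((len(scans), len(names)))
    for i, vol in enumerate(scans.volumes):
        for j, m in enumerate(flat):
            out[i, j] = vol.values[m].mean()
    return VOIMatrix(out, list(scans.subject_ids), names, scans.group)
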