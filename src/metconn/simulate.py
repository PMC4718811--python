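"""Synthetic multi-subject FDG-PET cohorts with planted ground truth.

The generator emulates the design of a cross-sectional maturation study:
three age groups (default 30 / 30 / 28 subjects at 5, 10 and 15 weeks) of
pre-aligned 3D uptake volumes on a shared grid.  Each volume is

    background + sum_j loading_ij * support_j + noise,   then smoothed,

where ``background`` is a fixed smooth ellipsoidal ("brain-shaped")
intensity field, ``support_j`` is a spherical indicator at the j-th VOI
center, and per-subject loadings are drawn from a group-specific
multivariate normal.  The loading means encode the age trend in regional
uptake (anterior increase, posterior decrease) and the loading covariance
encodes the across-subject interregional coupling, which by default
strengthens along the anterior-posterior axis with age.  Because the signal
enters as scalar loadings on fixed spherical supports, the VOI-extraction
stage recovers the planted covariance structure up to noise and smoothing
attenuation.

Randomness: one :class:`numpy.random.SeedSequence` per cohort, split per
subject by ``(group index, subject index)`` so volumes are reproducible
independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .voi import ATLAS_SCALE, VOISpec, default_vois, make_voi_mask
from .volume import BrainMask, BrainVolume, ScanSet, gaussian_smooth, write_volume

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_cohort",
    "plant_component_maps",
    "generate_component_cohort",
    "default_regional_means",
    "default_voi_covariance",
    "write_cohort",
]

#: Brain ellipsoid in the scaled mm frame: center and semi-axes.
_BRAIN_CENTER = np.array([0.0, -12.0, 28.0])
_BRAIN_SEMI = np.array([70.0, 85.0, 45.0])
_BACKGROUND_PEAK = 100.0

#: Default age-group labels, oldest last.
AGE_GROUPS = ("5wk", "10wk", "15wk")

#: Anterior nodes gain uptake with age, posterior nodes lose it.
_ANTERIOR = ("MedF", "Mot_L", "Mot_R", "SS_L", "SS_R")
_POSTERIOR = ("Hp_L", "Hp_R", "Rsp")


def default_regional_means(
    groups: tuple[str, ...] = AGE_GROUPS,
    vois: list[VOISpec] | None = None,
) -> dict[str, dict[str, float]]:
    """Per-group mean loading per VOI (arbitrary uptake units).

    Baseline 10 on a background peak of 100; anterior regions gain
    +0, +1.0, +1.5 across the three ages while posterior regions lose
    -0, -0.5, -1.0 — the anterior-increase / posterior-decrease trend.
    """
    vois = vois if vois is not None else default_vois()
    gain = {g: i for i, g in enumerate(groups)}
    out: dict[str, dict[str, float]] = {}
    anterior_steps = [0.0, 1.0, 1.5]
    posterior_steps = [0.0, -0.5, -1.0]
    for g in groups:
        i = min(gain[g], 2)
        out[g] = {}
        for v in vois:
            base = 10.0
            if v.abbreviation in _ANTERIOR:
                out[g][v.abbreviation] = base + anterior_steps[i]
            else:
                out[g][v.abbreviation] = base + posterior_steps[i]
    return out


def default_voi_covariance(
    groups: tuple[str, ...] = AGE_GROUPS,
    vois: list[VOISpec] | None = None,
    loading_sd: float = 3.0,
) -> dict[str, np.ndarray]:
    """Per-group loading covariance among the 8 VOIs.

    A base inter-node correlation of 0.2, bilateral homotopic pairs at 0.6,
    and anterior-posterior coupling that strengthens with age: the midline
    edge (MedF-Rsp) matures 0.1 -> 0.5 -> 0.8 and the midline-to-
    sensorimotor edges (MedF/Rsp to Mot_*/SS_*) mature 0.2 -> 0.35 -> 0.5,
    emulating the developmental strengthening of default-mode-to-
    sensorimotor covariance.  Scaled by ``loading_sd**2``.  Each matrix is
    checked positive semidefinite.
    """
    vois = vois if vois is not None else default_vois()
    names = [v.abbreviation for v in vois]
    idx = {n: i for i, n in enumerate(names)}
    p = len(names)
    pairs = [("Hp_L", "Hp_R"), ("Mot_L", "Mot_R"), ("SS_L", "SS_R")]
    midline = [0.1, 0.5, 0.8]
    cross = [0.2, 0.35, 0.5]
    sensorimotor = ("Mot_L", "Mot_R", "SS_L", "SS_R")
    out = {}
    for gi, g in enumerate(groups):
        corr = np.full((p, p), 0.2)
        np.fill_diagonal(corr, 1.0)
        for a, b in pairs:
            if a in idx and b in idx:
                corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = 0.6
        stage = min(gi, 2)
        if "MedF" in idx and "Rsp" in idx:
            r = midline[stage]
            corr[idx["MedF"], idx["Rsp"]] = corr[idx["Rsp"], idx["MedF"]] = r
        for hub in ("MedF", "Rsp"):
            if hub not in idx:
                continue
            for s in sensorimotor:
                if s in idx:
                    corr[idx[hub], idx[s]] = corr[idx[s], idx[hub]] = cross[stage]
        cov = corr * loading_sd**2
        _check_psd(cov, f"default covariance for group {g!r}")
        out[g] = cov
    return out


def _check_psd(cov: np.ndarray, what: str) -> None:
    cov = np.asarray(cov, dtype=np.float64)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError(f"{what}: not square, shape {cov.shape}")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError(f"{what}: not symmetric")
    w = np.linalg.eigvalsh(cov)
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ValueError(
            f"{what}: not positive semidefinite (min eigenvalue {w.min():.3g})"
        )


@dataclass
class SyntheticConfig:
    """Everything needed to generate one reproducible cohort.

    ``regional_means[group][voi]`` and ``voi_covariance[group]`` plant the
    across-subject mean and covariance of the VOI loadings; ``noise_sd`` is
    i.i.d. voxel noise added before smoothing; ``smoothing_fwhm_mm``
    emulates scanner resolution (applied at generation, distinct from the
    12 mm analysis smoothing).
    """

    grid_shape: tuple[int, int, int] = (40, 48, 16)
    voxel_spacing_mm: tuple[float, float, float] = (3.875, 3.875, 7.75)
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"5wk": 30, "10wk": 30, "15wk": 28}
    )
    regional_means: dict[str, dict[str, float]] | None = None
    voi_covariance: dict[str, np.ndarray] | None = None
    noise_sd: float = 1.0
    smoothing_fwhm_mm: float = 6.0
    seed: int = 0
    vois: list[VOISpec] = field(default_factory=default_vois)
    support_radius_mm: float = 12.0
    origin_mm: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError(f"voxel spacing must be positive, got {self.voxel_spacing_mm}")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {g!r} has size {n}; need at least 2 subjects")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.smoothing_fwhm_mm < 0:
            raise ValueError("smoothing_fwhm_mm must be non-negative")
        groups = tuple(self.group_sizes)
        if self.regional_means is None:
            self.regional_means = default_regional_means(groups, self.vois)
        if self.voi_covariance is None:
            self.voi_covariance = default_voi_covariance(groups, self.vois)
        p = len(self.vois)
        for g in groups:
            cov = np.asarray(self.voi_covariance[g], dtype=np.float64)
            if cov.shape != (p, p):
                raise ValueError(
                    f"covariance for group {g!r} has shape {cov.shape}, expected ({p}, {p})"
                )
            _check_psd(cov, f"voi_covariance[{g!r}]")
            self.voi_covariance[g] = cov
        if self.origin_mm is None:
            # center the grid on the brain ellipsoid
            ext = [(n - 1) * s for n, s in zip(self.grid_shape, self.voxel_spacing_mm)]
            self.origin_mm = tuple(
                float(c - e / 2.0) for c, e in zip(_BRAIN_CENTER, ext)
            )

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.group_sizes)

    @property
    def voi_names(self) -> list[str]:
        return [v.abbreviation for v in self.vois]


@dataclass
class GroundTruth:
    """What the generator planted, for checking downstream recovery."""

    brain_mask: BrainMask
    background: BrainVolume
    voi_masks: dict[str, BrainMask]
    component_maps: dict[str, np.ndarray]
    correlations: dict[str, np.ndarray]
    regional_means: dict[str, dict[str, float]]
    loadings: dict[str, np.ndarray]


def _background(config: SyntheticConfig) -> tuple[BrainVolume, BrainMask]:
    shape = config.grid_shape
    coords = [
        config.origin_mm[a] + config.voxel_spacing_mm[a] * np.arange(shape[a])
        for a in range(3)
    ]
    q = (
        ((coords[0] - _BRAIN_CENTER[0]) / _BRAIN_SEMI[0])[:, None, None] ** 2
        + ((coords[1] - _BRAIN_CENTER[1]) / _BRAIN_SEMI[1])[None, :, None] ** 2
        + ((coords[2] - _BRAIN_CENTER[2]) / _BRAIN_SEMI[2])[None, None, :] ** 2
    )
    inside = q <= 1.0
    bg = np.where(inside, _BACKGROUND_PEAK * (1.2 - q), 0.0)
    vol = BrainVolume(bg, config.voxel_spacing_mm, config.origin_mm)
    mask = BrainMask(inside, config.voxel_spacing_mm, config.origin_mm)
    return vol, mask


def _cov_factor(cov: np.ndarray) -> np.ndarray:
    """Deterministic factor L with L @ L.T = cov, valid for singular cov."""
    w, v = np.linalg.eigh(cov)
    return v * np.sqrt(np.clip(w, 0.0, None))


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[dict[str, ScanSet], GroundTruth]:
    """Generate one volume per subject per group, plus the planted truth.

    Deterministic given ``config.seed``; per-subject noise streams are
    spawned by ``(group index, subject index)``.
    """
    background, brain_mask = _background(config)
    supports = {}
    voi_masks = {}
    for v in config.vois:
        support_spec = VOISpec(
            v.name, v.abbreviation, v.ml_mm, v.dv_mm, v.ap_mm, v.component,
            radius_mm=config.support_radius_mm,
        )
        supports[v.abbreviation] = make_voi_mask(support_spec, background).values
        voi_masks[v.abbreviation] = make_voi_mask(v, background)

    support_stack = np.stack(
        [supports[n].astype(np.float64) for n in config.voi_names]
    )

    scansets: dict[str, ScanSet] = {}
    loadings: dict[str, np.ndarray] = {}
    correlations: dict[str, np.ndarray] = {}
    root = np.random.SeedSequence(config.seed)
    for gi, (group, n) in enumerate(config.group_sizes.items()):
        cov = config.voi_covariance[group]
        L = _cov_factor(cov)
        mu = np.array([config.regional_means[group][n_] for n_ in config.voi_names])
        sd = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
        correlations[group] = cov / np.outer(sd, sd)
        np.fill_diagonal(correlations[group], 1.0)

        vols, ids, lds = [], [], []
        for si in range(n):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=config.seed, spawn_key=(gi, si))
            )
            l = mu + L @ rng.standard_normal(len(mu))
            vals = background.values + np.tensordot(l, support_stack, axes=(0, 0))
            if config.noise_sd > 0:
                vals = vals + config.noise_sd * rng.standard_normal(config.grid_shape)
            vol = BrainVolume(vals, config.voxel_spacing_mm, config.origin_mm)
            if config.smoothing_fwhm_mm > 0:
                vol = gaussian_smooth(vol, config.smoothing_fwhm_mm)
            vols.append(vol)
            # rat identity is stable across ages: the same animal is scanned
            # at each age, so IDs carry no group prefix
            ids.append(f"r{si:03d}")
            lds.append(l)
        scansets[group] = ScanSet(ids, vols, group)
        loadings[group] = np.array(lds)

    component_maps = {}
    for v in config.vois:
        comp = v.component or "IC?"
        component_maps.setdefault(comp, np.zeros(config.grid_shape))
        component_maps[comp] += supports[v.abbreviation]

    truth = GroundTruth(
        brain_mask=brain_mask,
        background=background,
        voi_masks=voi_masks,
        component_maps=component_maps,
        correlations=correlations,
        regional_means={g: dict(m) for g, m in config.regional_means.items()},
        loadings=loadings,
    )
    return scansets, truth


def plant_component_maps(
    k: int, grid: BrainVolume | BrainMask, blob_fwhm_mm: float = 25.0
) -> list[np.ndarray]:
    """``k`` compact, pairwise low-overlap Gaussian blobs inside the brain.

    Centers are placed deterministically on a coarse lattice restricted to
    the brain-ellipsoid interior, spaced so that neighbouring blobs overlap
    negligibly.  Raises if ``k`` exceeds the number of placeable centers.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    coords = [
        grid.origin_mm[a] + grid.voxel_spacing_mm[a] * np.arange(grid.shape[a])
        for a in range(3)
    ]
    sigma = blob_fwhm_mm / np.sqrt(8.0 * np.log(2.0))
    spacing = 4.0 * sigma  # >= 4 sigma separation keeps pairwise overlap ~0
    candidates = []
    for cx in np.arange(-_BRAIN_SEMI[0], _BRAIN_SEMI[0] + 1, spacing):
        for cy in np.arange(-_BRAIN_SEMI[1], _BRAIN_SEMI[1] + 1, spacing):
            for cz in np.arange(-_BRAIN_SEMI[2], _BRAIN_SEMI[2] + 1, spacing):
                c = _BRAIN_CENTER + np.array([cx, cy, cz])
                q = np.sum(((c - _BRAIN_CENTER) / (_BRAIN_SEMI * 0.85)) ** 2)
                in_grid = all(
                    coords[a][0] <= c[a] <= coords[a][-1] for a in range(3)
                )
                if q <= 1.0 and in_grid:
                    candidates.append(c)
    if k > len(candidates):
        raise ValueError(
            f"cannot place {k} non-overlapping components; capacity is "
            f"{len(candidates)} for this grid"
        )
    # deterministic spread: sort by distance from brain center, take every
    # len/k-th so the chosen centers cover the volume
    candidates.sort(key=lambda c: (np.linalg.norm(c - _BRAIN_CENTER), tuple(c)))
    step = len(candidates) / k
    chosen = [candidates[int(i * step)] for i in range(k)]
    maps = []
    for c in chosen:
        d2 = (
            ((coords[0] - c[0])[:, None, None]) ** 2
            + ((coords[1] - c[1])[None, :, None]) ** 2
            + ((coords[2] - c[2])[None, None, :]) ** 2
        )
        maps.append(np.exp(-d2 / (2.0 * sigma**2)))
    return maps


def generate_component_cohort(
    k: int,
    n_subjects: int,
    grid: BrainVolume | BrainMask,
    snr: float = 10.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Subjects x voxels data with ``k`` planted spatial sources.

    Returns ``(data, mixing, maps)`` where ``data = mixing @ maps + noise``
    flattened over the grid.  Noise sd is set from ``snr`` as the ratio of
    per-source signal sd (over voxels) to noise sd.  Ground truth for
    testing spatial ICA recovery.
    """
    if n_subjects < k + 1:
        raise ValueError("need more subjects than components")
    maps = plant_component_maps(k, grid)
    flat = np.stack([m.ravel() for m in maps])
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(7,)))
    mixing = rng.standard_normal((n_subjects, k))
    signal = mixing @ flat
    sig_sd = float(np.std(flat)) * np.sqrt(k)
    noise_sd = sig_sd / snr
    data = signal + noise_sd * rng.standard_normal(signal.shape)
    return data, mixing, maps


def write_cohort(
    scansets: dict[str, ScanSet],
    truth: GroundTruth,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Write NIfTI volumes, the brain mask, a TSV manifest, and truth JSON."""
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for group, scans in scansets.items():
        for sid, vol in scans:
            path = out_dir / f"{group}_{sid}.nii.gz"
            write_volume(vol, path)
            rows.append({"subject_id": sid, "group": group, "path": str(path)})
    write_volume(truth.brain_mask, out_dir / "brain_mask.nii.gz")
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    truth_json = {
        "correlations": {g: m.tolist() for g, m in truth.correlations.items()},
        "regional_means": truth.regional_means,
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(truth_json, indent=2))
    return manifest
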