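"""Calibration and recovery experiments on synthetic cohorts.

Each function sets up a cohort family under the study's design (three age
groups of 30/30/28 subjects, or two-group variants of it on a coarse test
grid), runs one analysis stage end to end, and measures a scalar quality:
null calibration of the permutation edge test, power against a planted
edge change, spatial-ICA recovery of planted components, directional
recovery of the efficiency maturation effect, and exact agreement of the
deterministic kernels with brute-force oracles.  Everything is seeded and
reproducible; problem sizes are arguments so studies can be scaled.
"""

from __future__ import annotations

import numpy as np

from .connectivity import correlation_matrix, fisher_z, permutation_edge_test
from .efficiency import group_efficiency, node_strength
from .ica import DataMatrix, infomax_ica, match_components
from .simulate import (
    SyntheticConfig,
    default_regional_means,
    default_voi_covariance,
    generate_cohort,
    generate_component_cohort,
)
from .voi import default_vois, extract_voi_means, make_voi_mask
from .volume import BrainVolume, gaussian_smooth, global_normalize
from .voxelstats import bh_fdr

__all__ = [
    "TEST_GRID",
    "TEST_SPACING",
    "preprocess_and_extract",
    "null_edge_calibration",
    "bh_oracle_agreement",
    "ica_recovery",
    "edge_change_detection",
    "efficiency_direction_recovery",
    "deterministic_oracle_errors",
]

#: Coarse grid for simulation studies: default field of view at 2x spacing.
TEST_GRID = (20, 24, 8)
TEST_SPACING = (7.75, 7.75, 15.5)


def _two_group_config(cov_a, cov_b, seed, n_a=30, n_b=30, equal_means=False):
    groups = ("A", "B")
    means = default_regional_means(groups)
    if equal_means:
        means = {g: dict(means["A"]) for g in groups}
    return SyntheticConfig(
        grid_shape=TEST_GRID,
        voxel_spacing_mm=TEST_SPACING,
        group_sizes={"A": n_a, "B": n_b},
        regional_means=means,
        voi_covariance={"A": cov_a, "B": cov_b},
        seed=seed,
    )


def preprocess_and_extract(scansets, truth, fwhm_mm=12.0):
    """Standard analysis chain: smooth, globally normalize, extract VOIs."""
    mask = truth.brain_mask
    out = {}
    for g, scans in scansets.items():
        pre = scans.map(lambda v: global_normalize(gaussian_smooth(v, fwhm_mm), mask))
        out[g] = extract_voi_means(pre, truth.voi_masks)
    return out


def null_edge_calibration(
    n_cohorts: int = 500, n_perm: int = 1000, seed: int = 0, alpha: float = 0.05
) -> float:
    """Per-edge uncorrected rejection rate when both groups share one
    generating distribution.  A calibrated test returns ~``alpha``."""
    cov = default_voi_covariance(("A", "B"))
    rejections = 0
    total = 0
    for i in range(n_cohorts):
        cfg = _two_group_config(cov["A"], cov["A"], seed=seed * 1_000_003 + i,
                                equal_means=True)
        scansets, truth = generate_cohort(cfg)
        vms = preprocess_and_extract(scansets, truth)
        res = permutation_edge_test(vms["A"], vms["B"], n_perm=n_perm, seed=i)
        rejections += int((res.table.p < alpha).sum())
        total += len(res.table)
    return rejections / total


def bh_oracle_agreement(n_vectors: int = 1000, seed: int = 0, q: float = 0.05) -> float:
    """Fraction of random p-vectors on which the FDR rejections equal an
    independent brute-force step-up enumeration."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_vectors):
        m = int(rng.integers(1, 51))
        # mix of null and signal p-values so rejection sets are non-trivial
        p = np.where(rng.random(m) < 0.3, rng.random(m) * 0.05, rng.random(m))
        reject, _ = bh_fdr(p, q)
        # oracle: largest i with p_(i) <= i q / m rejects the i smallest
        order = np.argsort(p, kind="stable")
        k = 0
        for i in range(1, m + 1):
            if p[order[i - 1]] <= i * q / m:
                k = i
        oracle = np.zeros(m, dtype=bool)
        oracle[order[:k]] = True
        agree += bool(np.array_equal(reject, oracle))
    return agree / n_vectors


def ica_recovery(
    n_seeds: int = 10, k: int = 4, n_subjects: int = 40, snr: float = 10.0
) -> dict[str, float]:
    """Worst and mean matched |spatial r| between infomax estimates and the
    planted component maps, across seeds."""
    grid = BrainVolume(np.zeros(TEST_GRID), TEST_SPACING,
                       SyntheticConfig(grid_shape=TEST_GRID,
                                       voxel_spacing_mm=TEST_SPACING,
                                       group_sizes={"a": 2, "b": 2}).origin_mm)
    mins, means = [], []
    for seed in range(n_seeds):
        data, _, maps = generate_component_cohort(k, n_subjects, grid, snr=snr,
                                                  seed=seed)
        dm = DataMatrix(data, [f"s{i}" for i in range(n_subjects)])
        cs = infomax_ica(dm, k, seed=seed)
        truth = np.stack([m.ravel() for m in maps])
        _, sims = match_components(cs.maps, truth)
        mins.append(np.abs(sims).min())
        means.append(np.abs(sims).mean())
    return {"min_abs_r": float(np.min(mins)), "mean_abs_r": float(np.mean(means))}


def edge_change_detection(
    n_cohorts: int = 200,
    n_perm: int = 1000,
    seed: int = 0,
    r_a: float = 0.1,
    r_b: float = 0.8,
    alpha: float = 0.05,
) -> float:
    """Power of the permutation edge test against a planted change of the
    anterior-posterior midline edge (MedF-Rsp), r_a vs r_b at n = 30/30."""
    names = [v.abbreviation for v in default_vois()]
    i, j = names.index("MedF"), names.index("Rsp")

    def cov_with(r_mid):
        cov = default_voi_covariance(("G",))["G"]
        sd2 = cov[0, 0]
        cov[i, j] = cov[j, i] = r_mid * sd2
        return cov

    detected = 0
    for c in range(n_cohorts):
        cfg = _two_group_config(cov_with(r_a), cov_with(r_b),
                                seed=seed * 1_000_003 + c, equal_means=True)
        scansets, truth = generate_cohort(cfg)
        vms = preprocess_and_extract(scansets, truth)
        res = permutation_edge_test(vms["A"], vms["B"], n_perm=n_perm, seed=c)
        t = res.table
        row = t[(t.voi_a == "MedF") & (t.voi_b == "Rsp")]
        detected += bool(row.p.iloc[0] < alpha)
    return detected / n_cohorts


def efficiency_direction_recovery(n_cohorts: int = 100, seed: int = 0) -> float:
    """Fraction of cohorts in which stronger anterior-posterior coupling
    (with unchanged regional means) raises BOTH midline-hub efficiencies.

    Group A uses the youngest-age default covariance, group B the
    oldest-age one (midline edge 0.1 -> 0.8, hub-to-sensorimotor
    0.2 -> 0.5); regional mean uptake is identical between groups, so any
    efficiency change is driven purely by connectivity strength."""
    covs = default_voi_covariance(("young", "mid", "old"))
    names = [v.abbreviation for v in default_vois()]
    i_medf, i_rsp = names.index("MedF"), names.index("Rsp")
    hits = 0
    for c in range(n_cohorts):
        cfg = _two_group_config(covs["young"], covs["old"],
                                seed=seed * 1_000_003 + c, equal_means=True)
        scansets, truth = generate_cohort(cfg)
        vms = preprocess_and_extract(scansets, truth)
        e_a = group_efficiency(vms["A"]).efficiency
        e_b = group_efficiency(vms["B"]).efficiency
        hits += bool(e_b[i_medf] > e_a[i_medf] and e_b[i_rsp] > e_a[i_rsp])
    return hits / n_cohorts


def deterministic_oracle_errors(seed: int = 0) -> dict[str, float]:
    """Max |difference| between each deterministic kernel and a brute-force
    re-computation: masked VOI means, node strength, Fisher z, and the
    Gaussian-smoothing impulse response."""
    rng = np.random.default_rng(seed)
    errors = {}

    # masked means: loop oracle over one synthetic subject
    cfg = SyntheticConfig(grid_shape=TEST_GRID, voxel_spacing_mm=TEST_SPACING,
                          group_sizes={"A": 2, "B": 2}, seed=seed)
    scansets, truth = generate_cohort(cfg)
    scans = scansets["A"]
    vm = extract_voi_means(scans, truth.voi_masks)
    err = 0.0
    for j, name in enumerate(truth.voi_masks):
        mask = truth.voi_masks[name].values
        acc, cnt = 0.0, 0
        for idx in np.argwhere(mask):
            acc += scans.volumes[0].values[tuple(idx)]
            cnt += 1
        err = max(err, abs(vm.values[0, j] - acc / cnt))
    errors["masked_means"] = err

    # node strength: edge-enumeration oracle on a random correlation matrix
    a = rng.standard_normal((12, 8))
    r = np.corrcoef(a, rowvar=False)
    s = node_strength(r)
    brute = np.zeros(8)
    for i in range(8):
        for j in range(8):
            if i != j and r[i, j] > 0:
                brute[i] += r[i, j]
    errors["node_strength"] = float(np.max(np.abs(s - brute)))

    # Fisher z: closed form 0.5 ln((1+r)/(1-r))
    rs = rng.uniform(-0.99, 0.99, size=100)
    errors["fisher_z"] = float(
        np.max(np.abs(fisher_z(rs) - 0.5 * np.log((1 + rs) / (1 - rs))))
    )

    # smoothing impulse response vs explicit truncated-kernel convolution
    shape, spacing, fwhm = (21, 21, 11), (2.0, 2.0, 4.0), 6.0
    vals = np.zeros(shape)
    vals[10, 10, 5] = 1.0
    smoothed = gaussian_smooth(BrainVolume(vals, spacing), fwhm).values
    sigma_mm = fwhm / np.sqrt(8 * np.log(2))
    kernels = []
    for ax in range(3):
        sig = sigma_mm / spacing[ax]
        radius = int(4.0 * sig + 0.5)
        x = np.arange(-radius, radius + 1)
        k = np.exp(-0.5 * (x / sig) ** 2)
        kernels.append(k / k.sum())
    brute = (
        kernels[0][:, None, None]
        * kernels[1][None, :, None]
        * kernels[2][None, None, :]
    )
    r0 = [len(k) // 2 for k in kernels]
    oracle = np.zeros(shape)
    for di in range(-r0[0], r0[0] + 1):
        for dj in range(-r0[1], r0[1] + 1):
            for dk in range(-r0[2], r0[2] + 1):
                oracle[10 + di, 10 + dj, 5 + dk] = brute[
                    r0[0] + di, r0[1] + dj, r0[2] + dk
                ]
    errors["smoothing_impulse"] = float(np.max(np.abs(smoothed - oracle)))
    return errors
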