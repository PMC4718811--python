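"""Group spatial ICA on the pooled subjects x voxels matrix.

All subjects of all age groups are stacked into one data matrix (rows =
subjects, columns = in-mask voxels); PCA reduces to k dimensions and an
infomax unmixing (logistic nonlinearity, natural-gradient updates) yields k
spatially independent component maps with a subjects x k mixing matrix.
Model order is estimated from the PCA eigenspectrum by minimum description
length (MDL); because neighbouring voxels are spatially correlated the
number of effective i.i.d. samples can be downweighted via
``sample_correction``.

Maps are z-scored over in-mask voxels, so the conventional display
threshold z > 1.5 marks voxels more than 1.5 SD above the component mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .volume import BrainMask, ScanSet

__all__ = [
    "DataMatrix",
    "ComponentSet",
    "build_data_matrix",
    "estimate_ncomp",
    "infomax_ica",
    "threshold_component",
    "match_components",
]


@dataclass
class DataMatrix:
    """subjects x in-mask-voxels matrix plus the row manifest and mask."""

    values: np.ndarray
    subject_ids: list[str]
    mask: BrainMask | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("DataMatrix must be 2D")
        if self.values.shape[0] != len(self.subject_ids):
            raise ValueError("row count != number of subject IDs")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


@dataclass
class ComponentSet:
    """K spatial maps (z-scored over in-mask voxels) + subjects x K mixing."""

    maps: np.ndarray  # (k, n_mask_voxels)
    mixing: np.ndarray  # (n_subjects, k)
    mask: BrainMask | None = None
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.mixing)):
            raise ValueError("mixing matrix contains non-finite values")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    def map_volume(self, i: int) -> np.ndarray:
        """Embed the i-th map into the full 3D grid (0 outside mask)."""
        if self.mask is None:
            raise ValueError("no mask attached; maps are flat vectors only")
        out = np.zeros(self.mask.shape)
        out[self.mask.values] = self.maps[i]
        return out


def build_data_matrix(scansets: dict[str, ScanSet], mask: BrainMask) -> DataMatrix:
    """Stack every subject of every group into one subjects x voxels matrix."""
    rows, ids = [], []
    for scans in scansets.values():
        for sid, vol in scans:
            rows.append(vol.values[mask.values])
            ids.append(sid)
    return DataMatrix(np.array(rows), ids, mask)


def estimate_ncomp(data: DataMatrix, sample_correction: float = 1.0) -> int:
    """MDL model-order estimate from the subject-covariance eigenspectrum.

    The number of sources k minimizing the description length

        N' (p - k) ln(arith/geo mean of trailing eigenvalues)
            + k (2p - k + 1)/2 ln N'

    with p = subjects and N' = voxels * ``sample_correction`` effective
    samples. Clipped to [1, p - 1].
    """
    if data.n_subjects < 3:
        raise ValueError("need at least 3 subjects to estimate model order")
    if not (0 < sample_correction <= 1.0):
        raise ValueError("sample_correction must lie in (0, 1]")
    X = data.values - data.values.mean(axis=1, keepdims=True)
    cov = X @ X.T / data.n_voxels
    eigs = np.linalg.eigvalsh(cov)[::-1]
    if eigs[0] <= 0:
        raise ValueError("degenerate data: subject covariance has no positive eigenvalue")
    eigs = np.clip(eigs, 1e-12 * eigs[0], None)
    p = len(eigs)
    n_eff = max(data.n_voxels * sample_correction, p + 1.0)
    mdl = np.empty(p - 1)
    for k in range(p - 1):
        tail = eigs[k:]
        log_geo = np.mean(np.log(tail))
        log_arith = np.log(np.mean(tail))
        mdl[k] = n_eff * (p - k) * (log_arith - log_geo) + 0.5 * k * (
            2 * p - k + 1
        ) * np.log(n_eff)
    return int(max(1, np.argmin(mdl)))


def _whiten(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """PCA-whiten rows of X to k dims: returns (Z, K) with Z = K X."""
    n_vox = X.shape[1]
    cov = X @ X.T / n_vox
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1][:k]
    w, v = w[order], v[:, order]
    if w[-1] <= 1e-12 * w[0]:
        raise ValueError(f"requested k={k} exceeds the numerical rank of the data")
    K = (v / np.sqrt(w)).T  # (k, n_sub)
    return K @ X, K


def infomax_ica(
    data: DataMatrix,
    k: int,
    seed: int = 0,
    learning_rate: float = 0.01 / np.log(2.718),
    max_iter: int = 500,
    tol: float = 1e-6,
    block_size: int = 512,
) -> ComponentSet:
    """Spatial infomax ICA: PCA whitening to k dims, then natural-gradient
    unmixing with a logistic nonlinearity.

    The learning rate is halved and the unmixing restarted whenever the
    weights blow up; non-convergence within ``max_iter`` passes is flagged
    on the returned :class:`ComponentSet`, never silent.  Deterministic
    given ``seed`` (which drives the per-pass voxel shuffling).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > min(data.n_subjects, data.n_voxels):
        raise ValueError(f"k={k} exceeds the data rank bound")
    X = data.values - data.values.mean(axis=0, keepdims=True)  # center per voxel
    Z, K = _whiten(X, k)
    n_vox = Z.shape[1]
    block = int(min(block_size, n_vox))
    rng = np.random.default_rng(seed)

    lr = learning_rate
    W = np.eye(k)
    eye = np.eye(k)
    converged = False
    n_iter = 0
    max_restarts = 20
    for _ in range(max_restarts):
        W = np.eye(k)
        diverged = False
        step = lr
        change_prev: np.ndarray | None = None
        for it in range(max_iter):
            order = rng.permutation(n_vox)
            W_prev = W.copy()
            for start in range(0, n_vox, block):
                idx = order[start : start + block]
                u = W @ Z[:, idx]
                y = 1.0 / (1.0 + np.exp(-u))
                grad = eye + (1.0 - 2.0 * y) @ u.T / len(idx)
                W = W + step * grad @ W
                if not np.all(np.isfinite(W)) or np.max(np.abs(W)) > 1e8:
                    diverged = True
                    break
            if diverged:
                break
            change = (W - W_prev).ravel()
            delta = np.max(np.abs(change))
            n_iter = it + 1
            if delta < tol:
                converged = True
                break
            # anneal only when successive updates oscillate (> 60 degrees),
            # the sign that the pass-level gradient is now dominated by the
            # stochastic block ordering rather than real progress
            if change_prev is not None:
                denom = np.linalg.norm(change) * np.linalg.norm(change_prev)
                if denom > 0 and (change @ change_prev) / denom < 0.5:
                    step *= 0.9
            change_prev = change
        if not diverged:
            break
        lr *= 0.5  # restart smaller after a blowup
    else:
        raise RuntimeError("infomax failed to stabilize after annealing")

    sources = W @ Z  # (k, n_vox)
    mixing = np.linalg.pinv(W @ K)  # (n_sub, k)

    # z-score maps over in-mask voxels; fold scale into the mixing columns
    mu = sources.mean(axis=1, keepdims=True)
    sd = sources.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    maps = (sources - mu) / sd
    mixing = mixing * sd.T
    # deterministic sign: orient each map so its extreme voxel is positive
    signs = np.sign(maps[np.arange(k), np.argmax(np.abs(maps), axis=1)])
    signs[signs == 0] = 1.0
    maps *= signs[:, None]
    mixing *= signs[None, :]
    # order by explained variance (mixing column energy)
    order = np.argsort(-np.sum(mixing**2, axis=0))
    return ComponentSet(
        maps=maps[order],
        mixing=mixing[:, order],
        mask=data.mask,
        converged=converged,
        n_iter=n_iter,
    )


def threshold_component(map_values: np.ndarray, z: float = 1.5) -> np.ndarray:
    """Binary mask of voxels whose z-scored value exceeds ``z``."""
    return np.asarray(map_values) > z


def match_components(
    estimated: np.ndarray, reference: np.ndarray
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Optimally pair estimated with reference maps by |spatial correlation|.

    Both arguments are (k, n_voxels) stacks on the same grid.  Returns the
    assignment as (estimated index, reference index) pairs and the signed
    Pearson correlation of each pair.
    """
    est = np.asarray(estimated, dtype=np.float64)
    ref = np.asarray(reference, dtype=np.float64)
    if est.ndim != 2 or ref.ndim != 2 or est.shape[1] != ref.shape[1]:
        raise ValueError(
            f"map stacks must share the voxel grid: {est.shape} vs {ref.shape}"
        )
    ec = est - est.mean(axis=1, keepdims=True)
    rc = ref - ref.mean(axis=1, keepdims=True)
    es = np.linalg.norm(ec, axis=1)
    rs = np.linalg.norm(rc, axis=1)
    es[es == 0] = 1.0
    rs[rs == 0] = 1.0
    corr = (ec @ rc.T) / np.outer(es, rs)
    rows, cols = linear_sum_assignment(-np.abs(corr))
    pairs = list(zip(rows.tolist(), cols.tolist()))
    sims = corr[rows, cols]
    return pairs, sims
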