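"""Across-subject interregional connectivity and its permutation inference.

Metabolic connectivity here is the Pearson correlation of normalized VOI
uptake computed ACROSS SUBJECTS within an age group (subjects, not time
points, are the samples).  Group differences per edge are tested on the
Fisher-z scale by pooling the two groups, reshuffling the group labels
(sizes preserved) and recomputing the z difference; p-values use the
add-one permutation estimator and the 28 edges are FDR-controlled with
Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .voi import VOIMatrix
from .voxelstats import bh_fdr

__all__ = [
    "ConnectivityResult",
    "EdgeComparison",
    "correlation_matrix",
    "fisher_z",
    "permutation_edge_test",
]

#: |r| = 1 is clamped to this before atanh to keep z finite.
_R_CLAMP = 1.0 - 1e-7


@dataclass
class ConnectivityResult:
    """Per-group interregional correlation on the r and Fisher-z scales."""

    r: np.ndarray
    z: np.ndarray
    voi_names: list[str]
    group: str = ""
    n_subjects: int = 0

    @property
    def n_edges(self) -> int:
        p = len(self.voi_names)
        return p * (p - 1) // 2

    def edge_frame(self) -> pd.DataFrame:
        """One row per unique edge: voi_a, voi_b, r, z."""
        iu = np.triu_indices(len(self.voi_names), k=1)
        return pd.DataFrame(
            {
                "voi_a": [self.voi_names[i] for i in iu[0]],
                "voi_b": [self.voi_names[j] for j in iu[1]],
                "r": self.r[iu],
                "z": self.z[iu],
            }
        )


@dataclass
class EdgeComparison:
    """Per-edge observed z difference, permutation p, and FDR decision."""

    table: pd.DataFrame  # voi_a, voi_b, delta_z, p, q, significant, direction
    group_a: str
    group_b: str
    n_perm: int

    def __len__(self) -> int:
        return len(self.table)


def fisher_z(r) -> np.ndarray | float:
    """Variance-stabilizing transform z = atanh(r); |r| = 1 is clamped.

    Accepts scalars or arrays; |r| > 1 is rejected.
    """
    arr = np.asarray(r, dtype=np.float64)
    if np.any(np.abs(arr) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    if np.any(np.abs(arr) == 1):
        warnings.warn("clamping |r| = 1 before Fisher transform", stacklevel=2)
        arr = np.clip(arr, -_R_CLAMP, _R_CLAMP)
    z = np.arctanh(arr)
    return float(z) if np.isscalar(r) else z


def correlation_matrix(m: VOIMatrix) -> ConnectivityResult:
    """Pairwise Pearson r across subjects, with the Fisher-z matrix."""
    if m.n_subjects < 4:
        raise ValueError(f"need at least 4 subjects, got {m.n_subjects}")
    sd = m.values.std(axis=0)
    dead = np.where(sd == 0)[0]
    if dead.size:
        names = [m.voi_names[i] for i in dead]
        raise ValueError(f"zero-variance VOI column(s): {names}")
    r = np.corrcoef(m.values, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    z = np.arctanh(np.clip(r, -_R_CLAMP, _R_CLAMP))
    np.fill_diagonal(r, 1.0)
    return ConnectivityResult(
        r=r, z=z, voi_names=list(m.voi_names), group=m.group, n_subjects=m.n_subjects
    )


def _batched_corr(groups: np.ndarray) -> np.ndarray:
    """Correlation matrices for a batch: (P, n, p) -> (P, p, p)."""
    c = groups - groups.mean(axis=1, keepdims=True)
    cov = np.einsum("pni,pnj->pij", c, c)
    sd = np.sqrt(np.einsum("pii->pi", cov))
    sd[sd == 0] = 1.0
    return cov / (sd[:, :, None] * sd[:, None, :])


def permutation_correlations(
    pooled: np.ndarray,
    n_a: int,
    n_perm: int,
    rng: np.random.Generator,
    batch: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """Null correlation matrices for both pseudo-groups of every relabeling.

    ``pooled`` is the (n_a + n_b, p) stacked VOI matrix.  Returns two
    (n_perm, p, p) stacks of Pearson matrices for the pseudo-A and pseudo-B
    halves of each of ``n_perm`` label shuffles.  Batched to bound memory.
    """
    n_tot = pooled.shape[0]
    p = pooled.shape[1]
    ra = np.empty((n_perm, p, p))
    rb = np.empty((n_perm, p, p))
    for start in range(0, n_perm, batch):
        stop = min(start + batch, n_perm)
        nb = stop - start
        idx = np.argsort(rng.random((nb, n_tot)), axis=1)  # nb independent shuffles
        shuffled = pooled[idx]  # (nb, n_tot, p)
        ra[start:stop] = _batched_corr(shuffled[:, :n_a, :])
        rb[start:stop] = _batched_corr(shuffled[:, n_a:, :])
    return ra, rb


def permutation_edge_test(
    m_a: VOIMatrix,
    m_b: VOIMatrix,
    n_perm: int = 10000,
    seed: int = 0,
    q: float = 0.05,
    two_sided: bool = True,
) -> EdgeComparison:
    """Permutation test of the per-edge Fisher-z difference (B - A).

    Pools subjects, reshuffles group labels preserving group sizes,
    recomputes each pseudo-group's correlation matrix and the edge-wise
    delta-z; p = (1 + #{|dz_perm| >= |dz_obs|}) / (n_perm + 1), then BH-FDR
    over the unique edges at level ``q``.
    """
    if m_a.voi_names != m_b.voi_names:
        raise ValueError("VOI columns differ between the two groups")
    if n_perm < 100:
        raise ValueError(f"need at least 100 permutations, got {n_perm}")

    ca = correlation_matrix(m_a)
    cb = correlation_matrix(m_b)
    iu = np.triu_indices(len(m_a.voi_names), k=1)
    obs = (cb.z - ca.z)[iu]

    pooled = np.vstack([m_a.values, m_b.values])
    rng = np.random.default_rng(seed)
    ra, rb = permutation_correlations(pooled, m_a.n_subjects, n_perm, rng)
    za = np.arctanh(np.clip(ra, -_R_CLAMP, _R_CLAMP))
    zb = np.arctanh(np.clip(rb, -_R_CLAMP, _R_CLAMP))
    null = (zb - za)[:, iu[0], iu[1]]  # (n_perm, n_edges)

    if two_sided:
        exceed = np.abs(null) >= np.abs(obs)[None, :]
    else:
        exceed = null >= obs[None, :]
    p = (1.0 + exceed.sum(axis=0)) / (n_perm + 1.0)
    reject, q_adj = bh_fdr(p, q)

    table = pd.DataFrame(
        {
            "voi_a": [m_a.voi_names[i] for i in iu[0]],
            "voi_b": [m_a.voi_names[j] for j in iu[1]],
            "r_a": ca.r[iu],
            "r_b": cb.r[iu],
            "delta_z": obs,
            "p": p,
            "q": q_adj,
            "significant": reject,
            "direction": np.where(obs >= 0, "increase", "decrease"),
        }
    )
    return EdgeComparison(
        table=table, group_a=m_a.group, group_b=m_b.group, n_perm=n_perm
    )
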