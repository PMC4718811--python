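"""Voxelwise age contrasts: paired t-maps, BH-FDR, cluster extent filtering.

The cross-sectional design compares age groups voxel-by-voxel with a paired
t-test on within-subject differences (subjects scanned at both ages),
controls the false discovery rate over in-mask voxels with the
Benjamini-Hochberg step-up procedure, and reports only clusters of at least
``extent`` contiguous suprathreshold voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .volume import BrainMask, ScanSet

__all__ = ["StatMap", "ClusterTable", "paired_t_map", "bh_fdr", "label_clusters"]

_CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class StatMap:
    """Per-voxel paired-t results restricted to the brain mask.

    ``t``, ``p`` and ``q`` are full-grid arrays, NaN outside the mask;
    ``q`` is the BH-FDR-adjusted p over in-mask voxels.
    """

    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    dof: int
    mask: BrainMask


@dataclass
class ClusterTable:
    """Signed suprathreshold clusters surviving the extent filter."""

    table: pd.DataFrame  # label, n_voxels, peak_x_mm, peak_y_mm, peak_z_mm, peak_t, direction
    labels: np.ndarray  # 3D int array, 0 = background

    def __len__(self) -> int:
        return len(self.table)


def paired_t_map(
    group_a: ScanSet,
    group_b: ScanSet,
    mask: BrainMask,
    pairing: dict[str, str] | None = None,
    fdr_q: float = 0.05,
) -> StatMap:
    """Paired t-test (B - A) at every in-mask voxel.

    ``pairing`` maps subject IDs of A to IDs of B; by default subjects with
    identical IDs in both groups are paired and unmatched subjects are
    dropped (the design loses subjects at later ages).  Zero-variance
    voxels get t = 0, p = 1 rather than infinities.
    """
    if pairing is None:
        common = [sid for sid in group_a.subject_ids if sid in set(group_b.subject_ids)]
        pairing = {sid: sid for sid in common}
    missing_a = [a for a in pairing if a not in set(group_a.subject_ids)]
    missing_b = [b for b in pairing.values() if b not in set(group_b.subject_ids)]
    if missing_a or missing_b:
        raise ValueError(
            f"pairing refers to unknown subjects: {missing_a + missing_b}"
        )
    n = len(pairing)
    if n < 3:
        raise ValueError(f"need at least 3 pairs for a paired t-test, got {n}")

    idx_a = {sid: i for i, sid in enumerate(group_a.subject_ids)}
    idx_b = {sid: i for i, sid in enumerate(group_b.subject_ids)}
    stack_a = group_a.stack()
    stack_b = group_b.stack()
    m = mask.values
    diffs = np.stack(
        [stack_b[idx_b[b]][m] - stack_a[idx_a[a]][m] for a, b in pairing.items()]
    )

    dof = n - 1
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    nonzero = sd > 0
    t[nonzero] = mean[nonzero] / (sd[nonzero] / np.sqrt(n))
    p = np.ones_like(t)
    p[nonzero] = 2.0 * stats.t.sf(np.abs(t[nonzero]), dof)

    _, q = bh_fdr(p, fdr_q)

    def full(vals: np.ndarray) -> np.ndarray:
        out = np.full(mask.shape, np.nan)
        out[m] = vals
        return out

    return StatMap(t=full(t), p=full(p), q=full(q), dof=dof, mask=mask)


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted q-values).

    Empty input yields empty output; p-values outside [0, 1] are rejected.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if not (0 < q < 1):
        raise ValueError(f"q must lie in (0, 1), got {q}")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q_adj, _, _ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape), q_adj.reshape(p.shape)


def label_clusters(
    binary_map: np.ndarray,
    volume_like,
    connectivity: int = 18,
    extent: int = 100,
    t_map: np.ndarray | None = None,
) -> ClusterTable:
    """Connected components of a suprathreshold map, extent-filtered.

    ``connectivity`` is the 3D neighbourhood (6 faces, 18 faces+edges, 26
    full); components smaller than ``extent`` voxels are removed.  When a
    ``t_map`` is given, each cluster reports its peak |t| location and the
    sign of the effect there.
    """
    if connectivity not in _CONNECTIVITY_STRUCTS:
        raise ValueError(
            f"connectivity must be one of 6, 18, 26; got {connectivity}"
        )
    if extent < 1:
        raise ValueError(f"extent must be a positive integer, got {extent}")
    binary = np.asarray(binary_map).astype(bool)
    labels, n_raw = ndimage.label(binary, structure=_CONNECTIVITY_STRUCTS[connectivity])
    rows = []
    out_labels = np.zeros_like(labels)
    next_label = 0
    for lab in range(1, n_raw + 1):
        where = labels == lab
        size = int(where.sum())
        if size < extent:
            continue
        next_label += 1
        out_labels[where] = next_label
        if t_map is not None:
            tv = np.where(where, np.nan_to_num(t_map), 0.0)
            flat_peak = np.argmax(np.abs(tv))
            peak_idx = np.unravel_index(flat_peak, tv.shape)
            peak_t = float(tv[peak_idx])
        else:
            coords_vox = np.argwhere(where)
            peak_idx = tuple(coords_vox[0])
            peak_t = np.nan
        peak_mm = [
            volume_like.origin_mm[a] + volume_like.voxel_spacing_mm[a] * peak_idx[a]
            for a in range(3)
        ]
        rows.append(
            {
                "label": next_label,
                "n_voxels": size,
                "peak_x_mm": peak_mm[0],
                "peak_y_mm": peak_mm[1],
                "peak_z_mm": peak_mm[2],
                "peak_t": peak_t,
                "direction": "increase" if peak_t >= 0 else "decrease",
            }
        )
    cols = ["label", "n_voxels", "peak_x_mm", "peak_y_mm", "peak_z_mm", "peak_t", "direction"]
    table = pd.DataFrame(rows, columns=cols)
    return ClusterTable(table=table, labels=out_labels)
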