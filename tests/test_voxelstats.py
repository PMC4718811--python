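"""Voxelwise contrasts: paired t-maps, BH-FDR, cluster extent filtering."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from metconn import BrainMask, BrainVolume, ScanSet, bh_fdr, label_clusters, paired_t_map


def brute_force_bh(p, q):
    """Independent step-up oracle: largest i with p_(i) <= i q / m."""
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


def _scanset(stacks, group=""):
    ids = [f"r{i:03d}" for i in range(len(stacks))]
    vols = [BrainVolume(s, (1.0, 1.0, 1.0)) for s in stacks]
    return ScanSet(ids, vols, group)


class TestPairedTMap:
    def _mask(self, shape):
        return BrainMask(np.ones(shape, dtype=bool), (1.0, 1.0, 1.0))

    def test_identical_groups_give_zero_t(self):
        rng = np.random.default_rng(0)
        stacks = rng.standard_normal((5, 4, 4, 3))
        sm = paired_t_map(_scanset(stacks), _scanset(stacks), self._mask((4, 4, 3)))
        np.testing.assert_allclose(np.nan_to_num(sm.t), 0.0)
        np.testing.assert_allclose(np.nan_to_num(sm.p, nan=1.0), 1.0)
        assert sm.dof == 4

    def test_planted_difference_matches_expected_t(self):
        """Mean difference d with noise sd sigma over n pairs gives
        t close to d / (sigma / sqrt(n)) on average over simulations."""
        d, sigma, n, n_sims = 1.0, 2.0, 20, 200
        expected = d / (sigma / np.sqrt(n))
        rng = np.random.default_rng(7)
        shape = (3, 3, 2)
        t_mean = 0.0
        for _ in range(n_sims):
            base = rng.standard_normal((n, *shape))
            diffs = d + sigma * rng.standard_normal((n, *shape))
            sm = paired_t_map(
                _scanset(base), _scanset(base + diffs), self._mask(shape)
            )
            t_mean += sm.t.mean() / n_sims
        # Monte-Carlo tolerance: SE of the mean t is ~ 1/sqrt(n_sims * n_vox)
        assert t_mean == pytest.approx(expected, rel=0.08)

    def test_two_pairs_rejected(self):
        stacks = np.zeros((2, 3, 3, 3))
        with pytest.raises(ValueError, match="3 pairs"):
            paired_t_map(_scanset(stacks), _scanset(stacks), self._mask((3, 3, 3)))

    def test_unknown_subject_in_pairing_rejected(self):
        stacks = np.zeros((4, 3, 3, 3))
        with pytest.raises(ValueError, match="unknown"):
            paired_t_map(
                _scanset(stacks),
                _scanset(stacks),
                self._mask((3, 3, 3)),
                pairing={"nope": "r000", "r001": "r001", "r002": "r002"},
            )

    def test_unmatched_subjects_dropped_by_default(self):
        rng = np.random.default_rng(1)
        a = _scanset(rng.standard_normal((5, 3, 3, 2)))
        b = _scanset(rng.standard_normal((4, 3, 3, 2)))  # r004 missing
        sm = paired_t_map(a, b, self._mask((3, 3, 2)))
        assert sm.dof == 3  # 4 common pairs


class TestBhFdr:
    def test_all_below_threshold_rejected(self):
        reject, _ = bh_fdr(np.array([0.001, 0.002, 0.003]), q=0.05)
        assert reject.all()

    def test_step_up_example(self):
        # thresholds i*q/m = 0.0125, 0.025, 0.0375, 0.05: the largest i with
        # p_(i) <= i*q/m is 2 (0.04 > 0.0375), so only the first two reject
        reject, _ = bh_fdr(np.array([0.01, 0.02, 0.04, 0.50]), q=0.05)
        np.testing.assert_array_equal(reject, [True, True, False, False])

    def test_empty_input(self):
        reject, qv = bh_fdr(np.array([]), q=0.05)
        assert reject.size == 0 and qv.size == 0

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.5]), q=0.05)

    def test_q_values_dominate_p(self):
        rng = np.random.default_rng(3)
        p = rng.random(100)
        _, qv = bh_fdr(p, q=0.05)
        assert np.all(qv >= p - 1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        p=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50),
        q=st.floats(0.01, 0.2),
    )
    def test_matches_brute_force_oracle(self, p, q):
        p = np.array(p)
        m = len(p)
        # exclude p-values sitting exactly on a step-up boundary, where the
        # decision depends on rounding order in i*q/m (a measure-zero tie)
        thresholds = np.arange(1, m + 1) * q / m
        assume(np.abs(p[:, None] - thresholds[None, :]).min() > 1e-9)
        reject, _ = bh_fdr(p, q)
        np.testing.assert_array_equal(reject, brute_force_bh(p, q))


class TestLabelClusters:
    def _grid(self, shape=(12, 12, 12)):
        return BrainVolume(np.zeros(shape), (1.0, 1.0, 1.0))

    def test_solid_block_survives_extent(self):
        binary = np.zeros((12, 12, 12), dtype=bool)
        binary[2:7, 2:7, 2:7] = True  # 125 voxels
        ct = label_clusters(binary, self._grid(), extent=100)
        assert len(ct) == 1
        assert ct.table.n_voxels.iloc[0] == 125

    def test_component_below_extent_removed(self):
        binary = np.zeros((12, 12, 12), dtype=bool)
        binary[0, :11, :9] = True  # 99 voxels
        ct = label_clusters(binary, self._grid(), extent=100)
        assert len(ct) == 0
        assert not ct.labels.any()

    def test_empty_map_empty_table(self):
        ct = label_clusters(np.zeros((5, 5, 5), dtype=bool), self._grid((5, 5, 5)))
        assert len(ct) == 0

    def test_invalid_connectivity_rejected(self):
        with pytest.raises(ValueError, match="6, 18, 26"):
            label_clusters(np.ones((3, 3, 3), dtype=bool), self._grid((3, 3, 3)),
                           connectivity=10, extent=1)

    @pytest.mark.parametrize("connectivity,expect_joined", [(6, 2), (18, 1)])
    def test_edge_touching_components_depend_on_connectivity(
        self, connectivity, expect_joined
    ):
        # two unit cubes touching along an edge: joined under 18, not under 6
        binary = np.zeros((4, 4, 4), dtype=bool)
        binary[1, 1, 1] = True
        binary[2, 2, 1] = True
        ct = label_clusters(binary, self._grid((4, 4, 4)),
                            connectivity=connectivity, extent=1)
        assert len(ct) == expect_joined

    def test_labeling_invariant_to_axis_order(self):
        rng = np.random.default_rng(5)
        binary = rng.random((10, 10, 10)) > 0.7
        ct = label_clusters(binary, self._grid((10, 10, 10)), extent=3)
        ct_t = label_clusters(
            binary.transpose(2, 0, 1), self._grid((10, 10, 10)), extent=3
        )
        assert sorted(ct.table.n_voxels) == sorted(ct_t.table.n_voxels)

    def test_peak_reported_in_mm(self):
        vol = BrainVolume(np.zeros((8, 8, 8)), (2.0, 2.0, 4.0), (-4.0, 0.0, 0.0))
        binary = np.zeros((8, 8, 8), dtype=bool)
        binary[2:5, 2:5, 2:5] = True
        t_map = np.zeros((8, 8, 8))
        t_map[3, 4, 2] = -7.0  # strongest effect, a decrease
        ct = label_clusters(binary, vol, extent=1, t_map=t_map)
        row = ct.table.iloc[0]
        assert (row.peak_x_mm, row.peak_y_mm, row.peak_z_mm) == (2.0, 8.0, 8.0)
        assert row.direction == "decrease"
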