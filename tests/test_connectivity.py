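"""VOI construction, uptake extraction, correlation, permutation inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metconn import (
    BrainVolume,
    ScanSet,
    VOIMatrix,
    VOISpec,
    correlation_matrix,
    default_vois,
    extract_voi_means,
    fisher_z,
    make_voi_mask,
    permutation_edge_test,
)


def _random_voi_matrix(rng, n=20, p=4, group=""):
    return VOIMatrix(
        rng.standard_normal((n, p)) + 2.0,
        [f"r{i:03d}" for i in range(n)],
        [f"V{j}" for j in range(p)],
        group,
    )


class TestVoiMasks:
    def test_eight_default_specs(self):
        vois = default_vois()
        assert len(vois) == 8
        assert [v.abbreviation for v in vois] == [
            "Hp_L", "Hp_R", "MedF", "Rsp", "Mot_L", "Mot_R", "SS_L", "SS_R",
        ]
        by_comp = {}
        for v in vois:
            by_comp.setdefault(v.component, []).append(v.abbreviation)
        assert {k: len(v) for k, v in by_comp.items()} == {
            "IC1": 3, "IC5": 1, "IC8": 2, "IC9": 2,
        }

    def test_eight_masks_on_analysis_grid(self, small_grid_volume):
        masks = {v.abbreviation: make_voi_mask(v, small_grid_volume)
                 for v in default_vois()}
        assert len(masks) == 8
        assert all(m.n_voxels > 0 for m in masks.values())

    def test_tiny_radius_selects_single_nearest_voxel(self):
        grid = BrainVolume(np.zeros((9, 9, 9)), (2.0, 2.0, 2.0), (-8.0, -8.0, -8.0))
        # radius below half the minimum spacing, centered on a voxel center
        spec = VOISpec("x", "x", ml_mm=0.2, dv_mm=0.2, ap_mm=0.2, radius_mm=0.9)
        mask = make_voi_mask(spec, grid)
        assert mask.n_voxels == 1
        assert mask.values[5, 5, 5]  # nearest center is (2, 2, 2) mm

    def test_voxel_count_matches_brute_force(self, small_grid_volume):
        spec = default_vois()[2]  # MedF
        mask = make_voi_mask(spec, small_grid_volume)
        cx, cy, cz = spec.center_mm
        count = 0
        for i in range(small_grid_volume.shape[0]):
            for j in range(small_grid_volume.shape[1]):
                for k in range(small_grid_volume.shape[2]):
                    x = small_grid_volume.origin_mm[0] + small_grid_volume.voxel_spacing_mm[0] * i
                    y = small_grid_volume.origin_mm[1] + small_grid_volume.voxel_spacing_mm[1] * j
                    z = small_grid_volume.origin_mm[2] + small_grid_volume.voxel_spacing_mm[2] * k
                    d2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
                    count += d2 <= spec.radius_mm**2
        assert mask.n_voxels == count

    def test_center_outside_grid_rejected(self, small_grid_volume):
        spec = VOISpec("far", "far", ml_mm=50.0, dv_mm=3.0, ap_mm=0.0)
        with pytest.raises(ValueError, match="outside"):
            make_voi_mask(spec, small_grid_volume)


class TestExtractVoiMeans:
    def test_constant_volume_gives_constant_entries(self, small_grid_volume):
        vol = small_grid_volume.with_values(np.full(small_grid_volume.shape, 3.5))
        scans = ScanSet(["r000"], [vol], "g")
        masks = {v.abbreviation: make_voi_mask(v, small_grid_volume)
                 for v in default_vois()}
        m = extract_voi_means(scans, masks)
        np.testing.assert_allclose(m.values, 3.5)

    def test_agrees_with_voxel_loop_oracle(self, small_cohort):
        _, scansets, truth = small_cohort
        scans = scansets["10wk"]
        m = extract_voi_means(scans, truth.voi_masks)
        names = list(truth.voi_masks)
        for i in (0, 3):
            for j in (0, 5):
                acc, cnt = 0.0, 0
                mask = truth.voi_masks[names[j]].values
                vol = scans.volumes[i].values
                for idx in np.argwhere(mask):
                    acc += vol[tuple(idx)]
                    cnt += 1
                assert m.values[i, j] == pytest.approx(acc / cnt, abs=1e-6)

    def test_subject_order_preserves_manifest(self, small_cohort):
        _, scansets, truth = small_cohort
        m = extract_voi_means(scansets["5wk"], truth.voi_masks)
        assert m.subject_ids == scansets["5wk"].subject_ids

    def test_grid_mismatch_rejected(self, small_cohort, small_grid_volume):
        _, scansets, truth = small_cohort
        bad = ScanSet(["x"], [BrainVolume(np.zeros((3, 3, 3)), (1, 1, 1))])
        with pytest.raises(ValueError, match="grid"):
            extract_voi_means(bad, truth.voi_masks)


class TestCorrelationMatrix:
    def test_eight_vois_give_28_edges(self):
        rng = np.random.default_rng(0)
        m = _random_voi_matrix(rng, n=20, p=8)
        c = correlation_matrix(m)
        assert c.n_edges == 28
        assert len(c.edge_frame()) == 28

    def test_duplicated_column_gives_unit_r(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal((10, 3))
        vals = np.column_stack([vals, vals[:, 0]])
        m = VOIMatrix(vals, [f"r{i}" for i in range(10)], list("abcd"))
        c = correlation_matrix(m)
        assert c.r[0, 3] == pytest.approx(1.0)

    def test_agrees_with_per_pair_formula(self):
        rng = np.random.default_rng(2)
        m = _random_voi_matrix(rng, n=15, p=5)
        c = correlation_matrix(m)
        for i in range(5):
            for j in range(i + 1, 5):
                a, b = m.values[:, i], m.values[:, j]
                num = np.mean((a - a.mean()) * (b - b.mean()))
                assert c.r[i, j] == pytest.approx(num / (a.std() * b.std()), abs=1e-12)

    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(3)
        c = correlation_matrix(_random_voi_matrix(rng))
        np.testing.assert_allclose(c.r, c.r.T)
        np.testing.assert_allclose(np.diag(c.r), 1.0)

    def test_zero_variance_column_rejected_by_name(self):
        vals = np.ones((10, 3))
        vals[:, :2] = np.random.default_rng(0).standard_normal((10, 2))
        m = VOIMatrix(vals, [f"r{i}" for i in range(10)], ["a", "b", "dead"])
        with pytest.raises(ValueError, match="dead"):
            correlation_matrix(m)

    def test_too_few_subjects_rejected(self):
        m = VOIMatrix(np.random.default_rng(0).standard_normal((3, 4)),
                      list("abc"), list("wxyz"))
        with pytest.raises(ValueError, match="4 subjects"):
            correlation_matrix(m)


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_half_maps_to_known_value(self):
        # atanh(0.5) = ln(3)/2
        assert fisher_z(0.5) == pytest.approx(0.5493061443, abs=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(r=st.floats(-0.999, 0.999))
    def test_antisymmetry(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)

    def test_unit_r_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamp"):
            z = fisher_z(1.0)
        assert np.isfinite(z)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.5)


class TestPermutationEdgeTest:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        a = _random_voi_matrix(rng, group="A")
        b = _random_voi_matrix(rng, group="B")
        r1 = permutation_edge_test(a, b, n_perm=200, seed=11)
        r2 = permutation_edge_test(a, b, n_perm=200, seed=11)
        np.testing.assert_array_equal(r1.table.p.values, r2.table.p.values)

    def test_add_one_rule_floor(self):
        """A difference no permutation can match gets p = 1/(n_perm+1)."""
        rng = np.random.default_rng(1)
        n = 30
        base = rng.standard_normal(n)
        # group A: independent columns; group B: two nearly identical columns
        a = VOIMatrix(rng.standard_normal((n, 2)), [f"r{i}" for i in range(n)],
                      ["u", "v"], "A")
        bvals = np.column_stack([base, base + 1e-6 * rng.standard_normal(n)])
        b = VOIMatrix(bvals, [f"r{i}" for i in range(n)], ["u", "v"], "B")
        res = permutation_edge_test(a, b, n_perm=200, seed=0)
        assert res.table.p.iloc[0] == pytest.approx(1.0 / 201.0)

    def test_exchange_symmetry(self):
        """Swapping the groups flips delta-z but leaves two-sided p unchanged."""
        rng = np.random.default_rng(2)
        a = _random_voi_matrix(rng, n=15, group="A")
        b = _random_voi_matrix(rng, n=12, group="B")
        ab = permutation_edge_test(a, b, n_perm=500, seed=3)
        ba = permutation_edge_test(b, a, n_perm=500, seed=3)
        np.testing.assert_allclose(
            ab.table.delta_z.values, -ba.table.delta_z.values, atol=1e-12
        )
        # same-seed shuffles of the pooled rows differ between orderings, so
        # p-values agree only statistically; check they are close
        np.testing.assert_allclose(ab.table.p.values, ba.table.p.values, atol=0.08)

    def test_column_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        a = _random_voi_matrix(rng)
        b = VOIMatrix(rng.standard_normal((10, 4)), [f"r{i}" for i in range(10)],
                      ["other"] * 2 + ["cols"] * 2)
        with pytest.raises(ValueError):
            permutation_edge_test(a, b, n_perm=200)

    def test_too_few_permutations_rejected(self):
        rng = np.random.default_rng(0)
        a, b = _random_voi_matrix(rng), _random_voi_matrix(rng)
        with pytest.raises(ValueError, match="100"):
            permutation_edge_test(a, b, n_perm=50)
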