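import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import perfconc as pc
from perfconc.concordance import ROIClassification
from perfconc.pet import CBFMap


@pytest.fixture(scope="module")
def atlas(phantom):
    return pc.build_synthetic_atlas(phantom)


def _cls(flags):
    return ROIClassification(hypoperfused=dict(flags), largest_cluster={k: 0 for k in flags})


class TestClassifyRoiHypoperfusion:
    def test_empty_mask_all_negative(self, atlas):
        cls = pc.classify_roi_hypoperfusion(
            np.zeros(atlas.grid.shape, dtype=bool), atlas, 65
        )
        assert not any(cls.hypoperfused.values())

    def test_blob_inside_single_roi_flags_only_it(self, atlas):
        name = atlas.names[1]
        roi = atlas.labels == 1
        idx = np.argwhere(roi)
        mask = np.zeros(atlas.grid.shape, dtype=bool)
        # grow a connected in-ROI blob of ≥ 70 voxels around a seed
        from scipy.ndimage import binary_dilation
        seed = np.zeros_like(mask)
        seed[tuple(idx[len(idx) // 2])] = True
        blob = seed
        while (blob & roi).sum() < 70:
            blob = binary_dilation(blob) & roi
        mask |= blob
        cls = pc.classify_roi_hypoperfusion(mask, atlas, 65)
        assert cls.hypoperfused[name]
        flagged = [k for k, v in cls.hypoperfused.items() if v]
        assert flagged == [name]

    def test_straddling_blob_counts_in_roi_parts_only(self, small_grid):
        labels = np.zeros(small_grid.shape, dtype=np.int16)
        labels[:8] = 1
        labels[8:] = 2
        atlas = pc.ROIAtlas(grid=small_grid, labels=labels,
                            names={1: "A", 2: "B"}, reference_roi="B")
        mask = np.zeros(small_grid.shape, dtype=bool)
        mask[4:12, 3:8, 3:5] = True  # 70-ish voxels straddling the boundary
        in_a = (mask & (labels == 1)).sum()
        in_b = (mask & (labels == 2)).sum()
        assert in_a < 65 and in_b < 65 and in_a + in_b >= 65
        cls = pc.classify_roi_hypoperfusion(mask, atlas, 65)
        assert not cls.hypoperfused["A"] and not cls.hypoperfused["B"]


class TestSensitivitySpecificity:
    def test_identical_classifications(self):
        c = _cls({f"r{i}": i < 5 for i in range(12)})
        assert pc.sensitivity_specificity(c, c) == (1.0, 1.0)

    def test_contingency_arithmetic(self):
        """ref⁺ = 7 ROIs of which test catches 5; ref⁻ = 5 of which test
        clears 4 → (0.714, 0.8)."""
        rois = [f"r{i}" for i in range(12)]
        ref = _cls({r: i < 7 for i, r in enumerate(rois)})
        test = _cls({r: (i < 5) or (i == 7) for i, r in enumerate(rois)})
        sens, spec = pc.sensitivity_specificity(test, ref)
        assert sens == pytest.approx(5 / 7)
        assert spec == pytest.approx(4 / 5)

    def test_all_negative_test(self):
        rois = [f"r{i}" for i in range(6)]
        ref = _cls({r: i < 3 for i, r in enumerate(rois)})
        test = _cls({r: False for r in rois})
        sens, spec = pc.sensitivity_specificity(test, ref)
        assert sens == 0.0 and spec == 1.0

    def test_undefined_sensitivity_is_nan(self):
        rois = ["a", "b"]
        ref = _cls({r: False for r in rois})
        test = _cls({r: False for r in rois})
        sens, spec = pc.sensitivity_specificity(test, ref)
        assert np.isnan(sens) and spec == 1.0


class TestOverlapPartition:
    def test_identical_masks(self):
        m = np.zeros((8, 8, 8), dtype=bool)
        m[2:5, 2:5, 2:5] = True
        assert pc.overlap_partition(m, m) == (100.0, 0.0, 0.0)

    def test_shifted_block_enumeration(self):
        """3×3 in-plane block vs the same block shifted by one voxel:
        overlap 6/9, adjacent 3/9, isolated 0."""
        ref = np.zeros((8, 8, 3), dtype=bool)
        ref[2:5, 2:5, 1] = True
        test = np.zeros_like(ref)
        test[3:6, 2:5, 1] = True
        ov, adj, iso = pc.overlap_partition(test, ref)
        assert ov == pytest.approx(100 * 6 / 9)
        assert adj == pytest.approx(100 * 3 / 9)
        assert iso == 0.0

    def test_disjoint_component_is_isolated(self):
        ref = np.zeros((10, 10, 3), dtype=bool)
        ref[0:2, 0:2, 0] = True
        test = np.zeros_like(ref)
        test[0:2, 0:2, 0] = True  # overlapping part
        test[7:9, 7:9, 2] = True  # far away
        ov, adj, iso = pc.overlap_partition(test, ref)
        assert iso == pytest.approx(100 * 4 / 8)
        assert adj == 0.0

    def test_empty_test_mask_rejected(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        r = m.copy()
        r[0, 0, 0] = True
        with pytest.raises(ValueError):
            pc.overlap_partition(m, r)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10**6))
    def test_percentages_sum_to_100(self, seed):
        rng = np.random.default_rng(seed)
        test = rng.random((6, 6, 6)) > 0.6
        ref = rng.random((6, 6, 6)) > 0.6
        if not test.any():
            test[0, 0, 0] = True
        ov, adj, iso = pc.overlap_partition(test, ref)
        assert ov + adj + iso == pytest.approx(100.0, abs=1e-9)

    def test_subset_of_reference_is_pure_overlap(self):
        ref = np.zeros((8, 8, 8), dtype=bool)
        ref[1:6, 1:6, 1:6] = True
        test = np.zeros_like(ref)
        test[2:4, 2:4, 2:4] = True
        assert pc.overlap_partition(test, ref) == (100.0, 0.0, 0.0)
        assert pc.jaccard(test, ref) == pytest.approx(test.sum() / ref.sum())


class TestJaccardAndVolumeChange:
    def test_set_arithmetic_cases(self):
        a = np.zeros((4, 4, 1), dtype=bool)
        b = np.zeros_like(a)
        a[0, 0] = a[0, 1] = True
        b[0, 1] = b[0, 2] = True
        assert pc.jaccard(a, b) == pytest.approx(1 / 3)
        assert pc.jaccard(a, a) == 1.0
        assert pc.jaccard(a, np.zeros_like(a)) == 0.0
        assert pc.jaccard(np.zeros_like(a), np.zeros_like(a)) == 0.0
        assert pc.jaccard(a, b) == pc.jaccard(b, a)

    def test_volume_change(self):
        ref = np.zeros((10, 10, 1), dtype=bool)
        ref[:10, :10] = True
        test = np.zeros_like(ref)
        test[:8, :10] = True
        assert pc.cluster_volume_change(ref, test) == pytest.approx(20.0)
        assert pc.cluster_volume_change(ref, ref) == 0.0
        assert pc.cluster_volume_change(ref, np.zeros_like(ref)) == 100.0
        with pytest.raises(ValueError):
            pc.cluster_volume_change(np.zeros_like(ref), test)


class TestRoiValues:
    def test_uniform_map_means(self, phantom, atlas):
        m = CBFMap(grid=phantom.grid, values=np.full(phantom.grid.shape, 33.0), modality="pet")
        means = pc.roi_mean_cbf(m, atlas)
        assert all(v == pytest.approx(33.0) for v in means.values())
        assert len(means) == 13

    def test_invalid_voxels_excluded_vs_brute_force(self, phantom, atlas):
        rng = np.random.default_rng(5)
        vals = rng.uniform(10, 90, phantom.grid.shape)
        valid = rng.random(phantom.grid.shape) > 0.3
        m = CBFMap(grid=phantom.grid, values=vals, modality="pet", valid=valid)
        means = pc.roi_mean_cbf(m, atlas)
        for lab, name in atlas.names.items():
            sel = (atlas.labels == lab) & valid
            assert means[name] == pytest.approx(vals[sel].mean(), rel=1e-12)

    def test_regression_affine_recovery(self):
        x = np.array([10.0, 20.0, 30.0, 40.0])
        assert pc.regress_rois(x, x) == pytest.approx((0.0, 1.0, 1.0))
        i, s, r = pc.regress_rois(x, 2 * x + 3)
        assert (i, s, r) == pytest.approx((3.0, 2.0, 1.0))
        with pytest.raises(ValueError):
            pc.regress_rois(np.full(4, 5.0), x)

    def test_pearson_matches_formula_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 8.0, 9.0])
        y = np.array([9.0, 6.0, 5.0, 2.0, 1.5])
        _, _, r = pc.regress_rois(x, y)
        hand = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(hand, abs=1e-12)

    def test_bland_altman_hand_values(self):
        x = np.array([10.0, 10.0])
        y = np.array([12.0, 8.0])  # d = {+2, −2}: sd = 2.828
        bias, lo, hi = pc.bland_altman(x, y)
        assert bias == 0.0
        assert hi == pytest.approx(1.96 * 2.8284271247461903, rel=1e-9)
        assert pc.bland_altman(x, x) == (0.0, 0.0, 0.0)
        bias, lo, hi = pc.bland_altman(x, x + 5.0)
        assert (bias, lo, hi) == (5.0, 5.0, 5.0)


class TestGroupRoiTest:
    def test_identical_groups(self):
        df = pd.DataFrame({"roiA": [1.0, 2.0, 3.0]})
        res = pc.group_roi_test(df, df.copy())
        assert res.loc["roiA", "t"] == 0.0
        assert res.loc["roiA", "p"] == pytest.approx(1.0)

    def test_welch_hand_computation(self):
        a = pd.DataFrame({"r": [1.0, 2.0, 3.0]})
        b = pd.DataFrame({"r": [4.0, 5.0, 6.0]})
        res = pc.group_roi_test(a, b)
        # hand Welch: means 2 and 5, var 1 each, n 3 → t = −3/√(2/3)
        assert res.loc["r", "t"] == pytest.approx(-3 / np.sqrt(2 / 3), rel=1e-12)
        swapped = pc.group_roi_test(b, a)
        assert swapped.loc["r", "t"] == pytest.approx(-res.loc["r", "t"])
        assert swapped.loc["r", "p"] == pytest.approx(res.loc["r", "p"])

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            pc.group_roi_test(pd.DataFrame({"r": [1.0]}), pd.DataFrame({"r": [1.0, 2.0]}))


class TestSummarizeColumns:
    def test_hand_sample_sd(self):
        df = pd.DataFrame({"x": [0.0, 100.0]})
        out = pc.summarize_columns(df)
        assert out.loc["x", "mean"] == 50.0
        assert out.loc["x", "sd"] == pytest.approx(70.71067811865476)

    def test_constant_column(self):
        df = pd.DataFrame({"x": [7.0, 7.0, 7.0]})
        out = pc.summarize_columns(df)
        assert out.loc["x", "mean"] == 7.0 and out.loc["x", "sd"] == 0.0

    def test_reference_cohort_summary_means(self):
        """The built-in per-patient reference table reproduces its published
        column means (to the table's printed rounding)."""
        fl_abs = pc.summarize_columns(pc.ftd_overlap_reference("fl_te", "absolute"))
        assert round(fl_abs.loc["overlap", "mean"], 1) == 29.9
        assert round(fl_abs.loc["adjacent", "mean"], 1) == 56.2
        assert round(fl_abs.loc["jaccard", "mean"], 2) == 0.11
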