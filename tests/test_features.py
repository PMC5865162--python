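"""Feature catalog and per-family feature computations."""

import math

import numpy as np
import pytest

from radsubtypes.features import (
    FeatureTable, compute_circularity, compute_histogram_features,
    compute_intensity_stats, compute_location_features, compute_sphericity,
    compute_volumetric_features, default_catalog, extract_feature_table,
    normalize_channel,
)
from radsubtypes.synthetic import ATLAS_REGIONS, SEG_LABELS, make_atlas


class TestCatalog:
    def test_default_family_counts(self):
        counts = default_catalog().family_counts()
        assert counts == {"volumetric_shape": 11, "intensity": 66,
                          "histogram": 165, "texture": 24, "location": 9,
                          "growth": 3}

    def test_exclusions(self):
        cat = default_catalog(exclusions=["ED_BINS_FLAIR_5", "TU_MEAN_T1"])
        assert len(cat) == 276
        with pytest.raises(ValueError, match="unknown"):
            default_catalog().exclude(["NOT_A_FEATURE"])

    def test_names_unique(self):
        names = default_catalog().names
        assert len(set(names)) == len(names)


class TestVolumetric:
    def test_hand_example(self):
        seg = np.zeros((10, 10, 10), dtype=int)
        seg.flat[:100] = SEG_LABELS["ED"]
        seg.flat[100:200] = SEG_LABELS["NC"]
        seg.flat[200:300] = SEG_LABELS["TU"]
        brain = np.zeros_like(seg, dtype=bool)
        brain.flat[:1000] = True
        vals = compute_volumetric_features(seg, brain)
        assert vals == pytest.approx([0.1, 0.1, 0.1, 1 / 3, 1.0])

    def test_empty_ed_gives_zero_ratio(self):
        seg = np.zeros((6, 6, 6), dtype=int)
        seg[0, 0, 0] = SEG_LABELS["NC"]
        seg[0, 0, 1] = SEG_LABELS["TU"]
        vals = compute_volumetric_features(seg, np.ones_like(seg, bool))
        assert vals[3] == 0.0

    def test_empty_nc_gives_missing_ratio(self):
        seg = np.zeros((6, 6, 6), dtype=int)
        seg[0, 0, 0] = SEG_LABELS["ED"]
        seg[0, 0, 1] = SEG_LABELS["TU"]
        vals = compute_volumetric_features(seg, np.ones_like(seg, bool))
        assert math.isnan(vals[4])

    def test_empty_brain_errors(self):
        with pytest.raises(ValueError, match="brain"):
            compute_volumetric_features(np.zeros((4, 4, 4), int),
                                        np.zeros((4, 4, 4), bool))

    def test_matches_brute_force_counting(self):
        rng = np.random.default_rng(1)
        seg = rng.choice([0, 1, 2, 4], size=(20, 20, 20))
        brain = rng.random((20, 20, 20)) < 0.9
        vals = compute_volumetric_features(seg, brain)
        # exhaustive voxel-count oracle
        n = {lab: 0 for lab in (1, 2, 4)}
        for v in seg.ravel():
            if v in n:
                n[v] += 1
        nb = int(sum(1 for v in brain.ravel() if v))
        ed, nc, tu = n[2], n[1], n[4]
        expect = [ed / nb, nc / nb, tu / nb, ed / (ed + nc + tu), tu / nc]
        assert vals == pytest.approx(expect)


class TestShape:
    def test_square_circularity_closed_form(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        assert compute_circularity(mask) == pytest.approx(math.pi / 4)

    def test_single_voxel_circularity(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        assert compute_circularity(mask) == pytest.approx(4 * math.pi / 16)

    def test_disk_circularity_manhattan_limit(self):
        """Edge-count perimeter of a disk converges to 8r, so circularity
        converges to pi^2/16, not 1 (Manhattan perimeter bias)."""
        r = 40
        y, x = np.indices((2 * r + 5, 2 * r + 5))
        mask = (y - r - 2) ** 2 + (x - r - 2) ** 2 <= r ** 2
        assert compute_circularity(mask) == pytest.approx(math.pi ** 2 / 16, rel=0.10)

    def test_cube_sphericity_closed_form(self):
        mask = np.zeros((16, 16, 16), bool)
        mask[3:13, 3:13, 3:13] = True
        assert compute_sphericity(mask) == pytest.approx((math.pi / 6) ** (1 / 3))

    def test_ball_sphericity_face_count_limit(self):
        """Face-count surface of a ball converges to 1.5x the true area, so
        sphericity converges to 2/3."""
        r = 30
        z, y, x = np.indices((2 * r + 5,) * 3)
        mask = (z - r - 2) ** 2 + (y - r - 2) ** 2 + (x - r - 2) ** 2 <= r ** 2
        assert compute_sphericity(mask) == pytest.approx(2 / 3, rel=0.10)

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        mask = np.zeros((20, 20, 20), bool)
        mask[4:9, 5:11, 6:10] = rng.random((5, 6, 4)) < 0.7
        shifted = np.roll(mask, (3, -2, 4), axis=(0, 1, 2))
        assert compute_sphericity(mask) == pytest.approx(compute_sphericity(shifted))

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            compute_circularity(np.zeros((4, 4), bool))
        with pytest.raises(ValueError):
            compute_sphericity(np.zeros((4, 4, 4), bool))


class TestIntensity:
    def test_constant_region(self):
        vol = np.full((6, 6, 6), 3.5)
        mask = np.zeros_like(vol, bool)
        mask[1:3, 1:3, 1:3] = True
        assert compute_intensity_stats(vol, mask) == (3.5, 0.0)

    def test_hand_arithmetic(self):
        vol = np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1)
        mean, sd = compute_intensity_stats(vol, np.ones((4, 1, 1), bool))
        assert mean == 2.5
        assert sd == pytest.approx(math.sqrt(1.25))  # population SD

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(3)
        vol = rng.normal(size=(8, 8, 8))
        mask = rng.random((8, 8, 8)) < 0.4
        mean, sd = compute_intensity_stats(vol, mask)
        vals = [float(v) for v, m in zip(vol.ravel(), mask.ravel()) if m]
        m1 = sum(vals) / len(vals)
        m2 = sum((v - m1) ** 2 for v in vals) / len(vals)
        assert mean == pytest.approx(m1, abs=1e-12)
        assert sd == pytest.approx(math.sqrt(m2), abs=1e-12)


class TestHistogram:
    def test_point_mass_in_middle_bin(self):
        vol = np.full((5, 5, 5), 0.5)
        mask = np.ones_like(vol, bool)
        assert list(compute_histogram_features(vol, mask)) == [0, 0, 100, 0, 0]

    def test_uniform_grid_counts(self):
        vals = np.linspace(0, 1, 1000).reshape(10, 10, 10)
        pct = compute_histogram_features(vals, np.ones_like(vals, bool))
        # exact per-bin counts of the 1000 grid points
        idx = np.minimum((vals.ravel() * 5).astype(int), 4)
        expect = np.bincount(idx, minlength=5) / 10.0
        np.testing.assert_allclose(pct, expect)
        assert all(abs(p - 20) <= 0.5 for p in pct)

    def test_sums_to_100(self):
        rng = np.random.default_rng(4)
        vol = rng.random((7, 7, 7))
        mask = rng.random((7, 7, 7)) < 0.5
        assert compute_histogram_features(vol, mask).sum() == pytest.approx(100, abs=1e-6)

    def test_empty_region_gives_nans(self):
        out = compute_histogram_features(np.ones((3, 3, 3)), np.zeros((3, 3, 3), bool))
        assert np.isnan(out).all()

    def test_normalize_channel_clips_to_unit_interval(self):
        rng = np.random.default_rng(5)
        vol = rng.normal(100, 20, size=(10, 10, 10))
        brain = np.ones_like(vol, bool)
        normed = normalize_channel(vol, brain)
        assert normed.min() >= 0 and normed.max() <= 1


class TestLocation:
    def test_single_region_core(self):
        atlas = make_atlas((24, 24, 24))
        frontal = atlas == (ATLAS_REGIONS.index("frontal") + 1)
        core = np.zeros_like(frontal)
        idx = np.argwhere(frontal)[:40]
        core[tuple(idx.T)] = True
        pct = compute_location_features(core, atlas)
        assert pct[ATLAS_REGIONS.index("frontal")] == 100.0
        assert pct.sum() == pytest.approx(100.0)

    def test_even_split(self):
        atlas = np.zeros((4, 4, 4), int)
        atlas[:2] = 1
        atlas[2:] = 2
        core = np.zeros((4, 4, 4), bool)
        core[1, 0, 0] = core[2, 0, 0] = True
        pct = compute_location_features(core, atlas)
        assert pct[0] == pct[1] == 50.0

    def test_matches_exhaustive_tally(self):
        atlas = make_atlas((20, 20, 20))
        rng = np.random.default_rng(6)
        core = rng.random((20, 20, 20)) < 0.1
        core &= atlas > 0
        pct = compute_location_features(core, atlas)
        tally = np.zeros(9)
        for pos in np.argwhere(core):
            lab = atlas[tuple(pos)]
            tally[lab - 1] += 1
        np.testing.assert_allclose(pct, tally / core.sum() * 100)

    def test_empty_core_errors(self):
        with pytest.raises(ValueError, match="core"):
            compute_location_features(np.zeros((4, 4, 4), bool), np.ones((4, 4, 4), int))


class TestExtractTable:
    def test_shape_and_no_missing(self, small_table):
        assert small_table.frame.shape == (12, 278)
        assert not small_table.frame.isna().any().any()

    def test_intensity_column_count(self, small_table):
        intensity = [s for s in small_table.catalog.specs if s.family == "intensity"]
        assert len(intensity) == 66

    def test_histogram_rows_sum_to_100(self, small_table):
        for region in ("TU", "NC", "ED"):
            for channel in ("T1", "rCBV"):
                cols = [f"{region}_BINS_{channel}_{b}" for b in range(1, 6)]
                sums = small_table.frame[cols].sum(axis=1)
                np.testing.assert_allclose(sums, 100.0, atol=1e-6)

    def test_deterministic_rows(self, small_cohort, atlas):
        studies, _ = small_cohort
        dup = [studies[0], studies[0]]
        table = extract_feature_table(dup, atlas)
        np.testing.assert_array_equal(table.frame.iloc[0].to_numpy(),
                                      table.frame.iloc[1].to_numpy())

    def test_missing_channel_errors(self, small_cohort, atlas):
        import copy
        studies, _ = small_cohort
        broken = copy.copy(studies[0])
        broken.channels = {k: v for k, v in studies[0].channels.items() if k != "FA"}
        with pytest.raises(ValueError, match="FA"):
            extract_feature_table([broken], atlas)

    def test_translation_invariance_of_geometry_features(self, small_cohort, atlas):
        """Volumetric, shape and location features are unchanged when the whole
        study (and atlas) is translated on the voxel grid."""
        import copy
        studies, _ = small_cohort
        st = studies[0]
        # shift within the lesion's free margin so np.roll does not wrap it
        lesion = np.argwhere(st.segmentation > 0)
        shift = tuple(int(min(2, st.segmentation.shape[a] - 1 - lesion[:, a].max()))
                      for a in range(3))
        assert any(shift)
        moved = copy.copy(st)
        moved.segmentation = np.roll(st.segmentation, shift, axis=(0, 1, 2))
        moved.channels = {k: np.roll(v, shift, axis=(0, 1, 2))
                          for k, v in st.channels.items()}
        atlas_moved = np.roll(atlas, shift, axis=(0, 1, 2))
        a = extract_feature_table([st], atlas).frame
        b = extract_feature_table([moved], atlas_moved).frame
        geom = [c for c in a.columns
                if c.endswith(("_VOLNORM", "_RATIO", "_CIRC", "_SPHER"))
                or c.startswith("LOC_")]
        np.testing.assert_allclose(a[geom].to_numpy(), b[geom].to_numpy(),
                                   rtol=1e-12)
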