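import numpy as np
import pytest
from hypothesis import given, strategies as st

from pethet.imgio import PETVolume, VOIMask
from pethet.texture import (
    NGLCM,
    TextureConfig,
    aggregate_patient,
    aggregate_patients,
    build_nglcm,
    extract_features,
    features_frame,
    glcm_contrast,
    glcm_entropy,
    glcm_homogeneity,
    histogram_cov,
    quantize_values,
    quantize_voi,
    size_variation,
)

from .conftest import checkerboard, make_lesion
from .oracles import brute_nglcm, brute_size_variation


def nglcm_from(p, offsets=(), pairs=100):
    return NGLCM(p=np.asarray(p, float), offsets_used=offsets, pair_count=pairs)


class TestQuantization:
    @pytest.mark.parametrize(
        ("values", "ng", "expected"),
        [
            ([0, 1, 2, 3], 4, [1, 2, 3, 4]),
            ([5, 5, 5], 8, [1, 1, 1]),
            ([0, 0.1, 9.9, 10], 2, [1, 1, 2, 2]),  # threshold at 5
        ],
    )
    def test_examples(self, values, ng, expected):
        np.testing.assert_array_equal(quantize_values(np.array(values), ng), expected)

    def test_rejects_single_level(self):
        with pytest.raises(ValueError, match="ng"):
            quantize_values(np.array([1.0, 2.0]), 1)

    @given(
        vals=st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=40),
        ng=st.integers(2, 64),
    )
    def test_monotone_and_bounded(self, vals, ng):
        """Quantization is monotone in SUV and stays within 1..ng."""
        levels = quantize_values(np.array(vals), ng)
        assert levels.min() >= 1 and levels.max() <= ng
        order = np.argsort(vals, kind="stable")
        assert np.all(np.diff(levels[order]) >= 0)


class TestNGLCM:
    def test_constant_lesion_single_cell(self, constant_lesion):
        vol, mask = constant_lesion
        nglcm = build_nglcm(quantize_voi(vol, mask, ng=4))
        assert nglcm.p[0, 0] == 1.0
        assert nglcm.p.sum() == pytest.approx(1.0)

    def test_checkerboard_matches_pair_enumerator(self, checkerboard_lesion):
        vol, mask = checkerboard_lesion
        q = quantize_voi(vol, mask, ng=2)
        nglcm = build_nglcm(q)
        p_oracle, pairs_oracle = brute_nglcm(q.grid_levels, 2)
        np.testing.assert_allclose(nglcm.p, p_oracle, atol=1e-12)
        assert nglcm.pair_count == pairs_oracle
        # axis and body-diagonal neighbors differ in parity -> off-diagonal mass
        assert nglcm.p[0, 1] == nglcm.p[1, 0] > 0

    def test_random_masks_match_enumerator(self, rng):
        for _ in range(20):
            shape = tuple(rng.integers(3, 6, size=3))
            grid = rng.random(shape) * 10
            mask = rng.random(shape) > 0.4
            if mask.sum() < 2:
                continue
            vol, voi = PETVolume(grid, (1, 1, 1)), VOIMask(mask, "P", "bone", "L0")
            q = quantize_voi(vol, voi, ng=6)
            try:
                nglcm = build_nglcm(q)
            except ValueError:
                continue  # isolated voxels only
            p_oracle, _ = brute_nglcm(q.grid_levels, 6)
            np.testing.assert_allclose(nglcm.p, p_oracle, atol=1e-12)
            np.testing.assert_allclose(nglcm.p, nglcm.p.T, atol=1e-15)
            assert nglcm.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_isolated_voxel_raises(self):
        grid = np.zeros((5, 5, 5))
        grid[2, 2, 2] = 7.0
        mask = grid > 0
        vol, voi = PETVolume(grid, (1, 1, 1)), VOIMask(mask, "P", "bone", "L0")
        with pytest.raises(ValueError, match="pair"):
            build_nglcm(quantize_voi(vol, voi, ng=2))


class TestMatrixFeatures:
    def test_entropy_closed_forms(self):
        single = nglcm_from(np.eye(1))  # all mass in one cell
        assert glcm_entropy(single) == 0.0
        uniform = nglcm_from(np.full((64, 64), 1.0 / 64**2))
        assert glcm_entropy(uniform) == pytest.approx(12.0)
        p = np.zeros((2, 2))
        p[0, 0], p[0, 1], p[1, 0] = 0.5, 0.25, 0.25
        assert glcm_entropy(nglcm_from(p)) == pytest.approx(1.5)

    def test_entropy_log_base(self):
        uniform = nglcm_from(np.full((4, 4), 1.0 / 16))
        assert glcm_entropy(uniform, log_base=np.e) == pytest.approx(np.log(16))

    def test_homogeneity_closed_forms(self):
        diag = nglcm_from(np.eye(3) / 3)
        assert glcm_homogeneity(diag) == pytest.approx(1.0)
        offdiag = np.zeros((2, 2))
        offdiag[0, 1] = offdiag[1, 0] = 0.5
        assert glcm_homogeneity(nglcm_from(offdiag)) == pytest.approx(0.5)
        p = np.zeros((3, 3))
        p[0, 0], p[0, 2], p[2, 0] = 0.5, 0.25, 0.25
        assert glcm_homogeneity(nglcm_from(p)) == pytest.approx(0.5 + 0.5 / 3)

    def test_contrast_closed_forms(self):
        diag = nglcm_from(np.eye(3) / 3)
        assert glcm_contrast(diag) == 0.0
        offdiag = np.zeros((2, 2))
        offdiag[0, 1] = offdiag[1, 0] = 0.5
        assert glcm_contrast(nglcm_from(offdiag)) == pytest.approx(1.0)
        far = np.zeros((3, 3))
        far[0, 2] = far[2, 0] = 0.5
        assert glcm_contrast(nglcm_from(far)) == pytest.approx(4.0)


class TestCOV:
    def test_examples(self):
        assert histogram_cov(np.full(10, 3.0)) == 0.0
        assert histogram_cov(np.array([2.0, 4.0])) == pytest.approx(1 / 3)
        assert histogram_cov(np.array([2.0, 4.0]), sd_mode="sample") == pytest.approx(
            np.sqrt(2) / 3
        )

    def test_scale_invariance(self, rng):
        vals = rng.random(50) + 0.5
        assert histogram_cov(7.3 * vals) == pytest.approx(histogram_cov(vals))

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError, match="mean"):
            histogram_cov(np.array([-1.0, 1.0]))


class TestSizeVariation:
    def test_constant_lesion_zero(self, constant_lesion):
        vol, mask = constant_lesion
        assert size_variation(quantize_voi(vol, mask, 8)) == 0.0

    @pytest.mark.parametrize("ng", [2, 4, 8])
    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_checkerboard_matches_neighbor_oracle(self, ng, connectivity):
        vals = checkerboard((4, 4, 4)) * 10.0
        vol, mask = make_lesion(vals)
        q = quantize_voi(vol, mask, ng)
        got = size_variation(q, connectivity)
        expected = brute_size_variation(q.grid_levels, connectivity)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_value_grows_with_level_spread(self):
        # same pattern at wider quantization -> larger neighbor differences
        vals = checkerboard((4, 4, 4)) * 10.0
        vol, mask = make_lesion(vals)
        results = [
            size_variation(quantize_voi(vol, mask, ng)) for ng in (2, 4, 8)
        ]
        assert results[0] < results[1] < results[2]

    def test_random_masks_match_oracle(self, rng):
        for _ in range(15):
            shape = tuple(rng.integers(3, 6, size=3))
            grid = rng.random(shape) * 5
            mask = rng.random(shape) > 0.3
            if mask.sum() < 2:
                continue
            vol, voi = PETVolume(grid, (1, 1, 1)), VOIMask(mask, "P", "bone", "L0")
            q = quantize_voi(vol, voi, 5)
            try:
                got = size_variation(q)
            except ValueError:
                continue
            assert got == pytest.approx(brute_size_variation(q.grid_levels), abs=1e-12)


class TestExtractFeatures:
    def test_constant_lesion_degenerate_values(self, constant_lesion):
        vol, mask = constant_lesion
        f = extract_features(vol, mask, TextureConfig(min_voxels=4))
        assert (f.cov, f.entropy, f.contrast, f.size_variation) == (0, 0, 0, 0)
        assert f.homogeneity == 1.0
        assert f.suv_mean == pytest.approx(5.0)

    def test_deterministic(self, rng):
        vol, mask = make_lesion(rng.random((5, 5, 5)) * 8 + 1)
        cfg = TextureConfig(min_voxels=4)
        f1, f2 = extract_features(vol, mask, cfg), extract_features(vol, mask, cfg)
        assert f1 == f2

    def test_small_lesion_flagged_not_dropped(self, constant_lesion):
        vol, mask = constant_lesion
        with pytest.warns(UserWarning, match="62-voxel floor"):
            f = extract_features(vol, mask)  # 27 voxels < default floor of 62
        assert f.below_min_voxels

    def test_invariant_under_axis_permutation_and_flip(self, rng):
        vals = rng.random((4, 5, 6)) * 10
        vol, mask = make_lesion(vals)
        cfg = TextureConfig(min_voxels=4)
        ref = extract_features(vol, mask, cfg)
        names = ("suv_mean", "cov", "entropy", "homogeneity", "contrast", "size_variation")
        transformed = [
            (np.transpose(vol.values, perm), np.transpose(mask.mask, perm))
            for perm in [(1, 0, 2), (2, 1, 0), (0, 2, 1)]
        ] + [(vol.values[::-1].copy(), mask.mask[::-1].copy())]
        for vals_t, mask_t in transformed:
            f = extract_features(
                PETVolume(vals_t, (1, 1, 1)), VOIMask(mask_t, "P", "bone", "L0"), cfg
            )
            for name in names:
                assert getattr(f, name) == pytest.approx(getattr(ref, name), rel=1e-12)

    def test_invariant_to_background_level(self, rng):
        vals = rng.random((4, 4, 4)) * 10
        cfg = TextureConfig(min_voxels=4)
        f0 = extract_features(*make_lesion(vals, background=0.0), cfg)
        f9 = extract_features(*make_lesion(vals, background=9.0), cfg)
        assert f0 == f9

    def test_glcm_features_invariant_under_affine_suv_rescale(self, rng):
        vals = rng.random((4, 4, 4)) * 10 + 2
        cfg = TextureConfig(min_voxels=4)
        ref = extract_features(*make_lesion(vals), cfg)
        scaled = extract_features(*make_lesion(3.0 * vals + 1.0), cfg)
        for name in ("entropy", "homogeneity", "contrast", "size_variation"):
            assert getattr(scaled, name) == pytest.approx(getattr(ref, name))
        pure_scale = extract_features(*make_lesion(3.0 * vals), cfg)
        assert pure_scale.cov == pytest.approx(ref.cov)

    def test_entropy_bounds_and_ranges(self, rng):
        vol, mask = make_lesion(rng.random((5, 5, 5)) * 10)
        cfg = TextureConfig(ng=16, min_voxels=4)
        f = extract_features(vol, mask, cfg)
        assert 0 <= f.entropy <= 2 * np.log2(16)
        assert 0 < f.homogeneity <= 1
        assert 0 <= f.contrast <= 15**2
        assert f.cov >= 0 and f.size_variation >= 0


class TestAggregation:
    def _feats(self, entropy):
        from pethet.texture import LesionFeatures

        return LesionFeatures(
            suv_mean=5.0, cov=0.2, entropy=entropy, homogeneity=0.5,
            contrast=10.0, size_variation=2.0, volume_cm3=20.0, n_voxels=160,
        )

    def test_single_and_identical_lesions(self):
        one = aggregate_patient({"bone": [self._feats(4.0)]})
        assert one["bone"].entropy == 4.0
        three = aggregate_patient({"bone": [self._feats(4.0)] * 3})
        assert three["bone"].entropy == 4.0

    def test_mean_over_three_bone_lesions(self):
        agg = aggregate_patient({"bone": [self._feats(e) for e in (4.0, 5.0, 6.0)]})
        assert agg["bone"].entropy == pytest.approx(5.0)

    def test_frame_aggregation_per_site(self):
        records = [
            ("P0", "bone", f"L{i}", self._feats(e)) for i, e in enumerate((4.0, 5.0, 6.0))
        ] + [("P0", "lymph_node", "L3", self._feats(2.0))]
        table = features_frame(records)
        agg = aggregate_patients(table)
        bone = agg[(agg.patient_id == "P0") & (agg.site == "bone")].iloc[0]
        assert bone.entropy == pytest.approx(5.0)
        assert bone.n_lesions == 3
        ln = agg[(agg.patient_id == "P0") & (agg.site == "lymph_node")].iloc[0]
        assert ln.entropy == 2.0
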