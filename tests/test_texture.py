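import numpy as np
import pytest

from oracles import glcm_brute_force, haralick_brute_force
from perfradiomics.io import IN_PLANE_DIRECTIONS, MapKind, ParametricVolume, RunConfig, VOIMask
from perfradiomics.texture import (
    HARALICK_FEATURE_NAMES,
    GLCMatrix,
    compute_glcm,
    directional_summary,
    extract_map_features,
    extract_subject_features,
    extract_texture_features,
    haralick_features,
    normalize_glcm,
    requantize,
)
from conftest import random_masked_volume


def _full_mask(shape):
    return VOIMask(np.ones(shape, dtype=bool))


class TestRequantize:
    def test_integer_ramp_maps_to_successive_levels(self):
        vox = np.arange(8, dtype=float).reshape(8, 1, 1)
        vol = ParametricVolume(vox, (1, 1, 1), MapKind.KTRANS)
        q = requantize(vol, _full_mask(vox.shape), G=8)
        # bin width (7-0)/8: value v falls in bin floor(v/0.875)+1, max clipped to 8
        expected = np.minimum(np.floor(np.arange(8) / 0.875).astype(int) + 1, 8)
        np.testing.assert_array_equal(q.levels.ravel(), expected)
        assert q.levels.min() == 1 and q.levels.max() == 8

    def test_constant_input_all_level_one(self):
        vox = np.full((4, 4, 2), 5.5)
        vol = ParametricVolume(vox, (1, 1, 1), MapKind.KTRANS)
        for G in (2, 8, 256):
            q = requantize(vol, _full_mask(vox.shape), G)
            assert set(np.unique(q.levels)) == {1}

    def test_affine_invariance(self, rng):
        vol, mask = random_masked_volume(rng, shape=(7, 7, 4))
        q1 = requantize(vol, mask, 16)
        vol2 = ParametricVolume(3.7 * vol.voxels + 11.0, vol.spacing, vol.map_kind)
        q2 = requantize(vol2, mask, 16)
        np.testing.assert_array_equal(q1.levels, q2.levels)

    def test_sentinel_zero_outside_mask(self, rng):
        vol, mask = random_masked_volume(rng, shape=(6, 6, 3), p_mask=0.5)
        q = requantize(vol, mask, 8)
        assert (q.levels[~mask.voxels] == 0).all()
        assert (q.levels[mask.voxels] >= 1).all() and (q.levels[mask.voxels] <= 8).all()

    def test_extremes_hit_levels_one_and_G(self, ktrans_pair):
        vol, mask = ktrans_pair
        q = requantize(vol, mask, 32)
        inside = q.levels[mask.voxels]
        assert inside.min() == 1 and inside.max() == 32


class TestGLCM:
    def test_worked_single_slice_example(self):
        levels = np.array([[1, 1, 2], [1, 2, 2]])[:, :, None]
        vol = ParametricVolume(levels - 1.0, (1, 1, 1), MapKind.KTRANS)
        mask = _full_mask(levels.shape)
        q = requantize(vol, mask, 2)
        np.testing.assert_array_equal(q.levels, levels)
        m = compute_glcm(q, mask, (0, 1))
        assert m.counts[0, 0] == 2
        assert m.counts[0, 1] == 2 and m.counts[1, 0] == 2
        assert m.counts[1, 1] == 2
        assert m.total == 8

    @pytest.mark.parametrize("G", [4, 8])
    def test_matches_brute_force_on_random_masked_volumes(self, G):
        """Accumulation equals explicit pair enumeration: 50 volumes x 4 directions."""
        rng = np.random.default_rng(G)
        for trial in range(50):
            vol, mask = random_masked_volume(rng, shape=(6, 6, 3))
            q = requantize(vol, mask, G)
            for direction in IN_PLANE_DIRECTIONS:
                try:
                    m = compute_glcm(q, mask, direction)
                except ValueError:
                    # degenerate for this direction: oracle must agree it is empty
                    assert glcm_brute_force(q.levels, mask.voxels, direction, 1, G).sum() == 0
                    continue
                expected = glcm_brute_force(q.levels, mask.voxels, direction, 1, G)
                np.testing.assert_array_equal(m.counts, expected)

    def test_constant_volume_all_mass_at_origin(self):
        vox = np.full((5, 5, 2), 2.0)
        vol = ParametricVolume(vox, (1, 1, 1), MapKind.KTRANS)
        mask = _full_mask(vox.shape)
        q = requantize(vol, mask, 8)
        m = compute_glcm(q, mask, (0, 1))
        assert m.counts[0, 0] == m.total > 0
        assert (m.counts.sum() - m.counts[0, 0]) == 0

    def test_symmetry(self, rng):
        vol, mask = random_masked_volume(rng, shape=(8, 8, 2))
        q = requantize(vol, mask, 8)
        for direction in IN_PLANE_DIRECTIONS:
            m = compute_glcm(q, mask, direction)
            np.testing.assert_array_equal(m.counts, m.counts.T)

    def test_degenerate_direction_raises(self):
        mask_arr = np.zeros((3, 3, 1), dtype=bool)
        mask_arr[0, 0, 0] = True  # a single voxel: no pair in any direction
        vol = ParametricVolume(np.ones((3, 3, 1)), (1, 1, 1), MapKind.KTRANS)
        mask = VOIMask(mask_arr)
        q = requantize(vol, mask, 4)
        with pytest.raises(ValueError, match="degenerate VOI"):
            compute_glcm(q, mask, (0, 1))


class TestNormalize:
    def test_uniform_counts_normalize_to_uniform(self):
        m = GLCMatrix(counts=np.full((8, 8), 3.0), direction=(0, 1))
        p = normalize_glcm(m)
        np.testing.assert_allclose(p.counts, 1 / 64)

    def test_sums_to_one_and_idempotent(self, rng):
        c = rng.random((6, 6))
        c = c + c.T
        m = GLCMatrix(counts=c, direction=(0, 1))
        p1 = normalize_glcm(m)
        assert p1.counts.sum() == pytest.approx(1.0, abs=1e-12)
        p2 = normalize_glcm(p1)
        np.testing.assert_allclose(p2.counts, p1.counts, atol=1e-15)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero-total"):
            normalize_glcm(GLCMatrix(counts=np.zeros((4, 4)), direction=(0, 1)))


class TestHaralick:
    def test_uniform_matrix_closed_forms(self):
        G = 8
        p = GLCMatrix(np.full((G, G), 1 / G**2), (0, 1), normalized=True)
        f = haralick_features(p)
        assert f["entropy"] == pytest.approx(6.0, abs=1e-12)  # log2(64)
        assert f["energy"] == pytest.approx(1 / 64, abs=1e-15)
        assert f["maximum_probability"] == pytest.approx(1 / 64, abs=1e-15)

    def test_single_diagonal_cell(self):
        G = 6
        c = np.zeros((G, G))
        c[2, 2] = 1.0
        f = haralick_features(GLCMatrix(c, (0, 1), normalized=True))
        assert f["energy"] == 1.0
        assert f["entropy"] == 0.0
        assert f["contrast"] == 0.0
        assert f["dissimilarity"] == 0.0
        assert f["maximum_probability"] == 1.0

    def test_matches_direct_summation_oracle(self):
        """Every feature vs the brute-force double-loop oracle, random 4x4 inputs."""
        rng = np.random.default_rng(77)
        for _ in range(25):
            c = rng.random((4, 4))
            c = c + c.T
            p = c / c.sum()
            ours = haralick_features(GLCMatrix(p, (0, 1), normalized=True))
            oracle = haralick_brute_force(p)
            assert set(ours) == set(HARALICK_FEATURE_NAMES)
            for name in HARALICK_FEATURE_NAMES:
                assert ours[name] == pytest.approx(oracle[name], abs=1e-10), name

    def test_range_invariants(self, rng):
        c = rng.random((8, 8)) + 0.01
        c = c + c.T
        f = haralick_features(GLCMatrix(c / c.sum(), (0, 1), normalized=True))
        assert 0 < f["energy"] <= 1
        assert f["entropy"] >= 0
        assert 0 < f["maximum_probability"] <= 1
        assert -1 <= f["correlation"] <= 1
        assert 0 <= f["imc2"] <= 1

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            haralick_features(GLCMatrix(np.ones((4, 4)), (0, 1), normalized=False))


class TestDirectionalSummary:
    def test_constant_directions(self):
        s = directional_summary([2.0, 2.0, 2.0, 2.0])
        assert (s.average, s.range, s.angular_variance) == (2.0, 0.0, 0.0)

    def test_worked_example(self):
        s = directional_summary([1.0, 3.0, 2.0, 4.0])
        assert s.average == 2.5
        assert s.range == 3.0
        assert s.angular_variance == 1.25  # population variance, divisor 4

    def test_permutation_invariance(self, rng):
        v = rng.normal(size=4)
        base = directional_summary(v)
        for _ in range(5):
            s = directional_summary(rng.permutation(v))
            assert s.average == pytest.approx(base.average, rel=1e-12)
            assert s.range == base.range
            assert s.angular_variance == pytest.approx(base.angular_variance, rel=1e-12)

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError, match="4"):
            directional_summary([1.0, 2.0, 3.0])


class TestExtraction:
    def test_exactly_300_texture_columns(self, ktrans_pair):
        vol, mask = ktrans_pair
        feats = extract_texture_features(vol, mask)
        assert len(feats) == 300  # 20 features x 5 gray levels x 3 summaries
        gs = {name.split("|")[2] for name in feats}
        assert gs == {"G8", "G16", "G32", "G64", "G256"}

    def test_310_per_map_620_fused(self, pd_lesion):
        kt = pd_lesion[MapKind.KTRANS]
        rc = pd_lesion[MapKind.RCBV]
        per_map = extract_map_features(*kt)
        assert len(per_map) == 310
        fused = extract_subject_features(kt, rc)
        assert len(fused) == 620
        assert len([n for n in fused if n.startswith("ktrans|")]) == 310
        assert len([n for n in fused if n.startswith("rcbv|")]) == 310

    def test_both_maps_absent_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            extract_subject_features(None, None)

    def test_rotation_invariance_of_all_texture_features(self, rng):
        """90-degree in-plane rotation (volume+mask jointly) leaves all 300 unchanged."""
        vol, mask = random_masked_volume(rng, shape=(10, 10, 4))
        base = extract_texture_features(vol, mask)
        rot_vol = ParametricVolume(
            np.rot90(vol.voxels, axes=(0, 1)).copy(), vol.spacing, vol.map_kind
        )
        rot_mask = VOIMask(np.rot90(mask.voxels, axes=(0, 1)).copy())
        rotated = extract_texture_features(rot_vol, rot_mask)
        for name, value in base.items():
            assert rotated[name] == pytest.approx(value, rel=1e-9, abs=1e-9), name

    def test_affine_intensity_invariance(self, ktrans_pair):
        vol, mask = ktrans_pair
        base = extract_texture_features(vol, mask)
        vol2 = ParametricVolume(2.5 * vol.voxels + 0.3, vol.spacing, vol.map_kind)
        other = extract_texture_features(vol2, mask)
        for name, value in base.items():
            assert other[name] == pytest.approx(value, abs=1e-9), name

    def test_constant_volume_entropy_zero_energy_one(self):
        vox = np.full((8, 8, 3), 1.23)
        vol = ParametricVolume(vox, (1, 1, 1), MapKind.KTRANS)
        feats = extract_texture_features(vol, _full_mask(vox.shape))
        for g in (8, 16, 32, 64, 256):
            assert feats[f"ktrans|glcm|G{g}|entropy|avg"] == 0.0
            assert feats[f"ktrans|glcm|G{g}|energy|avg"] == 1.0

    def test_deterministic_re_extraction(self, ktrans_pair):
        vol, mask = ktrans_pair
        a = extract_map_features(vol, mask)
        b = extract_map_features(vol, mask)
        assert a == b
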