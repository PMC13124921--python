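import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from amyhist.errors import InvalidArgumentError, InvalidInputError
from amyhist.volumes import (
    BinaryMask,
    ScalarVolume,
    load_volume,
    make_parenchyma_mask,
    make_tissue_mask,
    resample_upsample,
    save_volume,
)


def prob_volume(data):
    return ScalarVolume.from_voxel_size(np.asarray(data, dtype=float), (1, 1, 1), "probability")


class TestScalarVolume:
    def test_rejects_non_3d(self):
        with pytest.raises(InvalidInputError):
            ScalarVolume.from_voxel_size(np.zeros((4, 4)), (1, 1, 1), "suv")

    def test_rejects_nan(self):
        data = np.zeros((3, 3, 3))
        data[1, 1, 1] = np.nan
        with pytest.raises(InvalidInputError):
            ScalarVolume.from_voxel_size(data, (1, 1, 1), "suv")

    def test_rejects_probability_out_of_range(self):
        with pytest.raises(InvalidInputError):
            prob_volume(np.full((3, 3, 3), 1.5))

    def test_rejects_negative_labels(self):
        with pytest.raises(InvalidInputError):
            ScalarVolume.from_voxel_size(np.full((3, 3, 3), -1), (1, 1, 1), "label")

    def test_voxel_size_from_affine(self):
        v = ScalarVolume.from_voxel_size(np.zeros((3, 3, 3)), (2.3, 2.3, 4.0), "suv")
        np.testing.assert_allclose(v.voxel_size_mm, [2.3, 2.3, 4.0])


class TestResampleUpsample:
    def test_factor_one_identity(self, ramp_volume):
        out = resample_upsample(ramp_volume, 1)
        np.testing.assert_array_equal(out.data, ramp_volume.data)
        np.testing.assert_array_equal(out.affine, ramp_volume.affine)

    def test_constant_volume_reproduced(self):
        v = ScalarVolume.from_voxel_size(np.full((6, 5, 4), 1.3), (1, 1, 1), "suvr")
        out = resample_upsample(v, 2)
        assert out.shape == (12, 10, 8)
        np.testing.assert_allclose(out.data, 1.3, atol=1e-9)

    def test_ramp_lattice_points_preserved(self, ramp_volume):
        # oracle: analytic ramp formula value = 0.1*i + 0.5 at original lattice
        out = resample_upsample(ramp_volume, 2)
        i = np.arange(12)
        expected = 0.1 * i + 0.5
        np.testing.assert_allclose(out.data[2 * i, 0, 0], expected, atol=1e-6)

    def test_ramp_interior_matches_analytic(self, ramp_volume):
        # cubic interpolation tracks linear functions in the interior; spline
        # prefiltering with edge padding leaves a small boundary ripple
        out = resample_upsample(ramp_volume, 2)
        j = np.arange(4, 20)  # interior output indices
        expected = 0.1 * (j / 2) + 0.5
        np.testing.assert_allclose(out.data[j, 5, 5], expected, atol=5e-3)

    def test_geometry_scaling(self, ramp_volume):
        out = resample_upsample(ramp_volume, 2)
        np.testing.assert_allclose(out.voxel_size_mm, ramp_volume.voxel_size_mm / 2)
        # world coordinate of output voxel 2i equals that of input voxel i
        p_in = ramp_volume.affine @ np.array([3, 4, 2, 1])
        p_out = out.affine @ np.array([6, 8, 4, 1])
        np.testing.assert_allclose(p_in, p_out, atol=1e-12)

    def test_invalid_factor(self, ramp_volume):
        with pytest.raises(InvalidArgumentError):
            resample_upsample(ramp_volume, 0)

    def test_non_finite_rejected(self, ramp_volume):
        ramp_volume.data[0, 0, 0] = np.inf
        with pytest.raises(InvalidInputError):
            resample_upsample(ramp_volume, 2)

    def test_probability_clipped(self, rng):
        p = prob_volume(rng.uniform(0, 1, (8, 8, 8)))
        out = resample_upsample(p, 2)
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0

    def test_label_uses_nearest(self):
        labels = ScalarVolume.from_voxel_size(
            np.arange(27).reshape(3, 3, 3), (1, 1, 1), "label"
        )
        out = resample_upsample(labels, 3, method="cubic")
        assert np.issubdtype(out.data.dtype, np.integer)
        assert set(np.unique(out.data)) <= set(range(27))
        # original lattice points keep their labels
        np.testing.assert_array_equal(out.data[::3, ::3, ::3], labels.data)


class TestParenchymaMask:
    def test_sum_above_threshold_included(self):
        m = make_parenchyma_mask(
            prob_volume([[[0.30]]]), prob_volume([[[0.25]]])
        )
        assert m.data[0, 0, 0] and m.voxel_count == 1

    def test_sum_equal_threshold_excluded(self):
        m = make_parenchyma_mask(
            prob_volume([[[0.25]]]), prob_volume([[[0.25]]])
        )
        assert not m.data[0, 0, 0]

    def test_brute_force_count(self, rng):
        pg = rng.uniform(0, 0.6, (4, 4, 4))
        pw = rng.uniform(0, 0.4, (4, 4, 4))
        m = make_parenchyma_mask(prob_volume(pg), prob_volume(pw))
        # oracle: exhaustive loop over all 64 voxels
        k = sum(
            1
            for i in range(4)
            for j in range(4)
            for l in range(4)
            if pg[i, j, l] + pw[i, j, l] > 0.5
        )
        assert m.voxel_count == k

    def test_shape_mismatch(self):
        with pytest.raises(InvalidInputError):
            make_parenchyma_mask(
                prob_volume(np.zeros((3, 3, 3))), prob_volume(np.zeros((4, 4, 4)))
            )


class TestTissueMask:
    def test_strict_boundary(self):
        assert make_tissue_mask(prob_volume([[[0.61]]])).voxel_count == 1
        assert make_tissue_mask(prob_volume([[[0.60]]])).voxel_count == 0

    def test_all_zero(self):
        assert make_tissue_mask(prob_volume(np.zeros((4, 4, 4)))).voxel_count == 0

    def test_brute_force_equivalence(self, rng):
        p = rng.uniform(0, 1, (5, 5, 5))
        m = make_tissue_mask(prob_volume(p), 0.6)
        for i in range(5):
            for j in range(5):
                for l in range(5):
                    assert m.data[i, j, l] == (p[i, j, l] > 0.6)

    def test_threshold_out_of_range(self):
        with pytest.raises(InvalidArgumentError):
            make_tissue_mask(prob_volume(np.zeros((3, 3, 3))), threshold=1.5)


@given(
    pg=hnp.arrays(
        float, (4, 4, 4), elements=st.floats(0, 1, allow_nan=False, width=32)
    ),
    frac=st.floats(0.0, 1.0),
)
@settings(max_examples=50, deadline=None)
def test_masks_disjoint_and_nested(pg, frac):
    # p_wm = frac * (1 - p_gm) guarantees p_gm + p_wm <= 1
    pw = frac * (1.0 - pg)
    gm = make_tissue_mask(prob_volume(pg), 0.6)
    wm = make_tissue_mask(prob_volume(pw), 0.6)
    par = make_parenchyma_mask(prob_volume(pg), prob_volume(pw), 0.5)
    assert not np.any(gm.data & wm.data)
    assert np.all(par.data[gm.data | wm.data])


def test_upsample_mask_count_scales_cubically(small_phantom):
    _, p_gm, _, _, _ = small_phantom
    n1 = make_tissue_mask(p_gm, 0.6).voxel_count
    n2 = make_tissue_mask(resample_upsample(p_gm, 2), 0.6).voxel_count
    assert abs(n2 / (8 * n1) - 1) < 0.2


def test_nifti_round_trip(tmp_path, small_phantom):
    suv = small_phantom[0]
    path = tmp_path / "suv.nii"
    save_volume(suv, path)
    back = load_volume(path, "suv")
    np.testing.assert_allclose(back.data, suv.data, rtol=1e-7)
    np.testing.assert_allclose(back.affine, suv.affine, atol=1e-6)


def test_missing_file_raises():
    with pytest.raises(FileNotFoundError, match="nowhere.nii"):
        load_volume("nowhere.nii", "suv")


def test_binary_mask_invariants():
    m = BinaryMask.from_array(np.eye(3, dtype=bool)[None, :, :])
    assert m.voxel_count == 3
    with pytest.raises(InvalidInputError):
        BinaryMask(np.zeros((2, 2, 2), dtype=bool), (3, 3, 3))
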