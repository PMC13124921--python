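import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amyhist.errors import InvalidInputError, UndefinedResultError
from amyhist.histostats import (
    Histogram,
    binned_moments,
    build_histogram,
    descriptive_params,
    mode_value,
    sample_excess_kurtosis,
    sample_skewness,
)
from amyhist.model import ThreeComponentSpec, sample_voxels
from amyhist.volumes import BinaryMask, make_parenchyma_mask

from conftest import volume_from_values


def full_mask(vol):
    return BinaryMask.from_array(np.ones(vol.shape, dtype=bool))


class TestBuildHistogram:
    def test_single_voxel_placement(self):
        v = volume_from_values([1.02])
        h = build_histogram(v, full_mask(v))
        assert h.counts.sum() == 1
        idx = int(np.argmax(h.counts))
        assert h.bin_edges[idx] == pytest.approx(1.00)
        assert h.bin_edges[idx + 1] == pytest.approx(1.05)

    def test_half_open_boundary(self):
        v = volume_from_values([1.05])
        h = build_histogram(v, full_mask(v))
        idx = int(np.argmax(h.counts))
        assert h.bin_edges[idx] == pytest.approx(1.05)
        assert h.bin_edges[idx + 1] == pytest.approx(1.10)

    def test_conservation_on_phantom(self, small_phantom):
        suv, p_gm, p_wm, _, _ = small_phantom
        m = make_parenchyma_mask(p_gm, p_wm)
        h = build_histogram(suv, m)
        assert h.total == m.voxel_count

    def test_empty_mask_rejected(self):
        v = volume_from_values([1.0, 2.0])
        with pytest.raises(InvalidInputError):
            build_histogram(v, BinaryMask.from_array(np.zeros(v.shape, dtype=bool)))

    def test_explicit_range_clamps_and_flags(self):
        v = volume_from_values([0.1, 1.0, 5.0])
        h = build_histogram(v, full_mask(v), range=(0.5, 2.0))
        assert h.clipped
        assert h.total == 3
        assert h.counts[0] >= 1 and h.counts[-1] >= 1


class TestSkewness:
    def test_symmetric_zero(self):
        assert sample_skewness([1, 2, 3]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_formula(self):
        # oracle: n/((n-1)(n-2)) * sum(z^3) = (4/6)*3 = 2.0
        assert sample_skewness([0, 0, 0, 1]) == pytest.approx(2.0)

    def test_symmetry_limit(self, rng):
        x = rng.normal(size=10**6)
        se = np.sqrt(6 / x.size)
        assert abs(sample_skewness(x)) < 3 * se

    def test_too_few_or_constant(self):
        with pytest.raises(UndefinedResultError):
            sample_skewness([1.0, 2.0])
        with pytest.raises(UndefinedResultError):
            sample_skewness([1.0, 1.0, 1.0])


class TestKurtosis:
    def test_hand_formula(self):
        # oracle: 1.25*10.4 - 8.0 = 5.0 for the standard correction term
        assert sample_excess_kurtosis([0, 0, 0, 0, 1]) == pytest.approx(5.0)

    def test_alt_variant(self):
        # 1.25*10.4 - 3*4/6 = 13 - 2 = 11
        assert sample_excess_kurtosis([0, 0, 0, 0, 1], variant="alt") == pytest.approx(11.0)

    def test_two_point_limit(self):
        x = np.tile([-1.0, 1.0], 5000)
        assert sample_excess_kurtosis(x) == pytest.approx(-2.0, abs=1e-3)

    def test_gaussian_limit(self, rng):
        x = rng.normal(size=10**6)
        se = np.sqrt(24 / x.size)
        assert abs(sample_excess_kurtosis(x)) < 3 * se

    def test_too_few(self):
        with pytest.raises(UndefinedResultError):
            sample_excess_kurtosis([0.0, 1.0, 2.0])


class TestMode:
    def test_single_bin(self):
        h = Histogram(bin_edges=[1.00, 1.05], counts=[4])
        assert mode_value(h) == pytest.approx(1.025)

    def test_tie_breaks_low(self):
        edges = np.arange(1.00, 1.60 + 1e-9, 0.05)
        counts = np.zeros(len(edges) - 1)
        counts[0] = 5  # [1.00, 1.05)
        counts[10] = 5  # [1.50, 1.55)
        h = Histogram(bin_edges=edges, counts=counts)
        assert mode_value(h) == pytest.approx(1.025)

    def test_empty_rejected(self):
        h = Histogram(bin_edges=[1.0, 1.05, 1.1], counts=[0, 0])
        with pytest.raises(InvalidInputError):
            mode_value(h)


class TestDescriptiveParams:
    def test_mmr_identity(self, rng):
        x = rng.normal(1.2, 0.1, 4000)
        v = volume_from_values(x)
        d = descriptive_params(v, full_mask(v))
        assert d.mmr == pytest.approx(d.mode / d.mean)

    def test_hand_mmr(self):
        # mean 1.20 by construction, mode bin [1.04, 1.12) center 1.08 -> MMR 0.9
        vals = [1.05, 1.06, 1.10, 1.11, 1.36, 1.36, 1.36]
        v = volume_from_values(vals)
        h = build_histogram(v, full_mask(v), bin_width=0.08)
        d = descriptive_params(v, full_mask(v), h)
        assert d.mean == pytest.approx(1.20, abs=1e-9)
        assert d.mode == pytest.approx(1.08)
        assert d.mmr == pytest.approx(0.9, abs=1e-3)

    def test_negative_model_mmr_below_one(self):
        # simulator run: default spec with piG2 = 0 puts the peak left of the mean
        spec = ThreeComponentSpec(piG2=0.0)
        values, _ = sample_voxels(spec, 200_000, seed=3)
        v = volume_from_values(values)
        d = descriptive_params(v, full_mask(v))
        assert d.mmr < 1.0

    def test_zero_mean_rejected(self):
        v = volume_from_values([-1.0, 0.0, 1.0, 0.0])
        with pytest.raises(UndefinedResultError):
            descriptive_params(v, full_mask(v))


@given(
    a=st.floats(-2, 2),
    b=st.floats(0.1, 5),
)
@settings(max_examples=30, deadline=None)
def test_skewness_affine_invariance(a, b):
    x = np.array([0.1, 0.4, 0.45, 0.9, 1.7, 2.0, 2.2, 3.3])
    s = sample_skewness(x)
    assert sample_skewness(a + b * x) == pytest.approx(s, rel=1e-9, abs=1e-9)
    assert sample_skewness(a - b * x) == pytest.approx(-s, rel=1e-9, abs=1e-9)


def test_binned_moments_agree_with_exact(small_phantom):
    suv, p_gm, p_wm, _, _ = small_phantom
    m = make_parenchyma_mask(p_gm, p_wm)
    h = build_histogram(suv, m)
    binned = binned_moments(h)
    values = suv.data[m.data]
    assert abs(binned["skewness"] - sample_skewness(values)) < 0.02
    assert abs(binned["excess_kurtosis"] - sample_excess_kurtosis(values)) < 0.02


def test_kurtosis_decreases_with_separation(rng):
    # planted two-Gaussian mixtures: wider separation -> lower excess kurtosis
    kurts = []
    for sep in [0.0, 0.5, 1.0, 2.0, 3.0]:
        x = np.concatenate(
            [rng.normal(0, 1, 50_000), rng.normal(sep, 1, 50_000)]
        )
        kurts.append(sample_excess_kurtosis(x))
    assert all(b < a for a, b in zip(kurts, kurts[1:]))
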