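import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dwimc import (
    AlgorithmConfig,
    lowpass,
    mad,
    reject_repetitions,
    reject_voxels,
    slice_sums,
)

from conftest import make_stack


class TestMad:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([2, 4, 6, 8, 100], 2.0),  # median 6, |dev| median 2
            ([1, 2], 0.5),  # even-length median is the midpoint
            ([7, 7, 7, 7], 0.0),  # constant data has zero spread
        ],
    )
    def test_hand_examples(self, values, expected):
        assert mad(values) == expected

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            mad([])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(0, 1e6), min_size=1, max_size=30),
        st.floats(0.1, 100.0),
    )
    def test_scale_equivariance_and_nonnegativity(self, values, c):
        m = mad(values)
        assert m >= 0
        np.testing.assert_allclose(mad([c * v for v in values]), c * m, rtol=1e-9)


class TestSliceSums:
    def test_hand_sum(self):
        st_ = make_stack(np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 1, 2, 2))
        assert slice_sums(st_)[0, 0] == 10.0

    def test_linearity(self, random_stack):
        np.testing.assert_allclose(
            slice_sums(make_stack(2.5 * random_stack.data)),
            2.5 * slice_sums(random_stack),
        )


class TestRejectRepetitions:
    def test_hand_example(self):
        # zeta = [100, 98, 102, 101, 99, 5]: median 99.5, MAD 1.5,
        # threshold 99.5 - 5*1.5 = 92; only the dead repetition falls below.
        zeta = [100.0, 98.0, 102.0, 101.0, 99.0, 5.0]
        stack = make_stack(np.array(zeta).reshape(1, 6, 1, 1))
        rejected, threshold, z = reject_repetitions(stack, AlgorithmConfig())
        np.testing.assert_allclose(threshold, [92.0])
        np.testing.assert_array_equal(rejected[0], [False] * 5 + [True])

    def test_equal_sums_reject_nothing(self):
        stack = make_stack(np.full((2, 4, 3, 3), 7.0))
        rejected, threshold, zeta = reject_repetitions(stack)
        assert not rejected.any()
        np.testing.assert_allclose(threshold, np.median(zeta, axis=1))

    def test_single_repetition_never_rejected(self):
        stack = make_stack(np.ones((1, 1, 2, 2)))
        rejected, _, _ = reject_repetitions(stack)
        assert not rejected.any()

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 12), st.floats(0.5, 10.0))
    def test_at_most_half_rejected(self, seed, n_reps, lam):
        rng = np.random.default_rng(seed)
        stack = make_stack(rng.uniform(0, 50, size=(2, n_reps, 3, 3)))
        cfg = AlgorithmConfig(lambda_rep=lam)
        rejected, _, _ = reject_repetitions(stack, cfg)
        assert (rejected.sum(axis=1) <= n_reps // 2).all()

    def test_invariant_to_common_rescaling(self, random_stack):
        r1, _, _ = reject_repetitions(random_stack)
        r2, _, _ = reject_repetitions(make_stack(17.3 * random_stack.data))
        np.testing.assert_array_equal(r1, r2)


class TestLowpass:
    def test_sigma_zero_is_identity(self, random_stack):
        assert lowpass(random_stack, 0.0) is random_stack

    def test_constant_image_preserved(self):
        stack = make_stack(np.full((1, 2, 16, 16), 42.0))
        np.testing.assert_allclose(lowpass(stack, 2.0).data, 42.0)

    def test_impulse_mass_preserved(self):
        # Away from boundaries a normalized Gaussian preserves total mass.
        data = np.zeros((1, 1, 41, 41))
        data[0, 0, 20, 20] = 123.0
        out = lowpass(make_stack(data), 2.0)
        np.testing.assert_allclose(out.data.sum(), 123.0, rtol=1e-8)
        assert (out.data >= 0).all()


def brute_force_voxel_masks(filtered, rep_rejected, lam):
    """Literal per-voxel median/MAD thresholding, loop form."""
    n_z, n_i, n_y, n_x = filtered.shape
    mask = np.zeros(filtered.shape, dtype=bool)
    for z in range(n_z):
        kept = [i for i in range(n_i) if not rep_rejected[z, i]]
        for y in range(n_y):
            for x in range(n_x):
                series = [filtered[z, i, y, x] for i in kept]
                med = np.median(series)
                m = np.median(np.abs(np.asarray(series) - med))
                t = med - lam * m
                for i in range(n_i):
                    if rep_rejected[z, i]:
                        mask[z, i, y, x] = True
                    elif filtered[z, i, y, x] < t:
                        mask[z, i, y, x] = True
    return mask


class TestRejectVoxels:
    def test_hand_example(self, voxel_series_stack):
        # Series [50, 52, 48, 51, 10]: median 50, |dev| = [0, 2, 2, 1, 40]
        # whose median is 2, so the threshold is 50 - 3*2 = 44 and only
        # the dropped-out value 10 is rejected.
        stack = voxel_series_stack([50, 52, 48, 51, 10])
        rejected, threshold = reject_voxels(stack, np.zeros((1, 5), bool))
        np.testing.assert_allclose(threshold, 44.0)
        np.testing.assert_array_equal(rejected[0, :, 0, 0], [0, 0, 0, 0, 1])

    def test_constant_series_rejects_nothing(self, voxel_series_stack):
        stack = voxel_series_stack([9.0] * 6)
        rejected, _ = reject_voxels(stack, np.zeros((1, 6), bool))
        assert not rejected.any()

    def test_globally_rejected_repetitions_flagged_wholesale(self, random_stack):
        rep_rejected = np.zeros((1, 5), bool)
        rep_rejected[0, 2] = True
        rejected, _ = reject_voxels(random_stack, rep_rejected)
        assert rejected[0, 2].all()

    def test_statistics_exclude_rejected_repetitions(self):
        # A dead repetition must not drag the median down: with it
        # excluded the kept stats give threshold 100 - 3*0.5 = 98.5, so
        # the value 99 survives while the dead repetition stays flagged.
        series = np.array([100.0, 101.0, 99.0, 100.0, 0.0]).reshape(1, 5, 1, 1)
        rep_rejected = np.zeros((1, 5), bool)
        rep_rejected[0, 4] = True
        rejected, threshold = reject_voxels(make_stack(series), rep_rejected)
        assert threshold[0, 0, 0] > 0.0
        np.testing.assert_array_equal(rejected[0, :, 0, 0], [0, 0, 0, 0, 1])

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_oracle(self, trial, cfg):
        rng = np.random.default_rng(1000 + trial)
        stack = make_stack(rng.uniform(0, 100, size=(1, 5, 4, 4)))
        rep_rejected = rng.random((1, 5)) < 0.2
        if rep_rejected.all():
            rep_rejected[0, 0] = False
        fast, _ = reject_voxels(stack, rep_rejected, cfg)
        slow = brute_force_voxel_masks(stack.data, rep_rejected, cfg.lambda_vxl)
        np.testing.assert_array_equal(fast, slow)

    def test_invariant_to_common_rescaling(self, random_stack, cfg):
        flags = np.zeros((1, 5), bool)
        r1, _ = reject_voxels(random_stack, flags, cfg)
        r2, _ = reject_voxels(make_stack(0.01 * random_stack.data), flags, cfg)
        np.testing.assert_array_equal(r1, r2)

    def test_noise_only_rejection_rate_is_small(self, rng):
        # Pure noise fluctuation around a bright mean: the raw-MAD
        # threshold at lambda=3 rejects a few percent of entries
        # (measured ~3.5% for N=18; see docs/methods.md), never more.
        stack = make_stack(rng.normal(100.0, 5.0, size=(2, 18, 24, 24)).clip(min=0))
        rejected, _ = reject_voxels(stack, np.zeros((2, 18), bool))
        assert rejected.mean() < 0.05


class TestAlgorithmConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lambda_rep": 0.0},
            {"lambda_vxl": -1.0},
            {"lowpass_sigma": -0.1},
            {"weight_clip": 0.0},
            {"weight_clip": 1.5},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AlgorithmConfig(**kwargs)
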