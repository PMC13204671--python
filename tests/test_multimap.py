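"""The four-stage mapping chain and its ablation variants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semgmap import (
    MappingConfig,
    Recording,
    dynamic_range_interval,
    lg_map,
    linear_compress,
    multiple_mapping,
    sigmoid_normalize,
    sliding_average_power,
)
from semgmap.errors import LengthError


def naive_sliding_power(x, w):
    """Definitional O(n·w) oracle for the windowed mean of squares."""
    out = []
    for i in range(len(x) - w + 1):
        acc = 0.0
        for b in range(i, i + w):
            acc += x[b] ** 2
        out.append(acc / w)
    return np.array(out)


class TestSlidingAveragePower:
    def test_constant_signal(self):
        out = sliding_average_power(np.full(30, 3.0), w=5)
        assert out.shape == (26,)
        np.testing.assert_allclose(out, 9.0)

    def test_window_of_one_is_elementwise_square(self, rng):
        x = rng.standard_normal(20)
        np.testing.assert_array_equal(sliding_average_power(x, 1), x**2)

    @pytest.mark.parametrize("case", range(100))
    def test_matches_naive_loop_oracle(self, case):
        rng = np.random.default_rng(1000 + case)
        n = int(rng.integers(10, 60))
        w = int(rng.integers(1, n + 1))
        x = rng.standard_normal(n) * 10.0 ** rng.integers(-6, 2)
        np.testing.assert_allclose(
            sliding_average_power(x, w), naive_sliding_power(x, w),
            rtol=1e-12, atol=0,
        )

    def test_too_short_raises(self):
        with pytest.raises(LengthError):
            sliding_average_power(np.ones(5), w=6)


class TestLgMap:
    def test_abs_of_small_power(self):
        np.testing.assert_allclose(lg_map(np.array([1e-10])), [10.0])

    def test_zero_floored_by_epsilon(self):
        np.testing.assert_allclose(lg_map(np.array([0.0]), epsilon=1e-20), [20.0])

    def test_signed_variant(self):
        np.testing.assert_allclose(
            lg_map(np.array([1e-10]), use_abs=False), [-10.0]
        )

    def test_lognormal_becomes_symmetric(self):
        # log10 of a lognormal sample is normal: skewness collapses.
        rng = np.random.default_rng(42)
        p = rng.lognormal(mean=-20, sigma=1.5, size=10_000)
        y = lg_map(p, use_abs=False)
        exponent = (np.log(p)) / np.log(10)  # direct recomputation
        np.testing.assert_allclose(y, exponent, rtol=1e-12)
        z = (y - y.mean()) / y.std(ddof=1)
        sk = len(y) / ((len(y) - 1) * (len(y) - 2)) * np.sum(z**3)
        assert abs(sk) < 0.1

    def test_rejects_negative_power(self):
        with pytest.raises(Exception, match="non-negative"):
            lg_map(np.array([-1.0]))


class TestLinearCompress:
    def test_endpoint_and_midpoint(self):
        np.testing.assert_allclose(
            linear_compress(np.array([2.0, 3.0, 4.0]), half_width=4.0),
            [-4.0, 0.0, 4.0],
        )

    def test_constant_maps_to_midpoint(self):
        np.testing.assert_array_equal(
            linear_compress(np.full(5, 7.0)), np.zeros(5)
        )

    def test_dynamic_range_bookkeeping(self):
        # 1e-6..1e-4 V amplitudes: 100-fold ratio, 4 decades of log-power.
        j, J = dynamic_range_interval(zmax=1e-4, zmin=1e-6)
        assert j == pytest.approx(100.0)
        assert J == pytest.approx(4.0)


class TestSigmoid:
    def test_midpoint(self):
        assert sigmoid_normalize(np.array([0.0]))[0] == 0.5

    def test_saturation_endpoints(self):
        out = sigmoid_normalize(np.array([4.0, -4.0]))
        assert out[0] == pytest.approx(0.982, abs=5e-4)
        assert out[1] == pytest.approx(0.018, abs=5e-4)

    def test_full_range_image(self, rng):
        v = rng.uniform(-4, 4, size=1000)
        out = sigmoid_normalize(v)
        assert np.all((out >= 0.0179) & (out <= 0.9821))


class TestMultipleMapping:
    @staticmethod
    def _two_constant_channels(n=300):
        return Recording(
            np.vstack([np.full(n, 1e-5), np.full(n, 1e-4)]), fs=2000.0
        )

    def test_t2_constant_powers_separate_100fold(self):
        fm = multiple_mapping(self._two_constant_channels(),
                              MappingConfig(variant="T2", w=50))
        np.testing.assert_allclose(fm.values[0], 1e-10, rtol=1e-9)
        np.testing.assert_allclose(fm.values[1], 1e-8, rtol=1e-9)

    def test_t4_hand_composed_on_constants(self):
        # powers 1e-10 and 1e-8 -> |lg| = 10 and 8 -> global min/max compress
        # to +4 and -4 -> sigmoid 0.982 and 0.018: the abs reverses order.
        fm = multiple_mapping(self._two_constant_channels(),
                              MappingConfig(variant="T4", w=50))
        np.testing.assert_allclose(fm.values[0], 1 / (1 + np.exp(-4)), rtol=1e-9)
        np.testing.assert_allclose(fm.values[1], 1 / (1 + np.exp(4)), rtol=1e-9)

    def test_t4_outputs_open_unit_interval(self, small_recording):
        fm = multiple_mapping(small_recording, MappingConfig(variant="T4"))
        assert np.all((fm.values > 0) & (fm.values < 1))

    @pytest.mark.parametrize("variant,stage,length", [
        ("T1", "zscore", 1000),
        ("T2", "power", 801),
        ("T3", "lg", 801),
        ("T4", "sigmoid", 801),
    ])
    def test_stage_and_length_contract(self, small_recording, variant, stage, length):
        fm = multiple_mapping(small_recording, MappingConfig(variant=variant, w=200))
        assert fm.stage == stage
        assert fm.values.shape == (8, length)

    def test_channel_index_attached_to_errors(self):
        rec = Recording(np.ones((3, 10)), fs=100.0)
        with pytest.raises(LengthError, match="channel 0"):
            multiple_mapping(rec, MappingConfig(variant="T2", w=50))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_t4_monotone_decreasing_in_power_with_abs(self, seed):
        # For powers inside (0,1) the |lg| flips order, compression and
        # sigmoid are increasing: the composed map strictly reverses order.
        rng = np.random.default_rng(seed)
        p = np.sort(10.0 ** rng.uniform(-12, -6, size=20))
        p = np.unique(p)
        lg = lg_map(p, use_abs=True)
        out = sigmoid_normalize(linear_compress(lg))
        assert np.all(np.diff(out) < 0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_t4_monotone_increasing_without_abs(self, seed):
        rng = np.random.default_rng(seed)
        p = np.unique(np.sort(10.0 ** rng.uniform(-12, -6, size=20)))
        lg = lg_map(p, use_abs=False)
        out = sigmoid_normalize(linear_compress(lg))
        assert np.all(np.diff(out) > 0)


class TestDistributionCorrectionProperty:
    def test_lg_reduces_skew_in_95_of_100_trials(self):
        wins = 0
        for trial in range(100):
            rng = np.random.default_rng(5000 + trial)
            p = rng.lognormal(mean=-22, sigma=1.2, size=10_000)
            z_before = (p - p.mean()) / p.std(ddof=1)
            y = lg_map(p, use_abs=False)
            z_after = (y - y.mean()) / y.std(ddof=1)
            m = p.size
            c = m / ((m - 1) * (m - 2))
            if abs(c * np.sum(z_after**3)) < abs(c * np.sum(z_before**3)):
                wins += 1
        assert wins >= 95
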