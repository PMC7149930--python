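"""Time-domain parameters against frozen examples and naive-loop oracles."""

import math

import numpy as np
import pytest

from hrnv.time_domain import (
    kurtosis,
    mean_nn,
    nn50_family,
    rmssd,
    sdnn,
    skewness,
    triangular_index,
)

from .conftest import random_rr
from .oracles import (
    naive_moments,
    naive_nn50,
    naive_rmssd,
    naive_sd,
    naive_triangular_index,
)

SIX = [800.0, 810.0, 790.0, 805.0, 795.0, 820.0]


class TestBasicStatistics:
    def test_mean(self):
        assert mean_nn([1610.0, 1595.0, 1615.0]) == pytest.approx(1606.666666667)
        assert mean_nn([800.0]) == 800.0

    def test_sdnn_frozen_and_constant(self):
        # sample SD of the six-interval example, denominator 5
        assert sdnn(SIX) == pytest.approx(10.80123, abs=1e-5)
        assert sdnn([700.0] * 10) == 0.0

    def test_rmssd_frozen(self):
        # sqrt((100+400+225+100+625)/5)
        assert rmssd(SIX) == pytest.approx(17.02939, abs=1e-5)
        assert rmssd([700.0] * 5) == 0.0
        assert rmssd([700.0, 640.0]) == pytest.approx(60.0)

    def test_scaling_homogeneity(self, rng):
        x = rng.normal(800, 40, 100)
        for f, k in ((mean_nn, 3.7), (sdnn, 3.7), (rmssd, 3.7)):
            assert f(k * x) == pytest.approx(k * f(x), rel=1e-12)

    def test_short_series_errors(self):
        with pytest.raises(ValueError):
            mean_nn([])
        with pytest.raises(ValueError):
            sdnn([800.0])
        with pytest.raises(ValueError):
            rmssd([800.0])


class TestNN50Family:
    def test_worked_example(self):
        nn50, pnn50, nn50n, pnn50n = nn50_family([1610.0, 1500.0, 1615.0, 1612.0], 2)
        assert nn50 == 2          # |-110| and |115| exceed 50; |-3| does not
        assert nn50n == 2         # threshold 100 ms
        assert pnn50 == pytest.approx(50.0)
        assert pnn50n == pytest.approx(50.0)

    def test_constant_series(self):
        assert nn50_family([800.0] * 6, 3) == (0, 0.0, 0, 0.0)

    def test_absent_for_n1(self):
        nn50, pnn50, nn50n, pnn50n = nn50_family(SIX, 1)
        assert nn50n is None and pnn50n is None

    def test_strict_inequality_at_threshold(self):
        # a difference of exactly 50 ms does not count
        assert nn50_family([800.0, 850.0, 800.0], 1)[0] == 0
        assert nn50_family([800.0, 850.5, 800.0], 1)[0] == 2

    def test_pair_denominator_option(self):
        _, pnn50, _, _ = nn50_family([800.0, 900.0, 800.0], 1, denominator="pairs")
        assert pnn50 == pytest.approx(100.0)

    def test_scaled_threshold_never_counts_more(self, rng):
        x = rng.normal(1600, 120, 200)
        nn50, _, nn50n, _ = nn50_family(x, 2)
        assert nn50n <= nn50


class TestShapeAndGeometry:
    def test_symmetric_skewness_zero(self):
        assert skewness([790.0, 800.0, 810.0]) == pytest.approx(0.0, abs=1e-12)

    def test_normal_kurtosis_approaches_three(self, rng):
        x = rng.standard_normal(200_000)
        assert kurtosis(x) == pytest.approx(3.0, abs=0.06)
        assert kurtosis(x, excess=True) == pytest.approx(0.0, abs=0.06)

    def test_moments_brute_force(self):
        x = [1.0, 1.0, 1.0, 10.0]
        sk, ku = naive_moments(x)
        assert skewness(x) == pytest.approx(sk, rel=1e-12)
        assert kurtosis(x) == pytest.approx(ku, rel=1e-12)

    def test_zero_variance_returns_nan_with_warning(self):
        with pytest.warns(UserWarning):
            assert math.isnan(skewness([5.0] * 10))
        with pytest.warns(UserWarning):
            assert math.isnan(kurtosis([5.0] * 10))

    def test_triangular_index_definitions(self):
        # all in one bin -> 1;  10 elements with modal bin of 4 -> 2.5
        assert triangular_index([800.0, 801.0, 802.0], bin_width=10.0) == 1.0
        x = [100.0] * 4 + [200.0] * 3 + [300.0] * 3
        assert triangular_index(x, bin_width=10.0) == pytest.approx(10 / 4)
        spread = [10.0 * k + 5.0 for k in range(8)]  # one per bin
        assert triangular_index(spread, bin_width=10.0) == 8.0


class TestOracleAgreement:
    def test_against_naive_loops_on_random_series(self, rng):
        """All time-domain parameters match naive-loop implementations to
        1e-9 relative tolerance across 300 random series."""
        for _ in range(300):
            length = int(rng.integers(5, 200))
            x = list(rng.normal(800, 60, length))
            assert mean_nn(x) == pytest.approx(sum(x) / len(x), rel=1e-9)
            assert sdnn(x) == pytest.approx(naive_sd(x), rel=1e-9)
            assert rmssd(x) == pytest.approx(naive_rmssd(x), rel=1e-9)
            assert nn50_family(x, 2)[0] == naive_nn50(x, 50.0)
            assert nn50_family(x, 2)[2] == naive_nn50(x, 100.0)
            sk, ku = naive_moments(x)
            assert skewness(x) == pytest.approx(sk, rel=1e-9, abs=1e-9)
            assert kurtosis(x) == pytest.approx(ku, rel=1e-9)
            assert triangular_index(x) == pytest.approx(
                naive_triangular_index(x, 1000.0 / 128.0), rel=1e-9
            )
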