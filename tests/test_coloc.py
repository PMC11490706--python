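"""Pearson correlation, Costes thresholds, Costes randomization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tjmorph import (
    UndefinedCorrelation,
    coloc_analysis,
    costes_randomization,
    costes_threshold_regression,
    pearson,
)


class TestPearson:
    def test_identical(self, rng):
        a = rng.random((32, 32))
        assert pearson(a, a) == pytest.approx(1.0)

    def test_inverted(self, rng):
        a = rng.random((32, 32))
        assert pearson(a, a.max() - a) == pytest.approx(-1.0)

    def test_independent_noise_bound(self):
        rng = np.random.default_rng(42)
        n = 1000
        a = rng.normal(100, 10, (n, n))
        b = rng.normal(100, 10, (n, n))
        assert abs(pearson(a, b)) < 3 / n

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelation):
            pearson(np.ones((4, 4)), np.arange(16.0).reshape(4, 4))

    @given(st.floats(0.1, 50), st.floats(-100, 100), st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_affine_invariance(self, scale, offset, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((16, 16))
        b = rng.random((16, 16))
        assert pearson(scale * a + offset, b) == pytest.approx(pearson(a, b))

    def test_masked_scope(self, rng):
        a = rng.random((8, 8))
        b = a.copy()
        b[:4] = rng.random((4, 8))  # destroy half
        mask = np.zeros((8, 8), bool)
        mask[4:] = True
        assert pearson(a, b, mask) == pytest.approx(1.0)


class TestCostesThresholds:
    def test_exact_linear_tls(self, rng):
        a = rng.gamma(2.0, 50.0, (64, 64))
        th = costes_threshold_regression(a, 2 * a)
        assert th.slope == pytest.approx(2.0, rel=1e-9)
        assert th.intercept == pytest.approx(0.0, abs=1e-9)

    def test_symmetry_identical_channels(self, rng):
        a = rng.gamma(2.0, 50.0, (64, 64))
        th = costes_threshold_regression(a, a)
        assert th.slope == pytest.approx(1.0)
        assert th.threshold_a == pytest.approx(th.threshold_b)

    @pytest.mark.parametrize("noise", [2.0, 10.0, 50.0])
    def test_matches_stepwise_reference(self, noise):
        """Stopping rule agrees with an explicit step-by-step reference."""
        rng = np.random.default_rng(int(noise))
        a = rng.gamma(2.0, 50.0, (64, 64))
        b = np.clip(0.8 * a + 5 + rng.normal(0, noise, a.shape), 0, None)
        th = costes_threshold_regression(a, b)

        av, bv = a.ravel(), b.ravel()
        sxx, syy = av.var(), bv.var()
        sxy = np.cov(av, bv, bias=True)[0, 1]
        slope = (syy - sxx + np.hypot(syy - sxx, 2 * sxy)) / (2 * sxy)
        intercept = bv.mean() - slope * av.mean()
        expected = None
        for ta in np.linspace(av.max(), av.min(), 256):
            tb = slope * ta + intercept
            sel = (av < ta) & (bv < tb)
            if sel.sum() < 2 or av[sel].std() == 0 or bv[sel].std() == 0:
                continue
            if np.corrcoef(av[sel], bv[sel])[0, 1] <= 0:
                expected = (ta, tb)
                break
        if expected is None:
            assert not th.converged
        else:
            assert th.converged
            assert th.threshold_a == pytest.approx(expected[0])
            assert th.threshold_b == pytest.approx(expected[1])


class TestCostesRandomization:
    def test_identical_channels_p_zero(self, rng):
        a = rng.gamma(2.0, 50.0, (64, 64))
        assert costes_randomization(a, a, 1, 10, seed=0) == 0.0

    def test_granularity_n1(self, rng):
        a = rng.random((32, 32))
        b = rng.random((32, 32))
        assert costes_randomization(a, b, 1, 1, seed=0) in (0.0, 1.0)

    def test_deterministic_given_seed(self, rng):
        a = rng.random((32, 32))
        b = rng.random((32, 32))
        p1 = costes_randomization(a, b, 2, 50, seed=7)
        p2 = costes_randomization(a, b, 2, 50, seed=7)
        assert p1 == p2

    def test_null_calibration(self):
        """Independent channels: p roughly uniform, mean in [0.3, 0.7]."""
        ps = []
        master = np.random.default_rng(5)
        for k in range(20):
            a = master.normal(100, 10, (96, 96))
            b = master.normal(100, 10, (96, 96))
            ps.append(costes_randomization(a, b, 1, 19, seed=k))
        assert 0.3 <= np.mean(ps) <= 0.7

    def test_block_too_large_raises(self, rng):
        a = rng.random((8, 8))
        with pytest.raises(ValueError):
            costes_randomization(a, a, 16, 2, seed=0)

    def test_p_grid(self, rng):
        a = rng.random((32, 32))
        b = rng.random((32, 32))
        n = 10
        p = costes_randomization(a, b, 1, n, seed=3)
        assert p in {k / n for k in range(n + 1)}


class TestColocAnalysis:
    def test_identical_headline(self, rng):
        a = rng.gamma(2.0, 50.0, (4, 64, 64))  # small z-stack
        res = coloc_analysis(a, a, n_randomizations=10, seed=1)
        assert res.pearson_r_above_thresholds == pytest.approx(1.0)
        assert res.pearson_r_global == pytest.approx(1.0)
        assert res.p_value == 0.0

    def test_json_roundtrip(self, tmp_path, rng):
        import json

        a = rng.gamma(2.0, 50.0, (32, 32))
        b = a + rng.normal(0, 10, (32, 32)) - a.min()
        b = np.clip(b, 0, None)
        res = coloc_analysis(a, b, n_randomizations=5, seed=2)
        out = tmp_path / "coloc.json"
        res.to_json(out)
        loaded = json.loads(out.read_text())
        assert loaded["n_randomizations"] == 5
        assert -1.0 <= loaded["pearson_r_global"] <= 1.0
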