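import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from dynregnet.datatypes import ExpressionMatrix, ReplicatedExpression
from dynregnet.preprocess import (
    average_replicates,
    fourier_smooth,
    loess_normalize,
    quantile_normalize,
    select_degs,
)


def matrix(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"g{i}" for i in range(values.shape[0])],
        np.arange(values.shape[1], dtype=float),
    )


class TestQuantileNormalize:
    def test_hand_example(self):
        out = quantile_normalize(matrix([[1, 3], [2, 4]]))
        np.testing.assert_allclose(out.values, [[2, 2], [3, 3]])

    def test_identical_columns_fixed_point(self):
        m = matrix(np.tile([[5.0], [1.0], [3.0]], (1, 4)))
        np.testing.assert_allclose(quantile_normalize(m).values, m.values)

    @settings(deadline=None, max_examples=25)
    @given(
        hnp.arrays(
            float,
            st.tuples(st.integers(2, 12), st.integers(2, 5)),
            elements=st.floats(-50, 50, allow_nan=False),
        )
    )
    def test_columns_share_multiset_and_idempotence(self, values):
        once = quantile_normalize(matrix(values))
        twice = quantile_normalize(once)
        for j in range(values.shape[1]):
            np.testing.assert_allclose(
                np.sort(once.values[:, j]), np.sort(once.values[:, 0])
            )
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_single_column_warns(self):
        with pytest.warns(UserWarning):
            out = quantile_normalize(matrix([[1.0], [2.0]]))
        np.testing.assert_array_equal(out.values, [[1.0], [2.0]])


class TestLoessNormalize:
    def test_equal_channels_give_zero_ratio(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(10, 1000, 200)
        assert np.all(np.abs(loess_normalize(x, x)) < 1e-9)

    def test_constant_log_ratio_removed(self):
        rng = np.random.default_rng(1)
        green = rng.uniform(10, 1000, 200)
        red = green * 4.0  # M identically 2
        assert np.all(np.abs(loess_normalize(red, green)) < 1e-6)

    def test_linear_intensity_trend_removed(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(4, 10, 400)
        m = 0.3 * a - 1.0
        green = 2 ** (a - m / 2)
        red = 2 ** (a + m / 2)
        corrected = loess_normalize(red, green, span=0.5)
        slope = np.polyfit(a, corrected, 1)[0]
        assert abs(slope) < 1e-3

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            loess_normalize([1.0, -2.0], [1.0, 1.0])


class TestReplicates:
    def test_mean_across_replicates(self):
        values = np.stack([[[1.0, 3.0]], [[2.0, 6.0]]], axis=0)  # 2 genes
        expr = ReplicatedExpression(values, ["a", "b"], [0.0])
        out = average_replicates(expr)
        np.testing.assert_allclose(out.values, [[2.0], [4.0]])

    def test_single_replicate_identity(self):
        values = np.arange(6, dtype=float).reshape(2, 3, 1)
        expr = ReplicatedExpression(values, ["a", "b"], [0.0, 1.0, 2.0])
        np.testing.assert_array_equal(
            average_replicates(expr).values, values[:, :, 0]
        )


def _null_expression(n_genes, n_tp=11, n_rep=3, seed=0):
    rng = np.random.default_rng(seed)
    return ReplicatedExpression(
        rng.normal(size=(n_genes, n_tp, n_rep)),
        [f"g{i}" for i in range(n_genes)],
        np.arange(n_tp, dtype=float),
    )


class TestSelectDegs:
    def test_constant_gene_not_selected(self):
        values = np.ones((1, 5, 3))
        expr = ReplicatedExpression(values, ["flat"], np.arange(5.0))
        assert select_degs(expr) == set()

    def test_planted_shift_detected(self):
        expr = _null_expression(1, seed=3)
        expr.values[0, 4:8, :] *= 0.1
        expr.values[0, 4:8, :] += 10 * 0.1  # +10 SD shift at 4 time points
        expr.values[0, :4, :] *= 0.1
        expr.values[0, 8:, :] *= 0.1
        assert select_degs(expr) == {"g0"}

    def test_monotone_in_alpha(self):
        expr = _null_expression(300, seed=5)
        for a1, a2 in [(0.01, 0.05), (0.05, 0.2)]:
            assert select_degs(expr, alpha=a1) <= select_degs(expr, alpha=a2)

    def test_requires_replicates(self):
        expr = ReplicatedExpression(np.zeros((2, 4, 1)), ["a", "b"], np.arange(4.0))
        with pytest.raises(ValueError):
            select_degs(expr)


class TestFourierSmooth:
    t = np.linspace(0, 14, 11)

    def test_constant_series_unchanged(self):
        out = fourier_smooth(np.full(11, 2.5), self.t, n_harmonics=3)
        np.testing.assert_allclose(out, 2.5, atol=1e-9)

    def test_basis_function_recovered(self):
        period = 2 * (self.t[-1] - self.t[0])
        y = np.cos(2 * np.pi * self.t / period)
        out = fourier_smooth(y, self.t, n_harmonics=2)
        np.testing.assert_allclose(out, y, atol=1e-8)

    def test_nested_fits_reduce_residual(self):
        rng = np.random.default_rng(7)
        bump = np.exp(-((self.t - 4) ** 2) / 4) + rng.normal(0, 0.2, 11)
        rss = {
            h: np.sum((bump - fourier_smooth(bump, self.t, n_harmonics=h)) ** 2)
            for h in (1, 3)
        }
        assert rss[3] < rss[1]

    def test_square_system_interpolates(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=11)
        out = fourier_smooth(y, self.t, n_harmonics=5)  # 2*5+1 == 11
        np.testing.assert_allclose(out, y, atol=1e-6)

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError, match="underdetermined"):
            fourier_smooth(np.zeros(5), np.arange(5.0), n_harmonics=3)
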