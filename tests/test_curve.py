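"""S-curve construction: sorting, differences, smoothing, cubic overlay."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enorms.curve import (
    build_curve,
    cubic_crossings,
    effective_window,
    first_differences,
    fit_cubic,
    rolling_mean,
)
from enorms.exceptions import ContractError, InsufficientDataError

finite_floats = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)


class TestFirstDifferences:
    @pytest.mark.parametrize(
        "values,expected",
        [([1, 2, 4, 7], [1, 2, 3]), ([0, 0, 0], [0, 0])],
    )
    def test_examples(self, values, expected):
        np.testing.assert_array_equal(first_differences(values), expected)

    def test_matches_pairwise_loop_oracle(self):
        rng = np.random.default_rng(1)
        v = np.sort(rng.normal(size=200))
        oracle = np.array([v[i + 1] - v[i] for i in range(len(v) - 1)])
        np.testing.assert_array_equal(first_differences(v), oracle)

    def test_decreasing_input_rejected(self):
        with pytest.raises(ContractError):
            first_differences([3, 1, 2])


class TestRollingMean:
    def test_partial_prefix_convention(self):
        np.testing.assert_allclose(
            rolling_mean([1, 2, 3, 4], 2), [1.0, 1.5, 2.5, 3.5]
        )

    def test_constant_series_unchanged(self):
        np.testing.assert_allclose(rolling_mean([7.0] * 25, 5), [7.0] * 25)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=1000)
        w = 7
        oracle = np.array(
            [np.mean(s[max(0, i - w + 1) : i + 1]) for i in range(len(s))]
        )
        np.testing.assert_allclose(rolling_mean(s, w), oracle, atol=1e-12)

    def test_bad_window_rejected(self):
        with pytest.raises(ContractError):
            rolling_mean([1, 2], 0)

    @settings(deadline=None)
    @given(
        s=st.lists(finite_floats, min_size=1, max_size=50),
        w=st.integers(1, 60),
    )
    def test_bounded_by_window_extrema(self, s, w):
        out = rolling_mean(s, w)
        arr = np.asarray(s)
        for i, m in enumerate(out):
            window = arr[max(0, i - w + 1) : i + 1]
            assert window.min() - 1e-9 <= m <= window.max() + 1e-9


class TestEffectiveWindow:
    @pytest.mark.parametrize(
        "n,fraction,expected",
        [(4722, 0.001, 5), (1000, 0.001, 3), (100000, 0.001, 100)],
    )
    def test_values(self, n, fraction, expected):
        assert effective_window(n, fraction) == expected

    def test_preconditions(self):
        with pytest.raises(InsufficientDataError):
            effective_window(5, 0.001)
        with pytest.raises(ContractError):
            effective_window(100, 1.5)


class TestFitCubic:
    def test_interpolates_generating_cubic(self):
        r = np.arange(1, 21)
        coef = fit_cubic(r, r.astype(float) ** 3)
        np.testing.assert_allclose(coef, (1, 0, 0, 0), atol=1e-8)

    def test_linear_data(self):
        r = np.arange(1, 31)
        coef = fit_cubic(r, 2.0 * r + 1)
        np.testing.assert_allclose(coef, (0, 0, 2, 1), atol=1e-8)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        r = np.arange(1, 301, dtype=float)
        v = 0.001 * r**3 - 0.1 * r**2 + r + rng.normal(0, 5, 300)
        vand = np.vander(r, 4)  # columns r^3, r^2, r, 1
        oracle = np.linalg.solve(vand.T @ vand, vand.T @ v)
        np.testing.assert_allclose(fit_cubic(r, v), oracle, rtol=1e-6)

    def test_underdetermined_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_cubic([1, 2, 3], [1, 2, 3])

    def test_rss_never_worse_than_best_line(self):
        rng = np.random.default_rng(4)
        r = np.arange(1, 101, dtype=float)
        v = np.sort(rng.lognormal(0, 1, 100))
        a3, a2, a1, a0 = fit_cubic(r, v)
        cubic_rss = np.sum((v - (((a3 * r + a2) * r + a1) * r + a0)) ** 2)
        line = np.polyfit(r, v, 1)
        line_rss = np.sum((v - np.polyval(line, r)) ** 2)
        assert cubic_rss <= line_rss + 1e-9


class TestBuildCurve:
    def test_small_example(self):
        c = build_curve([3, 1, 2] + [5] * 7)  # pad to reach n >= 10
        np.testing.assert_array_equal(c.values[:3], [1, 2, 3])
        np.testing.assert_array_equal(c.ranks, np.arange(1, 11))
        np.testing.assert_array_equal(c.diffs[:2], [1, 1])

    def test_constant_input(self):
        c = build_curve([5.0] * 20)
        assert np.all(c.diffs == 0) and np.all(c.smoothed_diffs == 0)

    def test_against_independent_sort_and_diff(self):
        rng = np.random.default_rng(5)
        raw = rng.normal(50, 10, 500)
        c = build_curve(raw)
        np.testing.assert_array_equal(c.values, np.sort(raw.copy()))
        np.testing.assert_array_equal(c.diffs, np.diff(np.sort(raw.copy())))

    def test_rejects_tiny_and_nonfinite_input(self):
        with pytest.raises(InsufficientDataError):
            build_curve([1.0] * 9)
        with pytest.raises(ContractError):
            build_curve([np.nan] + [1.0] * 19)

    @settings(deadline=None, max_examples=30)
    @given(vals=st.lists(finite_floats, min_size=10, max_size=200))
    def test_values_are_permutation_and_diffs_telescope(self, vals):
        c = build_curve(vals)
        assert sorted(vals) == pytest.approx(c.values.tolist())
        assert c.diffs.sum() == pytest.approx(
            c.values[-1] - c.values[0], abs=1e-6 * (1 + abs(c.values[-1]))
        )

    def test_json_round_trip(self, tmp_path):
        from enorms.curve import ENormsCurve

        c = build_curve(np.random.default_rng(6).normal(size=50), meta={"curve_id": "x"})
        path = tmp_path / "c.json"
        c.to_json(path)
        c2 = ENormsCurve.from_json(path)
        np.testing.assert_allclose(c2.values, c.values)
        np.testing.assert_allclose(c2.smoothed_diffs, c.smoothed_diffs)
        assert c2.meta == c.meta and c2.window == c.window


class TestCubicCrossings:
    def test_no_crossing_when_residuals_one_sided(self):
        c = build_curve(np.arange(20, dtype=float))
        shifted = c.__class__(
            values=c.values,
            ranks=c.ranks,
            diffs=c.diffs,
            smoothed_diffs=c.smoothed_diffs,
            window=c.window,
            cubic=(0.0, 0.0, 1.0, -5.0),  # line below all values
        )
        assert cubic_crossings(shifted).crossings == []

    def test_analytic_inflection(self):
        c = build_curve(np.arange(20, dtype=float))
        fake = c.__class__(
            values=c.values, ranks=c.ranks, diffs=c.diffs,
            smoothed_diffs=c.smoothed_diffs, window=c.window,
            cubic=(1.0, -6.0, 0.0, 0.0),
        )
        assert cubic_crossings(fake).inflection_rank == pytest.approx(2.0)

    def test_symmetric_s_curve_inflects_at_center(self):
        # logistic-quantile-shaped curve: symmetric, so the cubic's
        # inflection must sit at the center rank
        n = 999
        p = (np.arange(1, n + 1) - 0.5) / n
        v = np.log(p / (1 - p))
        c = build_curve(v)
        res = cubic_crossings(c)
        assert res.inflection_rank == pytest.approx((n + 1) / 2, abs=0.5)
        assert len(res.crossings) >= 1
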