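"""Plateau detection and the blinded-rater reconciliation protocol."""

import numpy as np
import pytest

from enorms.curve import build_curve
from enorms.exceptions import ContractError, NoPlateauError, ProtocolError
from enorms.plateau import (
    Plateau,
    RaterMarks,
    ThirdRaterNeeded,
    detect_plateau_auto,
    fit_tangent,
    plateau_values,
    read_ratings,
    reconcile,
    resolve_third,
    write_ratings,
)


def exhaustive_plateau_oracle(curve, rmse_tolerance, min_size):
    """Independent all-windows scan: per-window np.polyfit, longest feasible
    window, ties by rmse then by start."""
    n = curve.n
    rmse_max = rmse_tolerance * (curve.values[-1] - curve.values[0])
    med = np.median(curve.smoothed_diffs)
    cap = med + 1e-9 * max(abs(med), float(np.mean(curve.smoothed_diffs)))
    best = None
    for length in range(n, min_size - 1, -1):
        candidates = []
        for i in range(0, n - length + 1):
            j = i + length - 1
            r = np.arange(i, j + 1, dtype=float)
            v = curve.values[i : j + 1]
            slope, intercept = np.polyfit(r, v, 1)
            rmse = np.sqrt(np.mean((v - (slope * r + intercept)) ** 2))
            if rmse <= rmse_max and np.mean(curve.smoothed_diffs[i:j]) <= cap:
                candidates.append((rmse, i))
        if candidates:
            rmse, i = min(candidates)
            best = (i + 1, i + length, rmse)
            break
    return best


class TestDetectAuto:
    def test_exact_line_yields_whole_curve(self):
        c = build_curve(np.arange(1, 201, dtype=float))
        p = detect_plateau_auto(c, rmse_tolerance=0.001, min_size=10)
        assert (p.start_rank, p.end_rank) == (1, 200)
        assert p.provenance == "auto"

    def test_three_segment_recovery(self, three_segment):
        values, m1, m2 = three_segment(seed=100)
        p = detect_plateau_auto(build_curve(values), rmse_tolerance=0.005, min_size=100)
        assert p.size >= 780
        assert m1 - 10 <= p.start_rank and p.end_rank <= m2 + 10

    def test_zero_tolerance_off_a_line_fails(self):
        rng = np.random.default_rng(8)
        c = build_curve(np.sort(rng.standard_cauchy(300)))
        with pytest.raises(NoPlateauError):
            detect_plateau_auto(c, rmse_tolerance=0.0, min_size=30)

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = np.sort(
            np.concatenate(
                [rng.normal(50, 4, 250), rng.normal(35, 6, 80), rng.normal(60, 3, 40)]
            )
        )
        c = build_curve(values)
        tol, min_size = 0.01, 30
        oracle = exhaustive_plateau_oracle(c, tol, min_size)
        p = detect_plateau_auto(c, rmse_tolerance=tol, min_size=min_size)
        assert oracle is not None
        o_start, o_end, o_rmse = oracle
        # same window, or same length with tied rmse
        if (p.start_rank, p.end_rank) != (o_start, o_end):
            assert p.size == o_end - o_start + 1
            t = fit_tangent(c, p.start_rank, p.end_rank)
            assert t.rmse == pytest.approx(o_rmse, abs=1e-9)

    def test_tolerance_monotonicity(self):
        rng = np.random.default_rng(9)
        c = build_curve(np.sort(rng.normal(50, 4, 400)))
        sizes = []
        for tol in [0.002, 0.005, 0.01, 0.05, 0.2]:
            try:
                sizes.append(detect_plateau_auto(c, tol, min_size=30).size)
            except NoPlateauError:
                sizes.append(0)
        assert sizes == sorted(sizes)

    def test_stride_scan_agrees_with_exact_on_large_n(self, three_segment, monkeypatch):
        # same construction scaled past the exact-scan cutoff: the strided
        # detector must match the exhaustive scan on this smooth curve
        import enorms.plateau as plateau_mod

        values, m1, m2 = three_segment(seed=21, n=6000, left=600, right=600)
        c = build_curve(values)
        p_stride = detect_plateau_auto(c, rmse_tolerance=0.005, min_size=600)
        monkeypatch.setattr(plateau_mod, "EXACT_SCAN_MAX_N", 10_000)
        p_exact = detect_plateau_auto(c, rmse_tolerance=0.005, min_size=600)
        assert (p_stride.start_rank, p_stride.end_rank) == (
            p_exact.start_rank,
            p_exact.end_rank,
        )
        # and the window brackets the true linear middle segment
        assert p_stride.start_rank <= m1 + 10 and p_stride.end_rank >= m2 - 10

    def test_min_size_larger_than_n(self):
        c = build_curve(np.arange(50, dtype=float))
        with pytest.raises(NoPlateauError):
            detect_plateau_auto(c, 0.01, min_size=100)


class TestFitTangent:
    def test_exact_line(self):
        c = build_curve(0.01 * np.arange(1, 101) + 4)
        t = fit_tangent(c, 10, 60)
        assert t.slope == pytest.approx(0.01)
        assert t.intercept == pytest.approx(4.0)
        assert t.rmse == pytest.approx(0.0, abs=1e-12)

    def test_two_points(self):
        c = build_curve(np.concatenate([[0.0], np.arange(1, 10) / 4]))
        t = fit_tangent(c, 1, 3)
        # values at ranks 1..3 are 0, 0.25, 0.5 -> slope 0.25, rmse 0
        assert t.slope == pytest.approx(0.25)
        assert t.rmse == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(10)
        v = np.sort(rng.normal(0, 1, 300))
        c = build_curve(v)
        t = fit_tangent(c, 51, 250)
        r = np.arange(51, 251, dtype=float)
        y = v[50:250]
        rb, yb = r.mean(), y.mean()
        slope = np.sum((r - rb) * (y - yb)) / np.sum((r - rb) ** 2)
        intercept = yb - slope * rb
        assert t.slope == pytest.approx(slope, abs=1e-10)
        assert t.intercept == pytest.approx(intercept, abs=1e-10)

    def test_invalid_window(self):
        c = build_curve(np.arange(20, dtype=float))
        with pytest.raises(ContractError):
            fit_tangent(c, 5, 5)
        with pytest.raises(ContractError):
            fit_tangent(c, 0, 10)


class TestReconcile:
    def test_similar_marks_average(self):
        a = RaterMarks("r1", "c1", 100, 200)
        b = RaterMarks("r2", "c1", 102, 198)
        p = reconcile(a, b)
        assert isinstance(p, Plateau)
        assert (p.start_rank, p.end_rank) == (101, 199)
        assert p.provenance == "reconciled"

    def test_dissimilar_marks_escalate(self):
        a = RaterMarks("r1", "c1", 100, 200)
        b = RaterMarks("r2", "c1", 100, 150)
        out = reconcile(a, b)
        assert isinstance(out, ThirdRaterNeeded)
        assert out.relative_size_difference == pytest.approx(50 / 76)

    def test_identical_marks(self):
        a = RaterMarks("r1", "c1", 50, 150)
        b = RaterMarks("r2", "c1", 50, 150)
        p = reconcile(a, b)
        assert (p.start_rank, p.end_rank) == (50, 150)

    def test_symmetry(self):
        a = RaterMarks("r1", "c1", 100, 203)
        b = RaterMarks("r2", "c1", 97, 199)
        assert reconcile(a, b) == reconcile(b, a)

    def test_mismatched_curves_rejected(self):
        with pytest.raises(ProtocolError):
            reconcile(RaterMarks("r1", "c1", 1, 10), RaterMarks("r2", "c2", 1, 10))


class TestResolveThird:
    def test_choices(self):
        a = RaterMarks("r1", "c1", 10, 100)
        b = RaterMarks("r2", "c1", 30, 120)
        pa = resolve_third(a, b, "r1")
        assert (pa.start_rank, pa.end_rank, pa.provenance) == (10, 100, "third_rater")
        pb = resolve_third(a, b, "r2")
        assert (pb.start_rank, pb.end_rank) == (30, 120)
        with pytest.raises(ProtocolError):
            resolve_third(a, b, "r9")


class TestPlateauValues:
    def test_slice_semantics(self):
        c = build_curve(np.arange(1, 11, dtype=float))
        np.testing.assert_array_equal(
            plateau_values(c, Plateau(3, 6)), [3, 4, 5, 6]
        )
        np.testing.assert_array_equal(plateau_values(c, Plateau(1, 10)), c.values)

    def test_out_of_bounds(self):
        c = build_curve(np.arange(1, 11, dtype=float))
        with pytest.raises(ContractError):
            plateau_values(c, Plateau(5, 11))

    def test_extract_is_middle_segment_on_construction(self, three_segment):
        values, m1, m2 = three_segment(seed=200)
        c = build_curve(values)
        p = detect_plateau_auto(c, rmse_tolerance=0.005, min_size=100)
        extract = plateau_values(c, p)
        assert len(extract) == p.size
        middle = set(np.round(values[m1 - 1 : m2], 9))
        outside = [x for x in np.round(extract, 9) if x not in middle]
        assert len(outside) <= 10


def test_ratings_round_trip(tmp_path):
    marks = [RaterMarks("r1", "c1", 10, 90), RaterMarks("r2", "c1", 12, 95)]
    path = tmp_path / "marks.csv"
    write_ratings(marks, path)
    assert read_ratings(path) == marks
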