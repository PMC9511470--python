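import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ihhop import (
    DiagonalHistogram,
    default_eps_grid,
    det_curve,
    determinism,
    diagonal_histogram,
    epsilon_opt,
    recurrence_matrix,
    segment_eps_opt,
)
from tests.conftest import brute_det, brute_diagonal_histogram


class TestRecurrenceMatrix:
    def test_three_point_example(self):
        R = recurrence_matrix([0, 1, 0], 0.5)
        np.testing.assert_array_equal(
            R.entries.astype(int), [[1, 0, 1], [0, 1, 0], [1, 0, 1]]
        )

    def test_saturates_to_all_ones(self, rng):
        x = rng.normal(size=20)
        R = recurrence_matrix(x, np.ptp(x))
        assert R.entries.all()

    def test_zero_threshold_keeps_exact_ties(self):
        R = recurrence_matrix([0, 1, 0], 0.0)
        expected = np.eye(3, dtype=bool)
        expected[0, 2] = expected[2, 0] = True
        np.testing.assert_array_equal(R.entries, expected)

    def test_symmetric_with_unit_diagonal(self, rng):
        x = rng.normal(size=30)
        R = recurrence_matrix(x, 0.7).entries
        np.testing.assert_array_equal(R, R.T)
        assert R.diagonal().all()

    def test_nested_in_epsilon(self, rng):
        x = rng.normal(size=25)
        small = recurrence_matrix(x, 0.3).entries
        large = recurrence_matrix(x, 0.9).entries
        assert (large | ~small).all()  # small => large entrywise

    def test_translation_invariance(self, rng):
        x = rng.normal(size=25)
        a = recurrence_matrix(x, 0.5).entries
        b = recurrence_matrix(x + 42.0, 0.5).entries
        np.testing.assert_array_equal(a, b)


class TestDiagonalHistogram:
    def test_period_two_pattern(self):
        R = recurrence_matrix([0, 1, 0], 0.5)
        assert diagonal_histogram(R).counts == {1: 2}

    def test_all_ones_four_by_four(self):
        R = recurrence_matrix([0.0, 0.0, 0.0, 0.0], 1.0)
        assert diagonal_histogram(R).counts == {3: 2, 2: 2, 1: 2}

    def test_identity_matrix_empty(self):
        R = recurrence_matrix([0.0, 10.0, 20.0], 1.0)
        assert diagonal_histogram(R).counts == {}

    def test_point_total_matches_off_band_recurrences(self, rng):
        x = rng.normal(size=40)
        R = recurrence_matrix(x, 0.5)
        hist = diagonal_histogram(R, theiler=1)
        off = R.entries.sum() - np.trace(R.entries)
        assert hist.total_points() == off

    @pytest.mark.parametrize("theiler", [0, 1, 3])
    def test_matches_brute_force_enumeration(self, rng, theiler):
        for _ in range(25):
            x = rng.integers(0, 3, size=int(rng.integers(4, 15))).astype(float)
            eps = float(rng.choice([0.0, 0.5, 1.0, 1.5]))
            R = recurrence_matrix(x, eps)
            assert diagonal_histogram(R, theiler).counts == brute_diagonal_histogram(
                R.entries, theiler
            )


class TestDeterminism:
    def test_histogram_arithmetic(self):
        hist = DiagonalHistogram({3: 2, 2: 2, 1: 2})
        assert determinism(hist, 2) == pytest.approx(10 / 12)

    def test_lmin_one_is_unity(self, rng):
        hist = DiagonalHistogram({int(k): int(v) for k, v in zip(rng.integers(1, 9, 5), rng.integers(1, 9, 5))})
        assert determinism(hist, 1) == 1.0

    def test_no_line_reaches_lmin(self):
        assert determinism(DiagonalHistogram({1: 5}), 2) == 0.0

    def test_empty_histogram_sentinel(self):
        assert determinism(DiagonalHistogram({}), 2) == 0.0

    def test_non_increasing_in_lmin(self, rng):
        x = rng.normal(size=60)
        hist = diagonal_histogram(recurrence_matrix(x, 0.8))
        dets = [determinism(hist, lm) for lm in range(1, 8)]
        assert all(a >= b for a, b in zip(dets, dets[1:]))


class TestDetCurve:
    def test_constant_series_flat_and_saturated(self):
        # every pair recurs at any eps > 0, so the curve is flat; DET is
        # 1 up to the corner diagonals shorter than l_min (378/380 here)
        c = det_curve(np.full(20, 5.0), np.array([0.1, 0.2, 0.3]), l_min=2)
        assert np.ptp(c.det_values) == 0.0
        np.testing.assert_allclose(c.det_values, 378 / 380)
        assert epsilon_opt(c).degenerate

    def test_staircase_below_step_is_empty(self):
        c = det_curve([0.0, 10.0, 20.0, 30.0, 40.0], np.array([1.0, 2.0, 3.0]), l_min=2)
        assert c.empty_flags.all()
        np.testing.assert_allclose(c.det_values, 0.0)

    def test_square_wave_fully_deterministic(self):
        x = np.array([0.0, 1.0] * 4)
        for eps in (0.25, 0.5, 0.75):
            c = det_curve(x, np.array([eps - 0.01, eps, eps + 0.01]), l_min=2)
            np.testing.assert_allclose(c.det_values, 1.0)

    def test_matches_histogram_route(self, rng):
        """The sorted-profile fast path equals the literal composition
        recurrence_matrix -> diagonal_histogram -> determinism."""
        for _ in range(15):
            x = rng.normal(size=int(rng.integers(6, 50)))
            l_min = int(rng.integers(1, 6))
            grid = default_eps_grid(x, 15)
            fast = det_curve(x, grid, l_min=l_min)
            slow = [
                determinism(diagonal_histogram(recurrence_matrix(x, e)), l_min)
                for e in grid
            ]
            np.testing.assert_allclose(fast.det_values, slow)

    def test_scale_equivariance(self, rng):
        x = rng.normal(size=40)
        grid = default_eps_grid(x, 12)
        a = 3.7
        c1 = det_curve(x, grid, l_min=3)
        c2 = det_curve(a * x, a * grid, l_min=3)
        np.testing.assert_allclose(c1.det_values, c2.det_values)


class TestEpsilonOpt:
    def test_single_jump_argmax(self):
        grid = np.arange(0.1, 1.05, 0.1)
        det = np.where(grid >= 0.5, 1.0, 0.0)
        from ihhop.recurrence import DetCurve

        curve = DetCurve(grid, det, l_min=2, empty_flags=np.zeros(grid.size, bool))
        est = epsilon_opt(curve)
        # central differences spread the jump over 0.4 and 0.5; the tie
        # resolves to the smaller grid point
        assert est.value == pytest.approx(0.4)
        assert not est.degenerate

    def test_constant_series_flagged_degenerate(self):
        est = segment_eps_opt(np.full(50, 94.0), l_min=2)
        assert est.degenerate

    def test_sine_below_noise(self):
        wins = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            t = np.arange(300.0)
            sine = np.sin(2 * np.pi * t / 60.0)
            noise = r.normal(0.0, np.std(sine), 300)
            es = segment_eps_opt(sine, l_min=10).value
            en = segment_eps_opt(noise, l_min=10).value
            wins += es < en
        assert wins >= 19

    def test_translation_and_scale(self, rng):
        x = rng.normal(94.0, 1.0, 200)
        base = segment_eps_opt(x, l_min=5).value
        shifted = segment_eps_opt(x + 3.0, l_min=5).value
        scaled = segment_eps_opt(4.0 * x, l_min=5, grid_points=100).value
        assert shifted == pytest.approx(base, rel=1e-9)
        assert scaled == pytest.approx(4.0 * base, rel=1e-6)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    st.lists(st.integers(0, 2), min_size=4, max_size=12),
    st.sampled_from([0.0, 0.5, 1.0, 1.5]),
    st.integers(1, 4),
)
def test_det_always_matches_brute_force(values, eps, l_min):
    x = np.asarray(values, dtype=float)
    R = recurrence_matrix(x, eps)
    expected = brute_det(R.entries, l_min)
    got = determinism(diagonal_histogram(R), l_min)
    assert got == pytest.approx(expected)
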