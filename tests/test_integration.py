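"""EPSP input-output curves, mode classification and morphometry."""

import math

import numpy as np
import pytest

from twostage.integration import (
    DendriteMorphometry,
    IntegrationMode,
    IOCurve,
    classify_mode,
    compare_groups,
    dendrite_volume,
    expected_curve,
    input_resistance,
    read_io_curves,
    read_swc_branches,
    surrogate_dendrite_response,
    surrogate_io_curve,
    write_io_curves,
)


class TestClosedForms:
    @pytest.mark.parametrize(
        "diam, length, expected",
        [
            (1.0, 100.0, math.pi * 25.0),
            (2.0, 100.0, math.pi * 100.0),  # quadratic in diameter
            (0.8, 150.0, math.pi * 0.16 * 150.0),
        ],
    )
    def test_cylinder_volume(self, diam, length, expected):
        assert dendrite_volume(diam, length) == pytest.approx(expected)

    def test_volume_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            dendrite_volume(0.0, 10.0)
        with pytest.raises(ValueError):
            dendrite_volume(1.0, -5.0)

    def test_volume_monotone_in_both_arguments(self):
        base = dendrite_volume(0.7, 80.0)
        assert dendrite_volume(0.8, 80.0) > base
        assert dendrite_volume(0.7, 90.0) > base

    @pytest.mark.parametrize(
        "dv, i, r", [(-10.0, -100.0, 100.0), (-5.0, -100.0, 50.0), (-20.0, -100.0, 200.0)]
    )
    def test_input_resistance_unit_arithmetic(self, dv, i, r):
        # -100 pA injection producing a -10 mV deflection is 100 MOhm
        assert input_resistance(dv, i) == pytest.approx(r)

    def test_input_resistance_zero_current(self):
        with pytest.raises(ValueError):
            input_resistance(-10.0, 0.0)


class TestExpectedCurve:
    def test_is_count_times_unitary(self):
        amps = expected_curve(0.5, 20)
        assert amps[0] == pytest.approx(0.5)
        assert amps[3] == pytest.approx(2.0)
        assert len(amps) == 20

    def test_last_value(self):
        assert expected_curve(0.3, 20)[-1] == pytest.approx(6.0)

    def test_rejects_nonpositive_unitary(self):
        with pytest.raises(ValueError):
            expected_curve(0.0)


def _oracle_classify(expected, actual, tol):
    """Exhaustive pointwise-comparison oracle for the mode labels."""
    above = [a > e + tol for a, e in zip(actual, expected)]
    below = [a < e - tol for a, e in zip(actual, expected)]
    if any(above):
        return IntegrationMode.SUPRALINEAR
    if any(below):
        return IntegrationMode.SUBLINEAR
    return IntegrationMode.LINEAR


class TestClassifyMode:
    def _curve(self, actual, unitary=0.5):
        n = np.arange(1, len(actual) + 1)
        return IOCurve(n, unitary, unitary * n, np.asarray(actual, float))

    def test_exact_linear_summation_is_linear(self):
        c = surrogate_io_curve(IntegrationMode.LINEAR)
        assert classify_mode(c) is IntegrationMode.LINEAR

    def test_uniform_shortfall_is_sublinear(self):
        exp = expected_curve(0.5, 10)
        assert classify_mode(self._curve(0.9 * exp)) is IntegrationMode.SUBLINEAR

    def test_short_supralinear_range_suffices(self):
        # sigmoid-shaped curve crossing above the diagonal only briefly
        exp = expected_curve(0.5, 20)
        actual = 0.8 * exp.copy()
        actual[7:10] = exp[7:10] + 1.0
        assert classify_mode(self._curve(actual)) is IntegrationMode.SUPRALINEAR

    def test_agrees_with_pointwise_oracle_on_random_curves(self):
        rng = np.random.default_rng(7)
        tol = 0.01
        for _ in range(1000):
            n_max = int(rng.integers(3, 20))
            unitary = float(rng.uniform(0.1, 1.0))
            exp = expected_curve(unitary, n_max)
            actual = exp * rng.uniform(0.5, 1.5, size=n_max)
            curve = IOCurve(np.arange(1, n_max + 1), unitary, exp, actual)
            assert classify_mode(curve, tol) is _oracle_classify(exp, actual, tol)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            IOCurve(np.arange(1, 4), 0.5, np.ones(3), np.ones(2))


class TestSurrogateCurves:
    def test_sublinear_normalized_at_one_synapse(self):
        out = surrogate_dendrite_response(IntegrationMode.SUBLINEAR, 1, unitary=0.4)
        assert out == pytest.approx(0.4)

    @pytest.mark.parametrize("mode", [IntegrationMode.SUPRALINEAR, IntegrationMode.SUBLINEAR])
    def test_round_trip_classification(self, mode):
        # curves generated under a mode label classify back to that label
        for unitary in (0.3, 0.5, 0.8):
            curve = surrogate_io_curve(mode, unitary=unitary)
            assert classify_mode(curve) is mode

    def test_round_trip_over_random_parameter_draws(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            unitary = float(rng.uniform(0.2, 0.9))
            thr = float(rng.uniform(5, 12))
            c = surrogate_io_curve(
                IntegrationMode.SUPRALINEAR, unitary=unitary, threshold=thr
            )
            assert classify_mode(c) is IntegrationMode.SUPRALINEAR
            c = surrogate_io_curve(IntegrationMode.SUBLINEAR, unitary=unitary)
            assert classify_mode(c) is IntegrationMode.SUBLINEAR


class TestWelch:
    def test_identical_groups(self):
        stat, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_textbook_welch_statistic(self):
        # independent hand computation of the Welch statistic
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([11.1, 12.0, 12.9, 14.2])
        stat, p = compare_groups(a, b)
        se = math.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        assert stat == pytest.approx((a.mean() - b.mean()) / se)
        assert p < 0.001

    def test_swap_negates_statistic(self):
        a, b = [1.0, 2.0, 4.0], [5.0, 6.5, 9.0]
        s1, p1 = compare_groups(a, b)
        s2, p2 = compare_groups(b, a)
        assert s1 == pytest.approx(-s2)
        assert p1 == pytest.approx(p2)

    def test_needs_two_observations(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])


class TestFileFormats:
    def test_io_curve_csv_round_trip(self, tmp_path):
        curves = [
            surrogate_io_curve(IntegrationMode.SUBLINEAR, dendrite_id=0),
            surrogate_io_curve(IntegrationMode.SUPRALINEAR, dendrite_id=1),
        ]
        path = tmp_path / "curves.csv"
        write_io_curves(curves, path)
        back = read_io_curves(path)
        assert len(back) == 2
        for orig, rt in zip(curves, back):
            np.testing.assert_allclose(rt.actual, orig.actual)
            assert classify_mode(rt) is classify_mode(orig)

    def test_swc_branch_morphometry(self, tmp_path):
        # soma root with two dendritic branches: a straight 3-node branch of
        # radius 0.5 (diam 1.0) and a single 20 um segment of radius 0.25
        swc = "\n".join(
            [
                "# synthetic two-branch tree",
                "1 1 0 0 0 5.0 -1",
                "2 3 10 0 0 0.5 1",
                "3 3 20 0 0 0.5 2",
                "4 3 0 15 0 0.25 1",
            ]
        )
        path = tmp_path / "cell.swc"
        path.write_text(swc)
        branches = read_swc_branches(path)
        assert len(branches) == 2
        by_len = sorted(branches, key=lambda b: b.length)
        assert by_len[1].length == pytest.approx(20.0)
        assert by_len[1].diam == pytest.approx(1.0)
        assert by_len[0].length == pytest.approx(15.0)
        assert by_len[0].diam == pytest.approx(0.5)
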