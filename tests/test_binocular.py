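"""Binocular integration: the quadratic-summation equations and OU-VFI.

Expected values are frozen from a scalar-arithmetic oracle (math module
only) written independently of the implementation.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vfdrive.binocular import (
    MAX_SUMMATION_GAIN_DB,
    IntegrationError,
    MonocularField,
    binocular_threshold,
    binocular_total_deviation,
    expected_binocular_threshold,
    integrate_fields,
    sensitivity,
    weighted_vfi,
)
from vfdrive.geometry import Eye, Pattern, build_pattern

from conftest import make_flat_field


def oracle_btv(l, r):
    """Independent scalar re-implementation of the printed summation."""
    return 10 * math.log10(math.sqrt((10 ** (l / 10)) ** 2 + (10 ** (r / 10)) ** 2))


def oracle_sens(btd, ebtv):
    if btd >= 0:
        return 100.0
    return max(0.0, 100 - 100 * abs(btd) / ebtv)


class TestBinocularThreshold:
    @pytest.mark.parametrize(
        "l, r, expected",
        [
            (30.0, 30.0, 31.50515),  # 30 + 10·log10(√2)
            (30.0, 0.0, 30.0000022),  # 10·log10(√(10⁶+1))
            (20.0, 30.0, 30.02161),  # a=100, b=1000
        ],
    )
    def test_worked_examples(self, l, r, expected):
        assert binocular_threshold(l, r) == pytest.approx(expected, abs=1e-4)

    def test_rejects_non_finite(self):
        with pytest.raises(IntegrationError):
            binocular_threshold(float("nan"), 30.0)
        with pytest.raises(IntegrationError):
            binocular_threshold(30.0, float("inf"))

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        l=st.floats(min_value=-30, max_value=45),
        r=st.floats(min_value=-30, max_value=45),
    )
    def test_summation_bounds(self, l, r):
        """max(l,r) ≤ bTV ≤ max(l,r) + 10·log10(√2) for all finite inputs."""
        out = binocular_threshold(l, r)
        assert out >= max(l, r) - 1e-9
        assert out <= max(l, r) + MAX_SUMMATION_GAIN_DB + 1e-9

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        l=st.floats(min_value=-30, max_value=45),
        r=st.floats(min_value=-30, max_value=45),
    )
    def test_matches_scalar_oracle(self, l, r):
        assert binocular_threshold(l, r) == pytest.approx(oracle_btv(l, r), abs=1e-9)


class TestExpectedThreshold:
    @pytest.mark.parametrize(
        "ltv, ltd, rtv, rtd",
        [(28, -2, 30, 0), (30, 0, 30, 0), (25, -5, 20, -10)],
    )
    def test_reduces_to_summation_of_expected_tvs(self, ltv, ltd, rtv, rtd):
        # all three cases have expected TV 30 in both eyes
        assert expected_binocular_threshold(ltv, ltd, rtv, rtd) == pytest.approx(31.50515, abs=1e-4)

    def test_equals_threshold_of_differences(self):
        assert expected_binocular_threshold(22, -4, 31, 2) == pytest.approx(
            binocular_threshold(26, 29), abs=1e-12
        )


class TestBinocularTotalDeviation:
    def test_worked_example(self):
        # oracle: 10log10(√(10^5.6 + 10^6)) − 31.50515
        expected = oracle_btv(28, 30) - oracle_btv(30, 30)
        got = binocular_total_deviation(28, -2, 30, 0)
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(-0.77745, abs=1e-4)

    def test_all_normal_location_is_zero(self):
        assert binocular_total_deviation(30, 0, 30, 0) == pytest.approx(0.0, abs=1e-12)

    def test_single_eye_falls_back_to_monocular_td(self):
        assert binocular_total_deviation(l_tv=27, l_td=-3.5) == pytest.approx(-3.5)
        assert binocular_total_deviation(r_tv=27, r_td=-1.0) == pytest.approx(-1.0)

    def test_no_eyes_rejected(self):
        with pytest.raises(IntegrationError):
            binocular_total_deviation()


class TestSensitivity:
    def test_nonnegative_deviation_is_fully_sensitive(self):
        assert sensitivity(0.0, 31.5) == 100.0
        assert sensitivity(2.3, 31.5) == 100.0

    def test_worked_example(self):
        btd = oracle_btv(28, 30) - oracle_btv(30, 30)
        expected = 100 - 100 * abs(btd) / oracle_btv(30, 30)
        assert sensitivity(btd, oracle_btv(30, 30)) == pytest.approx(expected, abs=1e-9)
        assert sensitivity(btd, oracle_btv(30, 30)) == pytest.approx(97.532, abs=1e-3)

    def test_deep_defect_clamped_to_zero(self):
        assert sensitivity(-40.0, 31.50515) == 0.0

    def test_continuous_at_zero_deviation(self):
        eps = 1e-9
        assert sensitivity(-eps, 31.5) == pytest.approx(100.0, abs=1e-6)

    def test_degenerate_normative_value_rejected(self):
        with pytest.raises(IntegrationError):
            sensitivity(-1.0, 0.0)
        with pytest.raises(IntegrationError):
            sensitivity(-1.0, -5.0)


class TestWeightedVfi:
    def test_endpoints(self):
        w = np.array([3.29, 1.28, 0.79, 0.57, 0.45])
        assert weighted_vfi(np.full(5, 100.0), w) == pytest.approx(100.0)
        assert weighted_vfi(np.zeros(5), w) == pytest.approx(0.0)

    def test_toy_example(self):
        # 329 / 374 by hand
        assert weighted_vfi([100.0, 0.0], [3.29, 0.45]) == pytest.approx(87.96791, abs=1e-4)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(IntegrationError):
            weighted_vfi([100.0, 50.0], [0.0, 0.0])


class TestIntegrateFields:
    def test_fully_normal_pair_scores_100(self, normal_pair):
        left, right = normal_pair
        field = integrate_fields(left, right)
        assert field.vfi == pytest.approx(100.0, abs=1e-12)
        assert np.allclose(field.btd, 0.0, atol=1e-12)

    def test_btd_identity_everywhere(self, normal_pair, grid_24_os, grid_24_od):
        rng = np.random.default_rng(7)

        def random_field(eye, grid):
            # draw the normative surface and the deviation, so expected TV
            # (tv − td) stays physically positive
            etv = rng.uniform(20, 35, grid.n_locations)
            td = rng.uniform(-20, 2, grid.n_locations)
            return MonocularField(eye=eye, grid=grid, tv=etv + td, td=td)

        left = random_field(Eye.OS, grid_24_os)
        right = random_field(Eye.OD, grid_24_od)
        field = integrate_fields(left, right)
        assert np.allclose(field.btd, field.btv - field.expected_btv, atol=1e-9)
        assert np.all((field.s >= 0) & (field.s <= 100))
        assert 0 <= field.vfi <= 100

    def test_uniform_defect_one_eye(self, grid_24_os, grid_24_od):
        """One eye normal, fellow eye −10 dB everywhere: per-location values
        match the scalar oracle at every binocular location."""
        left = make_flat_field(grid_24_os, tv=30.0, td=0.0)
        right = make_flat_field(grid_24_od, tv=20.0, td=-10.0)
        field = integrate_fields(left, right)
        expected_btv = oracle_btv(30, 20)
        expected_s = oracle_sens(expected_btv - oracle_btv(30, 30), oracle_btv(30, 30))
        both = {}
        for x, y, btv, s in zip(field.x, field.y, field.btv, field.s):
            both[(x, y)] = (btv, s)
        left_locs = {(p.x, p.y) for p in grid_24_os.points if not p.is_blind_spot}
        right_locs = {(p.x, p.y) for p in grid_24_od.points if not p.is_blind_spot}
        for loc in left_locs & right_locs:
            assert both[loc][0] == pytest.approx(expected_btv, abs=1e-9)
            assert both[loc][1] == pytest.approx(expected_s, abs=1e-9)
        # fellow-eye blind-spot locations fall back to the seeing eye
        for loc in left_locs - right_locs:
            assert both[loc][0] == pytest.approx(30.0, abs=1e-12)
        assert field.vfi < 100.0

    def test_eye_swap_symmetry(self, grid_24_os, grid_24_od):
        rng = np.random.default_rng(11)
        left = MonocularField(
            eye=Eye.OS, grid=grid_24_os,
            tv=rng.uniform(5, 35, 54), td=rng.uniform(-15, 2, 54),
        )
        right = MonocularField(
            eye=Eye.OD, grid=grid_24_od,
            tv=rng.uniform(5, 35, 54), td=rng.uniform(-15, 2, 54),
        )
        a = integrate_fields(left, right)
        b = integrate_fields(right, left)
        assert a.vfi == pytest.approx(b.vfi, abs=1e-12)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)
        assert np.allclose(a.s, b.s, atol=1e-12)

    def test_same_eye_twice_rejected(self, grid_24_od):
        f = make_flat_field(grid_24_od)
        with pytest.raises(IntegrationError):
            integrate_fields(f, f)

    def test_monotone_in_single_location_worsening(self, grid_24_os, grid_24_od):
        """Deepening one location's deviation never increases OU-VFI."""
        left = make_flat_field(grid_24_os, tv=30.0, td=0.0)
        base_right_tv = np.full(54, 30.0)
        prev = None
        idx = 20
        for drop in (0.0, 2.0, 5.0, 10.0, 20.0, 30.0):
            tv = base_right_tv.copy()
            tv[idx] -= drop
            right = MonocularField(
                eye=Eye.OD, grid=grid_24_od, tv=tv, td=tv - 30.0
            )
            vfi = integrate_fields(left, right).vfi
            if prev is not None:
                assert vfi <= prev + 1e-12
            prev = vfi

    def test_mixed_patterns_integrate_on_24_2_lattice(self, grid_24_os):
        g30 = build_pattern(Pattern.P30_2, Eye.OD)
        left = make_flat_field(grid_24_os)
        right = make_flat_field(g30)
        field = integrate_fields(left, right)
        locs = {(x, y) for x, y in zip(field.x, field.y)}
        lattice = {(p.x, p.y) for p in grid_24_os.points}
        assert locs <= lattice
        assert field.vfi == pytest.approx(100.0)

    def test_oracle_equivalence_random_fields(self, grid_24_os, grid_24_od):
        """integrate_fields matches a naive per-location scalar loop."""
        rng = np.random.default_rng(2024)
        for _ in range(20):
            ltd = rng.uniform(-25, 3, 54)
            ltv = rng.uniform(20, 35, 54) + ltd
            rtd = rng.uniform(-25, 3, 54)
            rtv = rng.uniform(20, 35, 54) + rtd
            left = MonocularField(eye=Eye.OS, grid=grid_24_os, tv=ltv, td=ltd)
            right = MonocularField(eye=Eye.OD, grid=grid_24_od, tv=rtv, td=rtd)
            field = integrate_fields(left, right)
            # naive oracle over the merged locations
            lmap = {
                (p.x, p.y): (ltv[i], ltd[i])
                for i, p in enumerate(grid_24_os.points)
                if not p.is_blind_spot
            }
            rmap = {
                (p.x, p.y): (rtv[i], rtd[i])
                for i, p in enumerate(grid_24_od.points)
                if not p.is_blind_spot
            }
            num = den = 0.0
            from vfdrive.geometry import RING_WEIGHTS, ring_of

            for loc in set(lmap) | set(rmap):
                if loc in lmap and loc in rmap:
                    (a, atd), (b, btd_) = lmap[loc], rmap[loc]
                    btv = oracle_btv(a, b)
                    ebtv = oracle_btv(a - atd, b - btd_)
                else:
                    tv, td = lmap.get(loc, rmap.get(loc))
                    btv, ebtv = tv, tv - td
                s = oracle_sens(btv - ebtv, ebtv)
                w = RING_WEIGHTS[ring_of(math.hypot(*loc)) - 1]
                num += s * w
                den += 100.0 * w
            assert field.vfi == pytest.approx(100 * num / den, abs=1e-6)
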