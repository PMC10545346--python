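"""Nematic circular statistics, wave-speed and growth fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from germorder.kinetics import (DivisionEvent, detect_reorientation, doubling_time,
                                fit_von_mises, fit_wave_speed, nematic_dispersion,
                                nematic_mean)


class TestNematicMean:
    def test_constant_angles(self):
        assert nematic_mean([0.3] * 7) == pytest.approx(0.3)

    def test_symmetric_pair_averages_to_zero(self):
        a = np.deg2rad([40.0, -40.0])
        assert nematic_mean(a) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_pair_undefined(self):
        assert np.isnan(nematic_mean([0.0, np.pi / 2]))

    @given(st.lists(st.floats(-np.pi / 2, np.pi / 2 - 1e-6), min_size=2, max_size=30),
           st.integers(0, 29))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_invariant_under_pi_flips_of_any_subset(self, angles, flip_at):
        angles = np.asarray(angles)
        m0 = nematic_mean(angles)
        flipped = angles.copy()
        flipped[flip_at % len(angles)] += np.pi
        m1 = nematic_mean(flipped)
        if np.isnan(m0):
            assert np.isnan(m1)
        else:
            assert m1 == pytest.approx(m0, abs=1e-9)

    def test_rotation_shifts_mean_and_preserves_dispersion(self):
        rng = np.random.default_rng(3)
        angles = rng.normal(0.2, 0.1, size=50)
        off = 0.4
        m0, m1 = nematic_mean(angles), nematic_mean(angles + off)
        assert (m1 - m0 + np.pi / 2) % np.pi - np.pi / 2 == pytest.approx(off, abs=1e-9)
        assert nematic_dispersion(angles + off) == pytest.approx(
            nematic_dispersion(angles), abs=1e-12)


class TestNematicDispersion:
    def test_identical_angles_give_zero(self):
        assert nematic_dispersion([0.7] * 100) == pytest.approx(0.0, abs=1e-7)

    def test_orthogonal_pair_gives_sqrt_two(self):
        assert nematic_dispersion([0.0, np.pi / 2]) == pytest.approx(np.sqrt(2))

    def test_uniform_angles_approach_sqrt_two(self):
        rng = np.random.default_rng(12)
        a = rng.uniform(-np.pi / 2, np.pi / 2, size=100_000)
        assert nematic_dispersion(a) == pytest.approx(np.sqrt(2), abs=0.01)

    def test_unrooted_variant_range(self):
        assert nematic_dispersion([0.0, np.pi / 2], squared=True) == pytest.approx(2.0)


class TestVonMisesFit:
    def test_concentration_recovered(self):
        rng = np.random.default_rng(21)
        doubled = rng.vonmises(0.0, 5.0, size=10_000)
        angles = doubled / 2
        loc, k, sat = fit_von_mises(angles)
        assert 4.5 <= k <= 5.5
        assert not sat
        assert abs(loc) < 0.05

    def test_uniform_gives_near_zero_concentration(self):
        rng = np.random.default_rng(22)
        angles = rng.uniform(-np.pi / 2, np.pi / 2, size=10_000)
        _, k, _ = fit_von_mises(angles)
        assert k < 0.1

    def test_degenerate_sample_saturates(self):
        from germorder.kinetics import KAPPA_MAX
        loc, k, sat = fit_von_mises([0.4] * 10)
        assert sat and k == KAPPA_MAX
        assert loc == pytest.approx(0.4)

    def test_too_few_angles_rejected(self):
        with pytest.raises(ValueError):
            fit_von_mises([0.1, 0.2])


def _events(ts, xs, ys, wave="wave1", ps=0):
    out = []
    for i, (t, x, y) in enumerate(zip(ts, xs, ys)):
        out.append(DivisionEvent(time=t, x=x, y=y, theta=0.0, parent_id=i,
                                 daughter_ids=(2 * i + 100, 2 * i + 101),
                                 wave=wave, parasegment=ps))
    return out


class TestWaveSpeed:
    def test_noiseless_line_exact(self):
        t = np.linspace(0, 4, 9)
        evs = _events(t, 7.5 * t, np.zeros_like(t))
        fit = fit_wave_speed(evs, "AP")
        assert fit.value == pytest.approx(7.5)
        assert fit.stderr == pytest.approx(0.0, abs=1e-9)

    def test_two_events_rejected(self):
        evs = _events([0.0, 1.0], [0.0, 7.5], [0.0, 0.0])
        with pytest.raises(ValueError):
            fit_wave_speed(evs, "AP")

    def test_zero_time_variance_rejected(self):
        evs = _events([1.0] * 5, np.arange(5.0), np.zeros(5))
        with pytest.raises(ValueError):
            fit_wave_speed(evs, "AP")

    def test_dv_fit_pools_sides_with_wave_relative_time(self):
        # two parasegments starting at different absolute times
        v = 19.2
        ys = np.array([0.0, 10, -10, 20, -20, 30])
        evs = []
        for ps, t0 in ((0, 5.0), (1, 9.0)):
            evs += _events(t0 + np.abs(ys) / v, np.full_like(ys, ps * 10.0), ys,
                           ps=ps)
        fit = fit_wave_speed(evs, "DV")
        assert fit.value == pytest.approx(v, rel=1e-9)

    def test_unbiased_on_jittered_waves(self):
        v_true = 7.5
        hits = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            t = np.sort(rng.uniform(0, 6, size=40))
            tj = t + rng.normal(scale=0.25, size=t.size)
            evs = _events(tj, v_true * t, np.zeros_like(t))
            fit = fit_wave_speed(evs, "AP")
            if abs(fit.value - v_true) <= 2 * fit.stderr:
                hits += 1
        assert hits >= 0.9 * 60


class TestDoublingTime:
    def test_noiseless_exponential_exact(self):
        t = np.linspace(0, 25, 6)
        counts = 100 * 2 ** (t / 10.0)
        fit = doubling_time(t, counts)
        assert fit.value == pytest.approx(10.0)
        assert fit.stderr == pytest.approx(0.0, abs=1e-6)

    def test_thinned_counts_recover_tau(self):
        tau = 10.0
        ok = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            t = np.linspace(0, 20, 8)
            n = rng.binomial((400 * 2 ** (t / tau)).astype(int), 0.9)
            fit = doubling_time(t, n)
            if abs(fit.value - tau) / tau < 0.1:
                ok += 1
        assert ok >= 38

    def test_constant_counts_reported_infinite(self):
        fit = doubling_time([0, 1, 2, 3], [50, 50, 50, 50])
        assert np.isinf(fit.value)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            doubling_time([0, 1, 2], [10, 0, 40])


class TestReorientation:
    @staticmethod
    def _series(final, start=None, window=10 / 60):
        ts = np.linspace(1.0 - window, 1.0, 11)
        if start is None:
            ang = np.full_like(ts, final)
        else:
            ang = np.linspace(start, final, ts.size)
        return ts, ang, final

    def test_constant_axis_not_flagged(self):
        flags, frac, n = detect_reorientation({0: self._series(0.2)})
        assert flags[0] is False and frac == 0.0 and n == 1

    def test_ninety_degree_swing_flagged(self):
        flags, frac, _ = detect_reorientation({0: self._series(0.0, start=np.pi / 2)})
        assert flags[0] is True and frac == 1.0

    def test_short_series_excluded_from_denominator(self):
        ts = np.array([0.99, 1.0])     # covers only the final minute
        series = {0: (ts, np.array([0.0, 0.0]), 0.0),
                  1: self._series(0.1)}
        flags, frac, n = detect_reorientation(series)
        assert n == 1 and 0 not in flags

    def test_planted_fraction_recovered(self):
        from germorder.synthetic import SyntheticGermbandParams, synth_germband
        params = SyntheticGermbandParams(n_rows=8, cells_per_row=8,
                                         reorient_fraction=0.074, seed=9)
        rz = synth_germband(params)
        _, frac, n = detect_reorientation(rz.reorientation_series)
        p = 0.074
        ci = 1.96 * np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) <= ci + 1e-9
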