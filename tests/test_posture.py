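"""COP computation, foot boundary, time-to-boundary and sway metrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import balancekit as bk
from balancekit import posture, signalio


def _record(fx=0.0, fy=0.0, fz=-700.0, mx=0.0, my=0.0, mz=0.0, n=10):
    data = np.tile(np.array([fx, fy, fz, mx, my, mz])[:, None], (1, n))
    return signalio.TimeSeriesBlock(data, 1000.0, list(signalio.FORCE_CHANNELS))


class TestComputeCop:
    def test_pure_vertical_load_cop_at_origin(self):
        cop = posture.compute_cop(_record())
        assert np.abs(cop).max() == 0.0

    def test_pitch_moment_shifts_cop(self):
        # applied load F = (0,0,-700) at x = +0.05 gives My = r x F = +35:
        # the formula COP_x = -My/Fz must invert that moment balance
        cop = posture.compute_cop(_record(my=35.0))
        assert np.allclose(cop[:, 0], 0.05)
        assert np.allclose(cop[:, 1], 0.0)

    def test_plate_offset_applied(self):
        cop = posture.compute_cop(_record(my=35.0), plate_offset=(0.01, 0.02, 0.0))
        assert np.allclose(cop[:, 0], 0.06)
        assert np.allclose(cop[:, 1], 0.02)

    def test_unloaded_samples_rejected_with_indices(self):
        rec = _record()
        rec.data[2, 3] = -5.0
        with pytest.raises(posture.UnloadedSampleError, match="3"):
            posture.compute_cop(rec)


class TestFootBoundary:
    def _foot_markers(self, rot_deg=0.0, jitter=0.0, seed=0, n=50):
        tmpl = bk.default_template()
        pts = {m: np.asarray(tmpl.segments["foot"][m]) for m in
               ("MT1", "MT5", "TOE", "HEEL")}
        rng = np.random.default_rng(seed)
        th = np.radians(rot_deg)
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        labels = list(pts)
        pos = np.stack([np.tile(R @ pts[m], (n, 1)) for m in labels], axis=1)
        if jitter:
            pos = pos + rng.normal(0, jitter, pos.shape)
        return bk.MarkerTrajectorySet(labels, pos, 100.0)

    def test_template_foot_ml_extent_is_10cm(self):
        fb = bk.foot_boundary(self._foot_markers())
        assert np.isclose(fb.ml_width, 0.10, atol=1e-9)
        assert np.isclose(fb.ap_extent[1] - fb.ap_extent[0], 0.25, atol=1e-9)

    def test_extents_invariant_to_foot_rotation(self):
        a = bk.foot_boundary(self._foot_markers())
        b = bk.foot_boundary(self._foot_markers(rot_deg=30.0))
        assert np.isclose(a.ml_width, b.ml_width, atol=1e-9)
        assert np.allclose(a.ap_extent, b.ap_extent, atol=1e-9)

    def test_extents_robust_to_1mm_jitter(self):
        a = bk.foot_boundary(self._foot_markers())
        b = bk.foot_boundary(self._foot_markers(jitter=0.001, seed=3))
        assert abs(a.ml_width - b.ml_width) < 0.002

    def test_coincident_heel_toe_rejected(self):
        mk = self._foot_markers()
        mk.positions[:, mk.labels.index("TOE")] = \
            mk.positions[:, mk.labels.index("HEEL")]
        with pytest.raises(posture.DegenerateAxisError):
            bk.foot_boundary(mk)

    def test_rectangle_contains_marker_projections(self):
        fb = bk.foot_boundary(self._foot_markers(rot_deg=17.0))
        mk = self._foot_markers(rot_deg=17.0)
        for m in ("MT1", "MT5", "TOE", "HEEL"):
            mlap = fb.to_foot_frame(mk.get(m).mean(axis=0)[:2][None])
            assert fb.ml_extent[0] - 1e-9 <= mlap[0, 0] <= fb.ml_extent[1] + 1e-9
            assert fb.ap_extent[0] - 1e-9 <= mlap[0, 1] <= fb.ap_extent[1] + 1e-9


def brute_force_ttb(p, v, b_med, b_lat, cap, vthr=1e-6):
    """Independent per-sample evaluation of the TTB definition."""
    ttb = np.empty_like(p)
    valid = np.ones(p.shape, dtype=bool)
    for i in range(p.size):
        if abs(v[i]) < vthr:
            ttb[i] = cap
            valid[i] = False
        elif v[i] > 0:
            ttb[i] = (b_lat - p[i]) / v[i]
        else:
            ttb[i] = (p[i] - b_med) / abs(v[i])
        if p[i] < b_med or p[i] > b_lat or ttb[i] < 0:
            ttb[i] = 0.0
            valid[i] = False
    return ttb, valid


def brute_force_minima(values, valid):
    """Plain-loop local-minima search (strict, first-of-plateau, valid runs)."""
    out = []
    n = len(values)
    for i in range(n):
        if not valid[i]:
            continue
        # left neighbour strictly larger within the valid run
        j = i - 1
        while j >= 0 and valid[j] and values[j] == values[i]:
            j -= 1
        if j < 0 or not valid[j] or values[j] <= values[i]:
            continue
        k = i + 1
        while k < n and valid[k] and values[k] == values[i]:
            k += 1
        if k >= n or not valid[k] or values[k] <= values[i]:
            continue
        if i > 0 and valid[i - 1] and values[i - 1] == values[i]:
            continue  # not first of its plateau
        out.append(i)
    return np.array(out, dtype=int)


class TestTTB:
    def test_constant_velocity_distance_over_speed(self):
        rate = 100.0
        t = np.arange(200) / rate
        p = -0.01 + 0.02 * t  # crosses the centre at t = 0.5 s
        s = posture.ttb_ml(p, rate, (-0.05, 0.05))
        i = 50  # p ~ 0, v = +0.02
        assert np.isclose(s.ttb[i], (0.05 - p[i]) / 0.02, atol=1e-9)
        assert np.isclose(s.ttb[i], 2.5, atol=1e-3)

    def test_zero_velocity_all_capped_invalid(self):
        s = posture.ttb_ml(np.zeros(100), 100.0, (-0.05, 0.05), cap=10.0)
        assert (s.ttb == 10.0).all()
        assert not s.valid.any()

    def test_outside_rectangle_clipped_and_warned(self):
        p = np.linspace(-0.2, 0.2, 100)
        with pytest.warns(posture.BoundaryMismatchWarning):
            s = posture.ttb_ml(p, 100.0, (-0.05, 0.05))
        outside = (p < -0.05) | (p > 0.05)
        assert (s.ttb[outside] == 0.0).all()
        assert not s.valid[outside].any()

    @given(st.integers(0, 500))
    def test_matches_brute_force_on_random_trajectories(self, seed):
        rng = np.random.default_rng(seed)
        rate = 100.0
        t = np.arange(300) / rate
        p = sum(rng.uniform(0.002, 0.01) *
                np.sin(2 * np.pi * rng.uniform(0.2, 2.0) * t + rng.uniform(0, 6))
                for _ in range(3))
        p = np.clip(p, -0.045, 0.045)
        s = posture.ttb_ml(p, rate, (-0.05, 0.05))
        v = np.gradient(p, 1.0 / rate)
        ttb_ref, valid_ref = brute_force_ttb(p, v, -0.05, 0.05, 10.0)
        assert np.abs(s.ttb - ttb_ref).max() < 1e-12
        assert (s.valid == valid_ref).all()

    def test_velocity_scaling_divides_every_valid_sample(self):
        rng = np.random.default_rng(1)
        rate = 100.0
        t = np.arange(500) / rate
        p = 0.02 * np.sin(2 * np.pi * 0.7 * t) + 0.01 * np.sin(2 * np.pi * 1.9 * t)
        v = np.gradient(p, 1.0 / rate)
        for k in (2.0, 3.5):
            a = posture.ttb_ml(p, rate, (-0.05, 0.05), ml_velocity=v)
            b = posture.ttb_ml(p, rate, (-0.05, 0.05), ml_velocity=k * v)
            assert (a.valid == b.valid).all()
            assert np.abs(b.ttb[b.valid] - a.ttb[a.valid] / k).max() < 1e-12
            sa, sb = posture.ttb_summary(a), posture.ttb_summary(b)
            assert np.isclose(sb.mean_of_minima, sa.mean_of_minima / k)
            assert np.isclose(sb.absolute_minimum, sa.absolute_minimum / k)
            assert np.isclose(sb.sd_of_minima, sa.sd_of_minima / k)

    def test_translation_invariance_of_cop_and_boundary(self):
        """Rigidly translating foot markers and COP together leaves every
        TTB summary unchanged (the foot frame moves with them)."""
        tmpl = bk.default_template()
        labels = ["MT1", "MT5", "TOE", "HEEL"]
        base = np.stack([np.tile(tmpl.segments["foot"][m], (50, 1))
                         for m in labels], axis=1)
        rate = 100.0
        t = np.arange(500) / rate
        cop = np.stack([0.02 * np.sin(2 * np.pi * 1.1 * t),
                        0.05 + 0.01 * np.sin(2 * np.pi * 0.4 * t)], axis=1)

        def summarise(shift):
            mk = bk.MarkerTrajectorySet(
                labels, base + np.array([*shift, 0.0]), rate)
            fb = bk.foot_boundary(mk)
            ml = fb.to_foot_frame(cop + np.array(shift))[:, 0]
            return posture.ttb_summary(posture.ttb_ml(ml, rate, fb.ml_extent))

        a = summarise((0.0, 0.0))
        b = summarise((0.31, -0.17))
        assert np.isclose(a.mean_of_minima, b.mean_of_minima, atol=1e-9)
        assert np.isclose(a.absolute_minimum, b.absolute_minimum, atol=1e-9)
        assert np.isclose(a.sd_of_minima, b.sd_of_minima, atol=1e-9)
        assert a.n_minima == b.n_minima


class TestTTBSummary:
    def test_hand_enumerated_example(self):
        s = posture.TTBSeries(np.array([3, 1, 3, 2, 0.5, 2.0]),
                              np.ones(6, bool), 10.0, 100.0)
        out = posture.ttb_summary(s)
        assert out.n_minima == 2
        assert np.isclose(out.mean_of_minima, 0.75)
        assert np.isclose(out.absolute_minimum, 0.5)
        assert np.isclose(out.sd_of_minima, np.std([1, 0.5], ddof=1))
        assert np.isclose(out.sd_of_minima, 0.35355, atol=1e-4)
        assert not out.degenerate

    def test_monotone_series_degenerate_with_last_value(self):
        s = posture.TTBSeries(np.linspace(5, 1, 20), np.ones(20, bool),
                              10.0, 100.0)
        out = posture.ttb_summary(s)
        assert out.degenerate
        assert np.isclose(out.absolute_minimum, 1.0)
        assert out.n_minima == 1

    def test_plateau_takes_first_sample(self):
        vals = np.array([3.0, 1.0, 1.0, 1.0, 3.0, 4.0])
        idx = posture.local_minima_indices(vals, np.ones(6, bool))
        assert idx.tolist() == [1]

    def test_no_valid_samples_rejected(self):
        s = posture.TTBSeries(np.ones(5), np.zeros(5, bool), 10.0, 100.0)
        with pytest.raises(posture.DegenerateTrialError):
            posture.ttb_summary(s)

    @given(st.integers(0, 300))
    def test_minima_match_brute_force_with_masks(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        vals = np.round(rng.uniform(0, 5, n), 1)  # ties are likely
        valid = rng.uniform(size=n) > 0.25
        ours = posture.local_minima_indices(vals, valid)
        ref = brute_force_minima(vals, valid)
        assert ours.tolist() == ref.tolist()

    def test_absolute_minimum_never_exceeds_mean_of_minima(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            vals = rng.uniform(0, 10, 100)
            valid = rng.uniform(size=100) > 0.1
            if not valid.any():
                continue
            try:
                out = posture.ttb_summary(
                    posture.TTBSeries(vals, valid, 10.0, 100.0))
            except posture.DegenerateTrialError:
                continue
            assert out.absolute_minimum <= out.mean_of_minima + 1e-12


class TestSway:
    def test_stationary_cop_zero_metrics(self):
        cop = np.zeros((100, 2))
        s = bk.sway_summary(cop, 100.0)
        assert s.sd_amp == 0.0
        assert s.sway_velocity == 0.0

    def test_circle_constant_amplitude_speed(self):
        rate = 1000.0
        T = 10.0
        t = np.arange(int(T * rate)) / rate
        r = 0.03
        w = 2 * np.pi * 3 / T  # integer revolutions: centroid is the centre
        speed = r * w
        cop = np.stack([r * np.cos(w * t), r * np.sin(w * t)], axis=1)
        s = bk.sway_summary(cop, rate)
        assert s.sd_amp < 1e-9
        assert np.isclose(s.sway_velocity, speed, rtol=1e-4)

    def test_unit_speed_line(self):
        rate = 100.0
        t = np.arange(int(10 * rate) + 1) / rate
        cop = np.stack([t, np.zeros_like(t)], axis=1)
        s = bk.sway_summary(cop, rate)
        assert np.isclose(s.sway_velocity, 1.0, atol=1e-12)
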