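"""Cycle segmentation, the three quality rules at their boundaries, per-cycle
MAPSE, aggregation, and end-to-end recovery."""

import math

import numpy as np
import pytest

from automapse.estimation import (Cycle, CycleSet, FilterConfig,
                                  aggregate, estimate_recording,
                                  jump_filter, mapse_per_cycle,
                                  rwave_weights, segment_cycles_ecg,
                                  segment_cycles_peaks, validity_filter)
from automapse.localization import LandmarkTrack, extract_track
from automapse.simdata import NoiseConfig
from automapse.trajectory import PeakSet, YSeries, rotation_correct

from conftest import make_recording
from test_trajectory import mapse_like_wave, track_from_xy


def yseries(y, valid=None, dt=1 / 38.0):
    y = np.asarray(y, dtype=float)
    valid = np.ones(len(y), bool) if valid is None else np.asarray(valid)
    yy = np.where(valid, y, np.nan)
    return YSeries(y_mm=yy, x_mm=np.zeros_like(yy), valid=valid,
                   times_s=np.arange(len(y)) * dt, rotation_deg_applied=0.0,
                   anisotropy=10.0, low_anisotropy=False, wall=0)


def track_with_validity(valid_per_frame, n=None):
    n = n or len(valid_per_frame)
    valid = np.zeros((n, 2), bool)
    valid[:, 0] = valid_per_frame
    valid[:, 1] = valid_per_frame
    y = np.linspace(0, 1, n)
    return track_from_xy(y, np.zeros(n), valid=valid)


class TestSegmentation:
    def test_four_rwaves_give_three_cycles(self):
        ys = yseries(np.sin(np.arange(120) / 5.0))
        rw = np.array([0.1, 0.9, 1.7, 2.5])
        cs = segment_cycles_ecg(ys, rw)
        assert cs.mode == "ecg" and len(cs) == 3
        for cyc, t in zip(cs.cycles, rw):
            assert cyc.rwave_frame == cyc.start
            assert abs(ys.times_s[cyc.start] - t) <= 0.5 / 38.0 + 1e-9

    def test_rwave_beyond_recording_clipped(self):
        ys = yseries(np.sin(np.arange(40) / 5.0))  # ~1.03 s
        cs = segment_cycles_ecg(ys, np.array([0.1, 0.6, 5.0]))
        assert len(cs) == 2
        assert cs.cycles[-1].end == 39

    def test_single_rwave_errors(self):
        ys = yseries(np.sin(np.arange(40) / 5.0))
        with pytest.raises(ValueError, match="insufficient ECG"):
            segment_cycles_ecg(ys, np.array([0.5]))

    def test_peaks_segmentation(self):
        peaks = PeakSet(maxima_frames=np.array([10, 48, 86]),
                        minima_frames=np.array([25, 60]),
                        prominences_mm=np.array([5.0, 5.0, 5.0]))
        cs = segment_cycles_peaks(peaks)
        assert [(c.start, c.end) for c in cs.cycles] == [(10, 48), (48, 86)]
        empty = segment_cycles_peaks(PeakSet(np.array([]), np.array([]),
                                             np.array([])))
        assert len(empty) == 0


class TestValidityFilter:
    def cycles_one(self, n):
        return CycleSet(mode="peaks", cycles=[Cycle(start=0, end=n)])

    def test_55pct_fails_60pct_passes(self):
        for n_valid, expect in [(11, False), (12, True)]:
            mask = np.zeros(20, bool)
            mask[:n_valid] = True
            track = track_with_validity(mask)
            cs = self.cycles_one(20)
            validity_filter(track, 0, cs, FilterConfig())
            assert cs.cycles[0].passed_validity is expect

    def test_weighted_validity_matches_hand_summed_kernel(self):
        # 40-frame cycle, R-wave at frame 0, invalid frames far from the
        # R-wave: the weighted validity must equal the hand-summed
        # sum(lam*exp(-lam*d)) / Z over valid frames, to 1e-10
        lam = 0.1
        n = 40
        valid = np.ones(n, bool)
        valid[20:] = False  # 50% valid, all invalid frames maximally far
        track = track_with_validity(valid)
        cs = CycleSet(mode="ecg", cycles=[Cycle(start=0, end=n,
                                                rwave_frame=0)])
        validity_filter(track, 0, cs, FilterConfig())
        z = sum(lam * math.exp(-lam * d) for d in range(n))
        expected = sum(lam * math.exp(-lam * d) for d in range(20)) / z
        w = rwave_weights(n, 0, lam)
        assert float(w @ valid) == pytest.approx(expected, abs=1e-10)
        assert expected > 0.5  # near frames count more than far frames
        assert cs.cycles[0].passed_validity is (expected >= 0.6)

    def test_weighted_mode_can_pass_where_unweighted_fails(self):
        n = 40
        valid = np.ones(n, bool)
        valid[22:] = False  # 55% valid: unweighted fails
        track = track_with_validity(valid)
        peaks_cs = self.cycles_one(n)
        validity_filter(track, 0, peaks_cs, FilterConfig())
        assert peaks_cs.cycles[0].passed_validity is False
        ecg_cs = CycleSet(mode="ecg",
                          cycles=[Cycle(start=0, end=n, rwave_frame=0)])
        validity_filter(track, 0, ecg_cs, FilterConfig())
        assert ecg_cs.cycles[0].passed_validity is True

    def test_all_valid_passes_regardless_of_lambda(self):
        track = track_with_validity(np.ones(30, bool))
        for lam in (0.01, 0.1, 2.0):
            cs = CycleSet(mode="ecg",
                          cycles=[Cycle(start=0, end=30, rwave_frame=15)])
            validity_filter(track, 0, cs, FilterConfig(lambda_per_frame=lam))
            w = rwave_weights(30, 15, lam)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            assert cs.cycles[0].passed_validity is True


class TestJumpFilter:
    def make_jump_track(self, jump_mm, at=50, n=120):
        # flat trace with a single-frame lateral excursion: the 2D step into
        # (and out of) frame `at` is exactly jump_mm
        rows = np.zeros(n)
        cols = np.zeros(n)
        cols[at] += jump_mm
        return track_from_xy(rows, cols)

    def test_exactly_5mm_retained_above_discarded(self):
        cfg = FilterConfig()
        for jump, expect_pass in [(5.0, True), (5.1, False), (6.0, False)]:
            track = self.make_jump_track(jump)
            ys = rotation_correct(track, 0)
            cs = CycleSet(mode="ecg", cycles=[
                Cycle(start=0, end=39, rwave_frame=0),
                Cycle(start=39, end=78, rwave_frame=39),
                Cycle(start=78, end=117, rwave_frame=78)])
            jump_filter(track, ys, 0, cs, cfg)
            assert cs.cycles[1].passed_jump is expect_pass
            assert cs.cycles[0].passed_jump and cs.cycles[2].passed_jump

    def test_peaks_mode_discards_both_adjacent_cycles(self):
        track = self.make_jump_track(6.0, at=50)
        ys = rotation_correct(track, 0)
        peaks = PeakSet(maxima_frames=np.array([5, 44, 83]),
                        minima_frames=np.array([20, 60]),
                        prominences_mm=np.array([9.0] * 3))
        cs = segment_cycles_peaks(peaks)
        jump_filter(track, ys, 0, cs, FilterConfig(), peaks=peaks)
        # jump at frame 50 -> nearest maximum 44 -> both cycles it bounds
        assert cs.cycles[0].passed_jump is False
        assert cs.cycles[1].passed_jump is False

    def test_clean_recording_has_no_jumps(self):
        seq, gt = make_recording(seed=21, hr=74.0)
        track = extract_track(seq)
        # oracle: the true frame-to-frame step stays below the threshold
        step = np.linalg.norm(np.diff(gt.positions_mm[:, 0], axis=0), axis=1)
        assert step.max() < 5.0
        ys = rotation_correct(track, 0)
        cs = segment_cycles_ecg(ys, gt.rwave_times_s)
        jump_filter(track, ys, 0, cs, FilterConfig())
        assert all(c.passed_jump for c in cs.cycles)


class TestMapsePerCycle:
    def test_amplitude_recovered_from_shaped_cycle(self):
        _, y = mapse_like_wave(n=45, amplitude=10.0)
        ys = yseries(y)
        cs = CycleSet(mode="ecg", cycles=[Cycle(start=0, end=45,
                                                rwave_frame=0)])
        for c in cs.cycles:
            c.passed_validity = c.passed_jump = True
        est = mapse_per_cycle(ys, cs, FilterConfig())
        assert est[0] == pytest.approx(float(y.max() - y.min()), abs=1e-9)

    def test_monotonic_cycle_yields_no_estimate(self):
        ys = yseries(np.linspace(0, 10, 40))
        cs = CycleSet(mode="ecg", cycles=[Cycle(start=0, end=40,
                                                rwave_frame=0)])
        cs.cycles[0].passed_validity = cs.cycles[0].passed_jump = True
        est = mapse_per_cycle(ys, cs, FilterConfig())
        assert est == []
        assert cs.cycles[0].discard_reason == "no_peak_pair"

    def test_unphysiological_estimate_discarded(self):
        _, y = mapse_like_wave(n=45, amplitude=40.0)
        ys = yseries(y)
        cs = CycleSet(mode="ecg", cycles=[Cycle(start=0, end=45,
                                                rwave_frame=0)])
        cs.cycles[0].passed_validity = cs.cycles[0].passed_jump = True
        est = mapse_per_cycle(ys, cs, FilterConfig())
        assert est == []
        assert cs.cycles[0].discard_reason == "unphysiological"


class TestAggregate:
    def wall_result(self, estimates, n_cycles=3):
        cycles = [Cycle(start=i * 10, end=(i + 1) * 10)
                  for i in range(n_cycles)]
        for i, c in enumerate(cycles):
            if i < len(estimates):
                c.passed_validity = c.passed_jump = True
                c.estimate_mm = estimates[i]
            else:
                c.passed_validity = False
                c.discard_reason = "validity"
        cs = CycleSet(mode="ecg", cycles=cycles)
        return aggregate(0, "left", cs, list(estimates))

    def test_mean_and_feasibility(self):
        res = self.wall_result([8.0, 10.0])
        assert res.mean_mm == pytest.approx(9.0)
        assert res.feasible and res.n_valid_cycles == 2

    def test_empty_is_nonfeasible(self):
        res = self.wall_result([])
        assert res.mean_mm is None and not res.feasible

    def test_counts_reconcile(self):
        res = self.wall_result([7.0], n_cycles=3)
        assert res.n_cycles == res.n_valid_cycles + \
            sum(res.discard_counts.values())


class TestEndToEnd:
    def test_recovery_and_mode_agreement_clean(self):
        rng = np.random.default_rng(7)
        for case in range(5):
            hr = float(rng.uniform(42, 153))
            amp = float(np.interp(hr, [42, 153], [22, 4]))
            seq, gt = make_recording(seed=200 + case, hr=hr,
                                     mapse=(amp, amp * 0.92),
                                     image=(160, 160))
            res_e = estimate_recording(seq, rwave_times_s=gt.rwave_times_s,
                                       mode="ecg")
            res_p = estimate_recording(seq, mode="peaks")
            for w in range(2):
                assert res_e.walls[w].feasible and res_p.walls[w].feasible
                assert res_e.walls[w].mean_mm == pytest.approx(
                    gt.mapse_truth_mm[w], abs=0.5)
                assert abs(res_e.walls[w].mean_mm
                           - res_p.walls[w].mean_mm) <= 0.2

    def test_injected_jump_discards_only_that_cycle(self):
        seq, gt = make_recording(seed=33)
        track = extract_track(seq)
        ys = rotation_correct(track, 0)
        cs = segment_cycles_ecg(ys, gt.rwave_times_s)
        mid = (cs.cycles[1].start + cs.cycles[1].end) // 2
        # inject a 6 mm lateral displacement inside cycle 2 of 3
        track.coords_mm[mid, 0, 1] += 6.0
        track.coords_px[mid, 0, 1] += 6.0 / track.pixel_spacing_mm
        jump_filter(track, ys, 0, cs, FilterConfig())
        assert [c.passed_jump for c in cs.cycles] == [True, False, True]

    def test_zero_surviving_estimates_marks_wall_nonfeasible(self):
        noise = NoiseConfig(dropout_prob=0.95, jitter_sigma_px=0,
                            clutter_prob=0, seed=4)
        seq, gt = make_recording(seed=44, noise=noise)
        res = estimate_recording(seq, rwave_times_s=gt.rwave_times_s,
                                 mode="ecg")
        assert res.n_walls_feasible == 0
        for w in res.walls:
            assert not w.feasible and w.mean_mm is None

    def test_filter_monotone_in_dropout(self):
        # more dropout never yields more valid cycles (coupled seeds)
        prev = None
        for p in [0.0, 0.3, 0.6, 0.9]:
            noise = NoiseConfig(dropout_prob=p, jitter_sigma_px=0.5,
                                clutter_prob=0, seed=10)
            seq, gt = make_recording(seed=55, noise=noise)
            res = estimate_recording(seq, rwave_times_s=gt.rwave_times_s,
                                     mode="ecg")
            total = sum(w.n_valid_cycles for w in res.walls)
            if prev is not None:
                assert total <= prev
            prev = total

    def test_discard_reasons_reconcile_under_noise(self):
        rng = np.random.default_rng(3)
        for case in range(6):
            noise = NoiseConfig(dropout_prob=float(rng.uniform(0, 0.5)),
                                jitter_sigma_px=1.0,
                                clutter_prob=float(rng.uniform(0, 0.3)),
                                seed=case)
            seq, gt = make_recording(seed=300 + case, noise=noise)
            for mode, rw in [("ecg", gt.rwave_times_s), ("peaks", None)]:
                res = estimate_recording(seq, rwave_times_s=rw, mode=mode)
                for w in res.walls:
                    if w.error is None:
                        assert w.n_cycles == w.n_valid_cycles + \
                            sum(w.discard_counts.values())
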