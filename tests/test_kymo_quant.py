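import numpy as np
import pytest

from curtainkit.kymo_quant import (CensorReason, CollisionOutcome, Kymograph,
                                   Segment, Termination, Trajectory,
                                   classify_termination, default_v_min,
                                   detect_release, events_to_dataframe,
                                   extract_events, score_collisions,
                                   segment_trajectory, track_free_end)
from curtainkit.synthetic_curtain import (SimParams, render_kymograph,
                                          simulate_compaction_trajectory,
                                          simulate_dataset)
from curtainkit.units import CurtainGeometry


def make_traj(pos, geometry, dt=5.0):
    pos = np.asarray(pos, dtype=float)
    return Trajectory(0, np.arange(len(pos)) * dt, pos, geometry)


class TestTracking:
    def test_noiseless_render_within_half_pixel(self, clean_params):
        traj, _ = simulate_compaction_trajectory(clean_params, 0)
        tracked = track_free_end(render_kymograph(traj, clean_params, noise=False))
        err = (tracked.pos_um - traj.pos_um) / traj.geometry.pixel_size_um
        assert np.nanmax(np.abs(err)) < 0.5

    def test_shot_noise_render_within_one_pixel_rms(self):
        p = SimParams(seed=3, n_molecules=4)
        errs = []
        for m in range(4):
            traj, _ = simulate_compaction_trajectory(p, m)
            tracked = track_free_end(render_kymograph(traj, p, noise=True))
            errs.append((tracked.pos_um - traj.pos_um) / 0.267)
        rms = np.sqrt(np.nanmean(np.concatenate(errs) ** 2))
        assert rms < 1.0

    def test_all_background_kymograph_raises(self, geometry):
        img = np.full((20, 50), 100.0)
        with pytest.raises(ValueError, match="empty kymograph"):
            track_free_end(Kymograph(img, geometry))

    def test_too_few_frames_rejected(self, geometry):
        with pytest.raises(ValueError):
            track_free_end(Kymograph(np.zeros((3, 50)), geometry))


class TestSegmentation:
    def test_pure_ramp_gives_one_exact_segment(self, geometry):
        t = np.arange(0, 300, 5.0)
        traj = make_traj(10.75 - 0.2 * t, geometry)
        [seg] = segment_trajectory(traj)
        assert seg.slope_um_s == pytest.approx(-0.200, abs=1e-9)

    def test_constant_position_gives_one_zero_slope_segment(self, geometry):
        traj = make_traj(np.full(40, 5.0), geometry)
        [seg] = segment_trajectory(traj)
        assert seg.slope_um_s == pytest.approx(0.0, abs=1e-12)
        assert seg.kind(default_v_min(geometry)) == "stall"

    def test_three_phase_trajectory_recovers_signs_and_changepoints(self, geometry, rng):
        # -0.2 um/s for 50 s, +0.1 for 20 s, -0.2 for 30 s, 0.05 px noise
        t = np.arange(0, 100, 5.0)
        y = np.piecewise(
            t, [t < 50, (t >= 50) & (t < 70), t >= 70],
            [lambda t: 10.75 - 0.2 * t,
             lambda t: 10.75 - 10.0 + 0.1 * (t - 50),
             lambda t: 10.75 - 10.0 + 2.0 - 0.2 * (t - 70)])
        traj = make_traj(y + rng.normal(0, 0.05 * 0.267, t.size), geometry)
        segs = segment_trajectory(traj)
        assert len(segs) == 3
        assert [np.sign(s.slope_um_s) for s in segs] == [-1, 1, -1]
        assert segs[1].i0 in (10, 11) and segs[2].i0 in (14, 15)

    def test_displacement_consistent_with_slope_and_span(self, geometry, rng):
        t = np.arange(0, 300, 5.0)
        traj = make_traj(10.75 - 0.02 * t + rng.normal(0, 0.01, t.size), geometry)
        for s in segment_trajectory(traj):
            j0 = max(s.i0 - 1, 0)
            span = traj.t_s[s.i1 - 1] - traj.t_s[j0]
            assert s.displacement_um == pytest.approx(s.slope_um_s * span)

    def test_too_short_trajectory_rejected(self, geometry):
        with pytest.raises(ValueError):
            segment_trajectory(make_traj([1.0, 2.0], geometry))


def _staircase_trajectory(geometry, pieces, dt=5.0, start=10.75):
    """Build a trajectory from (slope, n_frames) pieces."""
    pos = [start]
    for slope, n in pieces:
        for _ in range(n):
            pos.append(pos[-1] + slope * dt)
    return make_traj(pos, geometry, dt)


class TestEventExtraction:
    def test_runs_split_by_away_segments(self, geometry):
        # +3 um toward the barrier, 1 um away, 2 um toward: processivities [3, 2]
        traj = _staircase_trajectory(geometry, [(0.0, 5), (-0.1, 6), (+0.05, 4),
                                                (-0.1, 4), (0.0, 6)])
        events = extract_events(segment_trajectory(traj), traj)
        assert [round(e.processivity_um, 6) for e in events] == [3.0, 2.0]
        assert events[0].termination == Termination.REVERSAL
        assert not events[0].censored
        assert all(v > 0 for e in events for v in e.velocities_um_s)

    def test_processivity_equals_sum_of_segment_displacements(self, geometry):
        traj = _staircase_trajectory(geometry, [(0.0, 5), (-0.1, 6), (0.0, 4),
                                                (-0.05, 6), (+0.08, 4), (0.0, 5)])
        segs = segment_trajectory(traj)
        [ev, *_] = extract_events(segs, traj)
        v_min = default_v_min(geometry)
        toward_disp = sum(-s.displacement_um for s in segs
                          if s.kind(v_min) == "toward" and s.i0 <= 21)
        assert ev.processivity_um == pytest.approx(toward_disp)

    def test_stall_inside_run_does_not_split_it(self, geometry):
        traj = _staircase_trajectory(geometry, [(0.0, 5), (-0.1, 5), (0.0, 4),
                                                (-0.1, 5), (+0.09, 4), (0.0, 4)])
        events = extract_events(segment_trajectory(traj), traj)
        assert len(events) == 1
        assert events[0].processivity_um == pytest.approx(5.0, abs=1e-6)

    def test_run_reaching_barrier_is_complete_and_censored(self, geometry):
        traj = _staircase_trajectory(geometry, [(0.0, 4), (-0.2, 10), (0.0, 6)],
                                     start=10.2)
        [ev] = extract_events(segment_trajectory(traj), traj)
        assert ev.termination == Termination.COMPLETE
        assert ev.censored and ev.censor_reason == CensorReason.BARRIER_1PX

    def test_run_cut_by_record_end_is_censored(self, geometry):
        traj = _staircase_trajectory(geometry, [(0.0, 10), (-0.1, 10)])
        [ev] = extract_events(segment_trajectory(traj), traj)
        assert ev.censored and ev.censor_reason == CensorReason.END_OF_RECORD

    def test_run_in_progress_at_record_start_is_censored(self, geometry):
        traj = _staircase_trajectory(geometry, [(-0.1, 8), (0.0, 10)], start=8.0)
        [ev] = extract_events(segment_trajectory(traj), traj)
        assert ev.censored and ev.censor_reason == CensorReason.END_OF_RECORD

    def test_terminal_stall_is_not_censored(self, geometry):
        traj = _staircase_trajectory(geometry, [(0.0, 4), (-0.1, 8), (0.0, 12)])
        [ev] = extract_events(segment_trajectory(traj), traj)
        assert ev.termination == Termination.STALL
        assert not ev.censored

    def test_lag_is_time_to_first_run_start(self, geometry):
        traj = _staircase_trajectory(geometry, [(0.0, 10), (-0.1, 6), (0.0, 6)])
        [ev] = extract_events(segment_trajectory(traj), traj, arrival_t=10.0)
        # first toward frame is frame 10 (t = 50 s), arrival at 10 s
        assert ev.lag_s == pytest.approx(40.0, abs=5.0)

    def test_arrival_after_record_end_rejected(self, geometry):
        traj = _staircase_trajectory(geometry, [(0.0, 10)])
        with pytest.raises(ValueError):
            extract_events(segment_trajectory(traj), traj, arrival_t=1e6)

    def test_annotated_censor_reason_wins(self, geometry):
        traj = _staircase_trajectory(geometry, [(0.0, 4), (-0.1, 8), (0.0, 12)])
        [ev] = extract_events(segment_trajectory(traj), traj,
                              annotations={0: CensorReason.DNA_BREAKAGE})
        assert ev.censored and ev.censor_reason == CensorReason.DNA_BREAKAGE


class TestReleaseDetection:
    def _run_of(self, traj):
        from curtainkit.kymo_quant import _group_runs
        segs = segment_trajectory(traj)
        return _group_runs(segs, default_v_min(traj.geometry))[0]

    def test_single_frame_full_recovery_is_release(self, geometry):
        pos = [10.75] * 5 + [10.75 - 0.5 * k for k in range(1, 9)] + [10.75] * 8
        traj = make_traj(pos, geometry)
        run = self._run_of(traj)
        assert detect_release(traj, run)
        assert classify_termination(run, traj) == Termination.RELEASE

    def test_gradual_ramp_back_is_reversal_not_release(self, geometry):
        down = [10.75 - 0.5 * k for k in range(1, 9)]
        up = [down[-1] + 1.3 * k for k in range(1, 6)]
        traj = make_traj([10.75] * 5 + down + up + [10.75] * 4, geometry)
        run = self._run_of(traj)
        assert not detect_release(traj, run)
        assert classify_termination(run, traj) == Termination.REVERSAL

    def test_partial_single_frame_recovery_is_not_release(self, geometry):
        down = [10.75 - 0.5 * k for k in range(1, 9)]        # compacted 4 um
        pos = [10.75] * 5 + down + [down[-1] + 2.0] * 8       # recovers 50%
        traj = make_traj(pos, geometry)
        assert not detect_release(traj, self._run_of(traj))


class TestCollisions:
    def test_constant_velocity_crossing_is_clean_bypass(self, geometry):
        traj = _staircase_trajectory(geometry, [(0.0, 4), (-0.2, 9), (0.0, 4)])
        [rec] = score_collisions(traj, [5.0], smooth=False)
        assert rec.outcome == CollisionOutcome.BYPASS_NO_PAUSE
        assert rec.pause_frames == 0

    def test_two_frame_plateau_at_nucleosome_is_paused_bypass(self, geometry):
        traj = _staircase_trajectory(
            geometry, [(0.0, 4), (-0.2, 5), (0.0, 2), (-0.2, 5), (0.0, 4)])
        nuc = traj.pos_um[9]  # position of the plateau
        [rec] = score_collisions(traj, [nuc], smooth=False)
        assert rec.outcome == CollisionOutcome.BYPASS_WITH_PAUSE
        assert rec.pause_frames == 2

    def test_release_at_nucleosome_scored_as_release(self, geometry):
        down = [10.75 - 0.5 * k for k in range(1, 9)]
        traj = make_traj([10.75] * 5 + down + [10.75] * 8, geometry)
        nuc = down[-1] + 0.1
        [rec] = score_collisions(traj, [nuc], smooth=False)
        assert rec.outcome == CollisionOutcome.RELEASE

    def test_position_outside_span_rejected(self, geometry):
        traj = _staircase_trajectory(geometry, [(0.0, 10)])
        with pytest.raises(ValueError):
            score_collisions(traj, [99.0])

    def test_simulated_collision_outcome_fractions(self):
        p = SimParams(seed=13, n_molecules=120)
        _, truths = simulate_dataset(p, with_nucleosomes=True)
        outcomes = [c.outcome for g in truths for c in g.collisions]
        assert len(outcomes) > 100
        bypass = np.mean([o.startswith("bypass") for o in outcomes])
        assert bypass == pytest.approx(0.8, abs=0.1)


class TestClosedLoopInvariants:
    def test_censoring_soundness_on_simulated_events(self):
        trajs, _ = simulate_dataset(SimParams(seed=17, n_molecules=60))
        n_ev = 0
        for traj in trajs:
            for ev in extract_events(segment_trajectory(traj), traj):
                n_ev += 1
                assert ev.censored == (ev.censor_reason != CensorReason.NONE)
                if ev.termination == Termination.COMPLETE:
                    assert ev.censor_reason == CensorReason.BARRIER_1PX
                assert all(v > 0 for v in ev.velocities_um_s)
                assert ev.processivity_um >= 0
        assert n_ev > 40

    def test_events_dataframe_has_bp_columns_consistent_with_units(self, geometry):
        from curtainkit.units import um_to_bp
        traj = _staircase_trajectory(geometry, [(0.0, 5), (-0.1, 6), (0.0, 5)])
        df = events_to_dataframe(extract_events(segment_trajectory(traj), traj),
                                 geometry)
        np.testing.assert_allclose(df["velocity_bp_s"],
                                   um_to_bp(df["velocity_um_s"].to_numpy(), geometry))
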