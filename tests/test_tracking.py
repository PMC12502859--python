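"""Record-then-replay tracking: recording, interpolation, closed-loop replay."""

import math

import numpy as np
import pytest

from conftest import ground_truth_marks
from edpilot.beam_calibration import CalibrationConfig, calibrate_on_scope
from edpilot.tracking import (
    AcquireConfig,
    ExtrapolationError,
    RecordConfig,
    TrackingError,
    build_trajectory,
    interpolate,
    load_trajectory,
    record_trajectory_images,
    save_trajectory,
    track_and_acquire,
    update_trajectory,
)
from edpilot.virtual_microscope import (
    Crystal,
    GonioModel,
    VirtualMicroscope,
    VirtualScene,
)


def sine_path(alpha):
    return (256.0 + 40.0 * math.sin(math.radians(alpha + 20.0)), 256.0)


class TestRecord:
    def test_snapshot_count_and_return_to_start(self, crystal_scene):
        scope = VirtualMicroscope(crystal_scene)
        config = RecordConfig(-60, 60, image_interval=2.0, exposure=50.0, rotation_speed=2.0)
        run = record_trajectory_images(scope, config)
        # span / (speed × interval) + 1 snapshots across the sweep
        assert len(run.images) == int(120.0 / (2.0 * 2.0)) + 1
        alphas = [a for a, _ in run.images]
        assert alphas == sorted(alphas)
        assert alphas[-1] == pytest.approx(60.0, abs=0.1)
        assert scope.stage.alpha == pytest.approx(-60.0, abs=1e-6)

    def test_interval_shorter_than_exposure_rejected(self):
        with pytest.raises(ValueError):
            RecordConfig(-60, 60, image_interval=0.04, exposure=50.0)

    def test_blanked_fraction_between_snapshots(self, crystal_scene):
        scope = VirtualMicroscope(crystal_scene)
        config = RecordConfig(
            -60, 60, image_interval=2.0, exposure=50.0, blank_between=True
        )
        record_trajectory_images(scope, config)
        assert scope.blanked_time_s / scope.time_s > 0.9
        assert not scope.beam.blanked  # unblanked once finished

    def test_stage_limit_truncates_with_warning(self, crystal_scene):
        scope = VirtualMicroscope(crystal_scene)  # ±70° hard limit
        run = record_trajectory_images(scope, RecordConfig(-60, 85, image_interval=2.0))
        assert run.warning is not None
        assert max(a for a, _ in run.images) <= 70.0


class TestTrajectory:
    def test_linear_midpoint(self):
        traj = build_trajectory([(-60, 100, 100), (60, 200, 200)], "linear")
        assert interpolate(traj, 0.0) == pytest.approx((150.0, 150.0))

    def test_duplicate_alpha_marks_averaged(self):
        traj = build_trajectory([(0, 10, 10), (0, 20, 30), (10, 50, 50)], "linear")
        assert interpolate(traj, 0.0) == pytest.approx((15.0, 20.0))

    def test_single_alpha_rejected(self):
        with pytest.raises(TrackingError):
            build_trajectory([(0, 1, 1), (0, 2, 2)])

    def test_anchors_reproduced_exactly(self):
        marks = [(a, *sine_path(a)) for a in range(-60, 61, 10)]
        for method in ("linear", "spline"):
            traj = build_trajectory(marks, method)
            for a, u, v in marks:
                assert interpolate(traj, a) == pytest.approx((u, v), abs=1e-9)

    def test_spline_reproduces_a_line(self):
        marks = [(a, 100.0 + 2.0 * a, 50.0 - a) for a in (-30, 0, 30)]
        spline = build_trajectory(marks, "spline")
        linear = build_trajectory(marks, "linear")
        for a in np.linspace(-30, 30, 13):
            assert interpolate(spline, a) == pytest.approx(interpolate(linear, a), abs=1e-9)

    def test_spline_beats_linear_on_smooth_path(self):
        marks = [(a, *sine_path(a)) for a in range(-60, 61, 10)]
        spline = build_trajectory(marks, "spline")
        linear = build_trajectory(marks, "linear")
        midpoints = np.arange(-55, 60, 10.0)
        err_s = max(abs(interpolate(spline, a)[0] - sine_path(a)[0]) for a in midpoints)
        err_l = max(abs(interpolate(linear, a)[0] - sine_path(a)[0]) for a in midpoints)
        assert err_s < err_l
        assert abs(interpolate(spline, 55.0)[0] - sine_path(55.0)[0]) < 1.5
        assert abs(interpolate(spline, -55.0)[0] - sine_path(-55.0)[0]) < 1.5

    def test_no_silent_extrapolation(self):
        traj = build_trajectory([(-60, 100, 100), (60, 200, 200)])
        with pytest.raises(ExtrapolationError):
            interpolate(traj, 61.0)

    def test_error_decreases_with_anchor_density(self):
        # non-strict monotone improvement as the anchor grid is doubled
        dense_eval = np.linspace(-60, 60, 241)
        errors = []
        for step in (20, 10, 5):
            marks = [(float(a), *sine_path(a)) for a in np.arange(-60, 61, step)]
            traj = build_trajectory(marks, "spline")
            errors.append(
                max(abs(interpolate(traj, a)[0] - sine_path(a)[0]) for a in dense_eval)
            )
        assert errors[0] >= errors[1] >= errors[2]

    def test_file_round_trip(self, tmp_path):
        traj = build_trajectory(
            [(a, *sine_path(a)) for a in range(-60, 61, 10)], "spline",
            source_run_id="abc123",
        )
        path = tmp_path / "traj.json"
        save_trajectory(traj, path)
        back = load_trajectory(path)
        assert back.anchors == traj.anchors
        assert back.method == traj.method
        assert back.source_run_id == "abc123"


def tracked_scene(**gonio_kw):
    kw = dict(z_euc_true=-25.0, runout_amplitude=1.5, runout_phase=30.0, seed=7)
    kw.update(gonio_kw)
    return VirtualScene(crystals=[Crystal(1.0, 0.5, 300)], gonio=GonioModel(**kw))


def recorded_trajectory(scope, span=(-60.0, 60.0)):
    run = record_trajectory_images(
        scope, RecordConfig(span[0], span[1], image_interval=2.0, exposure=50.0)
    )
    marks = ground_truth_marks(scope, [a for a, _ in run.images])
    return run, build_trajectory(marks, "spline", source_run_id=run.run_id)


class TestTrackAndAcquire:
    def test_continuous_replay_keeps_crystal_in_beam(self):
        scene = tracked_scene()
        scope = VirtualMicroscope(scene)
        scope.move_stage(z=5.0)  # deliberately off-eucentric: large drift
        calib = calibrate_on_scope(scope, CalibrationConfig(delta=0.1))
        _, traj = recorded_trajectory(scope)
        lo, hi = traj.alpha_range
        frames, log = track_and_acquire(
            scope, traj, calib,
            AcquireConfig(alpha_start=lo, alpha_end=hi, rotation_speed=2.0, exposure=500.0),
        )
        assert max(e.beam_crystal_distance for e in log) < 2.0
        # frame count and angular spacing follow the dead-time arithmetic
        deg_per_frame = 2.0 * (500.0 + 21.0) / 1000.0
        assert len(frames) == int((hi - lo) / deg_per_frame)
        spacings = np.diff([e.alpha for e in log])
        np.testing.assert_allclose(spacings, deg_per_frame, rtol=1e-6)

    def test_tracking_benefit_under_large_drift(self):
        # drift amplitude three beam radii: untracked loses the crystal
        scene = tracked_scene(z_euc_true=0.0, runout_amplitude=3.6, runout_phase=0.0)
        assert scene.pixel_scale * scene.gonio.runout_amplitude == pytest.approx(
            3 * scene.beam_radius_px
        )
        config = None
        results = {}
        for tracking in (False, True):
            scope = VirtualMicroscope(scene)
            calib = calibrate_on_scope(scope, CalibrationConfig(delta=0.1))
            _, traj = recorded_trajectory(scope)
            lo, hi = traj.alpha_range
            config = AcquireConfig(alpha_start=lo, alpha_end=hi, rotation_speed=2.0,
                                   exposure=500.0)
            _, log = track_and_acquire(scope, traj, calib, config, tracking=tracking)
            results[tracking] = np.mean(
                [e.beam_crystal_distance <= scene.beam_radius_px for e in log]
            )
        assert results[False] < 0.5
        assert results[True] == 1.0

    def test_stepwise_precession_grid(self):
        scene = tracked_scene()
        scope = VirtualMicroscope(scene)
        calib = calibrate_on_scope(scope, CalibrationConfig(delta=0.1))
        marks = ground_truth_marks(scope, np.arange(-60.0, 61.0, 5.0))
        traj = build_trajectory(marks, "spline")
        frames, log = track_and_acquire(
            scope, traj, calib,
            AcquireConfig(alpha_start=-60, alpha_end=60, mode="stepwise_precession",
                          step=1.0, exposure=500.0),
        )
        assert len(frames) == 121
        assert all(e.precession for e in log)
        assert [e.alpha for e in log] == pytest.approx(list(np.arange(-60.0, 61.0)))

    def test_sweep_exceeding_trajectory_rejected_before_exposure(self):
        scene = tracked_scene()
        scope = VirtualMicroscope(scene)
        calib = calibrate_on_scope(scope, CalibrationConfig(delta=0.1))
        traj = build_trajectory(ground_truth_marks(scope, [-30.0, 0.0, 30.0]))
        with pytest.raises(TrackingError):
            track_and_acquire(
                scope, traj, calib,
                AcquireConfig(alpha_start=-60, alpha_end=60),
            )

    def test_replay_stability_across_cycles(self):
        # one recorded trajectory serves 12 consecutive acquisitions on a
        # reproducible-runout goniometer without losing the crystal
        scene = tracked_scene()
        scope = VirtualMicroscope(scene)
        scope.move_stage(z=5.0)
        calib = calibrate_on_scope(scope, CalibrationConfig(delta=0.1))
        _, traj = recorded_trajectory(scope)
        lo, hi = traj.alpha_range
        config = AcquireConfig(alpha_start=lo, alpha_end=hi, rotation_speed=2.0,
                               exposure=500.0)
        for _ in range(12):
            _, log = track_and_acquire(scope, traj, calib, config)
            assert max(e.beam_crystal_distance for e in log) < scene.beam_radius_px


class TestUpdateTrajectory:
    def test_multiple_crystals_from_one_record(self):
        scene = VirtualScene(
            crystals=[Crystal(1.0, 0.5, 300), Crystal(-1.5, -1.0, 300), Crystal(0.2, 2.0, 300)],
            gonio=GonioModel(z_euc_true=-20.0, runout_amplitude=1.0, seed=13),
        )
        scope = VirtualMicroscope(scene)
        scope.move_stage(z=3.0)
        calib = calibrate_on_scope(scope, CalibrationConfig(delta=0.1))
        run = record_trajectory_images(
            scope, RecordConfig(-50, 50, image_interval=2.0, exposure=50.0)
        )
        alphas = [a for a, _ in run.images]
        for idx in range(3):
            marks = ground_truth_marks(scope, alphas, crystal_index=idx)
            traj = update_trajectory(run, marks)
            assert traj.source_run_id == run.run_id
            lo, hi = traj.alpha_range
            _, log = track_and_acquire(
                scope, traj, calib,
                AcquireConfig(alpha_start=lo, alpha_end=hi, exposure=500.0),
                crystal_index=idx,
            )
            assert max(e.beam_crystal_distance for e in log) < scene.beam_radius_px

    def test_empty_marks_rejected(self):
        scene = tracked_scene()
        scope = VirtualMicroscope(scene)
        run = record_trajectory_images(scope, RecordConfig(-20, 20, image_interval=2.0))
        with pytest.raises(TrackingError):
            update_trajectory(run, [])
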