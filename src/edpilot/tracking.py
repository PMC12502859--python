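"""Record-then-replay crystal tracking for continuous-rotation diffraction.

The workflow has two phases.  *Record*: rotate the stage through the full
tilt range in imaging mode and grab low-dose snapshots at fixed time
intervals; the operator marks the crystal in each snapshot, yielding an
angle-indexed trajectory map.  *Track & Acquire*: switch to diffraction
mode, rotate through the same range, and steer the beam along the
interpolated trajectory while collecting diffraction frames, so the crystal
never leaves the illuminated area.  The scheme works because goniometer
runout is reproducible between consecutive rotation cycles; one recorded
trajectory can therefore serve many acquisitions (different crystals in the
same field of view, repeat runs, precession series).
"""

from __future__ import annotations

import json
import math
import uuid
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from . import beam_calibration as bc
from .virtual_microscope import DetectorFrame

__all__ = [
    "TrajectoryMap",
    "RecordConfig",
    "AcquireConfig",
    "RecordRun",
    "TrackLogEntry",
    "record_trajectory_images",
    "build_trajectory",
    "interpolate",
    "track_and_acquire",
    "update_trajectory",
    "save_trajectory",
    "load_trajectory",
]


class TrackingError(RuntimeError):
    pass


class ExtrapolationError(TrackingError):
    """Requested angle lies outside the recorded trajectory range."""


@dataclass
class TrajectoryMap:
    """Angle-indexed crystal positions with an interpolation rule.

    Anchors are (alpha°, u px, v px), strictly increasing in alpha.  The
    spline variant is a natural cubic through the anchors, u and v
    interpolated independently as functions of alpha.
    """

    anchors: list[tuple[float, float, float]]
    method: str = "spline"
    source_run_id: str = ""

    def __post_init__(self) -> None:
        if self.method not in ("linear", "spline"):
            raise ValueError("method must be 'linear' or 'spline'")
        if len(self.anchors) < 2:
            raise ValueError("a trajectory needs at least 2 anchors")
        alphas = [a for a, _, _ in self.anchors]
        if any(b <= a for a, b in zip(alphas, alphas[1:])):
            raise ValueError("anchor alphas must be strictly increasing")
        self._build()

    def _build(self) -> None:
        a = np.array([p[0] for p in self.anchors])
        u = np.array([p[1] for p in self.anchors])
        v = np.array([p[2] for p in self.anchors])
        if self.method == "spline" and len(a) >= 3:
            self._fu = CubicSpline(a, u, bc_type="natural")
            self._fv = CubicSpline(a, v, bc_type="natural")
        else:
            self._fu = lambda x: np.interp(x, a, u)
            self._fv = lambda x: np.interp(x, a, v)

    @property
    def alpha_range(self) -> tuple[float, float]:
        return (self.anchors[0][0], self.anchors[-1][0])


@dataclass(frozen=True)
class RecordConfig:
    alpha_start: float
    alpha_end: float
    image_interval: float = 2.0  # s between snapshots
    exposure: float = 50.0  # ms
    rotation_speed: float = 2.0  # deg/s
    blank_between: bool = False

    def __post_init__(self) -> None:
        if self.alpha_start == self.alpha_end:
            raise ValueError("alpha_start and alpha_end must differ")
        if self.image_interval * 1000.0 < self.exposure:
            raise ValueError("image_interval must be >= exposure")
        if self.rotation_speed <= 0:
            raise ValueError("rotation_speed must be > 0")


@dataclass(frozen=True)
class AcquireConfig:
    alpha_start: float
    alpha_end: float
    rotation_speed: float = 2.0  # deg/s
    exposure: float = 500.0  # ms
    frame_overhead: float = 21.0  # ms of detector dead time per frame
    mode: str = "continuous"  # or "stepwise_precession"
    step: float = 1.0  # deg, stepwise mode only

    def __post_init__(self) -> None:
        if self.rotation_speed <= 0 or self.exposure <= 0:
            raise ValueError("rotation_speed and exposure must be > 0")
        if self.mode not in ("continuous", "stepwise_precession"):
            raise ValueError("mode must be 'continuous' or 'stepwise_precession'")
        if self.mode == "stepwise_precession" and self.step <= 0:
            raise ValueError("step must be > 0 in stepwise mode")


@dataclass
class RecordRun:
    """Output of the Record phase: tilt-tagged snapshots plus provenance."""

    images: list[tuple[float, DetectorFrame]]
    run_id: str
    config: RecordConfig
    warning: str | None = None


@dataclass(frozen=True)
class TrackLogEntry:
    alpha: float  # deg, exposure midpoint
    commanded_pixel: tuple[float, float]
    beam_pixel: tuple[float, float]  # achieved beam centre (simulator truth)
    crystal_pixel: tuple[float, float] | None  # simulator ground truth
    beam_crystal_distance: float | None  # px
    precession: bool = False


def record_trajectory_images(scope, config: RecordConfig, *, presets=None) -> RecordRun:
    """Rotate through the tilt range, imaging at fixed time intervals.

    Loads the stored imaging preset first when a preset store is supplied
    (and refuses to run if the store has none).  Each snapshot is tagged
    with the stage alpha at its exposure midpoint.  If the stage limit cuts
    the sweep short, the partial series is returned with a warning.  On
    completion the stage is driven back to the start angle, ready for the
    Track & Acquire pass.
    """
    if presets is not None:
        preset = presets.get("imaging")
        if preset is None:
            raise TrackingError("no stored imaging preset; store one before Record")
        presets.apply(scope, "imaging")
    else:
        scope.set_mode("imaging")

    limit = scope.stage.alpha_limit
    start = float(np.clip(config.alpha_start, -limit, limit))
    end = float(np.clip(config.alpha_end, -limit, limit))
    warning = None
    if start != config.alpha_start or end != config.alpha_end:
        warning = (
            f"stage limit ±{limit}° truncated the sweep to [{start}, {end}]; "
            "partial series recorded"
        )

    scope.move_stage(alpha=start)
    scope.start_rotation(end, config.rotation_speed)
    images: list[tuple[float, DetectorFrame]] = []
    direction = 1.0 if end >= start else -1.0
    while True:
        if config.blank_between:
            scope.blank(False)
        frame = scope.acquire_frame(config.exposure)
        images.append((frame.stage_alpha_at_exposure, frame))
        if not scope.stage.moving:
            break
        if config.blank_between:
            scope.blank(True)
        scope.wait(config.image_interval - config.exposure / 1000.0)
        if not scope.stage.moving:
            # arrived during the wait: final snapshot at the end angle
            if config.blank_between:
                scope.blank(False)
            frame = scope.acquire_frame(config.exposure)
            images.append((frame.stage_alpha_at_exposure, frame))
            break
    # stage returns to the start angle in preparation for Track & Acquire;
    # the beam stays blanked for the return leg when blank_between is set
    if config.blank_between:
        scope.blank(True)
    scope.start_rotation(start, config.rotation_speed)
    scope.wait(abs(scope.stage.alpha - start) / config.rotation_speed + 1e-9)
    scope.blank(False)
    _ = direction
    return RecordRun(images=images, run_id=uuid.uuid4().hex[:12], config=config, warning=warning)


def build_trajectory(
    marks: list[tuple[float, float, float]],
    method: str = "spline",
    *,
    source_run_id: str = "",
) -> TrajectoryMap:
    """Turn operator marks (alpha, u, v) into an evaluable trajectory.

    Marks sharing the same alpha are averaged; at least two distinct tilt
    angles are required.
    """
    if not marks:
        raise TrackingError("no marks supplied")
    by_alpha: dict[float, list[tuple[float, float]]] = {}
    for a, u, v in marks:
        by_alpha.setdefault(float(a), []).append((float(u), float(v)))
    if len(by_alpha) < 2:
        raise TrackingError("need marks at >= 2 distinct tilt angles")
    anchors = [
        (a, float(np.mean([p[0] for p in pts])), float(np.mean([p[1] for p in pts])))
        for a, pts in sorted(by_alpha.items())
    ]
    return TrajectoryMap(anchors=anchors, method=method, source_run_id=source_run_id)


def interpolate(traj: TrajectoryMap, alpha: float) -> tuple[float, float]:
    """Evaluate the trajectory at tilt ``alpha`` (no silent extrapolation)."""
    lo, hi = traj.alpha_range
    if not (lo - 1e-9 <= alpha <= hi + 1e-9):
        raise ExtrapolationError(
            f"alpha {alpha}° outside trajectory range [{lo}, {hi}]°"
        )
    return (float(traj._fu(alpha)), float(traj._fv(alpha)))


def track_and_acquire(
    scope,
    traj: TrajectoryMap,
    calib: bc.CalibrationMatrix,
    config: AcquireConfig,
    *,
    presets=None,
    crystal_index: int | None = 0,
    tracking: bool = True,
) -> tuple[list[DetectorFrame], list[TrackLogEntry]]:
    """Replay a trajectory while acquiring diffraction frames.

    Continuous mode: the stage rotates at ``rotation_speed`` while the loop
    reads the current tilt, predicts the exposure-midpoint angle, steers the
    beam to the interpolated crystal position via the calibration, and
    exposes; one beam update per frame.  Stepwise (precession) mode: the
    stage pauses at each ``step`` increment and one precession-flagged frame
    is taken.  The per-frame log carries the commanded pixel and, on the
    simulator, the true crystal pixel and beam–crystal distance.

    ``tracking=False`` keeps the beam fixed at the trajectory's start
    position — the untracked control used to quantify the benefit.
    """
    lo, hi = traj.alpha_range
    a_start, a_end = config.alpha_start, config.alpha_end
    if not (min(a_start, a_end) >= lo - 1e-9 and max(a_start, a_end) <= hi + 1e-9):
        raise TrackingError(
            f"trajectory range [{lo}, {hi}]° does not cover the requested "
            f"sweep [{a_start}, {a_end}]°"
        )
    if presets is not None:
        if presets.get("diffraction") is None:
            raise TrackingError(
                "no stored diffraction preset; store one before Track & Acquire"
            )
        presets.apply(scope, "diffraction")
    else:
        scope.set_mode("diffraction")

    frames: list[DetectorFrame] = []
    log: list[TrackLogEntry] = []
    direction = 1.0 if a_end >= a_start else -1.0
    fixed_target = interpolate(traj, a_start)

    def steer(target_px: tuple[float, float]) -> None:
        di = bc.pixel_to_currents(target_px, calib)
        scope.set_deflectors(calib.ref_currents[0] + di[0], calib.ref_currents[1] + di[1])

    def log_frame(alpha_mid: float, target_px: tuple[float, float], precession: bool) -> None:
        beam_px = scope.beam_center()
        crystal_px = dist = None
        if crystal_index is not None and scope.scene.crystals:
            crystal_px = scope.crystal_pixel(crystal_index, alpha=alpha_mid)
            dist = math.hypot(beam_px[0] - crystal_px[0], beam_px[1] - crystal_px[1])
        log.append(
            TrackLogEntry(
                alpha=alpha_mid,
                commanded_pixel=target_px,
                beam_pixel=beam_px,
                crystal_pixel=crystal_px,
                beam_crystal_distance=dist,
                precession=precession,
            )
        )

    if config.mode == "continuous":
        frame_time_s = (config.exposure + config.frame_overhead) / 1000.0
        deg_per_frame = config.rotation_speed * frame_time_s
        n_frames = int(abs(a_end - a_start) / deg_per_frame)
        scope.move_stage(alpha=a_start)
        scope.start_rotation(a_end, config.rotation_speed)
        for _ in range(n_frames):
            alpha_mid = (
                scope.stage.alpha
                + direction * config.rotation_speed * config.exposure / 2000.0
            )
            target = interpolate(traj, alpha_mid) if tracking else fixed_target
            steer(target)
            frames.append(scope.acquire_frame(config.exposure))
            log_frame(alpha_mid, target, precession=False)
            scope.wait(config.frame_overhead / 1000.0)
        if scope.stage.moving:  # let the residual fraction of a frame finish
            scope.wait(
                abs(scope.stage.target_alpha - scope.stage.alpha) / config.rotation_speed
                + 1e-9
            )
    else:
        n_steps = int(round(abs(a_end - a_start) / config.step))
        for i in range(n_steps + 1):
            alpha = a_start + direction * i * config.step
            scope.move_stage(alpha=alpha)
            target = interpolate(traj, alpha) if tracking else fixed_target
            steer(target)
            frames.append(scope.acquire_frame(config.exposure))
            log_frame(alpha, target, precession=True)
    return frames, log


def update_trajectory(
    run: RecordRun,
    new_marks: list[tuple[float, float, float]],
    method: str = "spline",
) -> TrajectoryMap:
    """Build a fresh trajectory from re-marked Record images.

    The new map is bound to the same source run (provenance for "many
    crystals from one Record"); any previous trajectory is untouched.
    """
    if not new_marks:
        raise TrackingError("no marks supplied")
    if not run.images:
        raise TrackingError("record run holds no images")
    return build_trajectory(new_marks, method, source_run_id=run.run_id)


def save_trajectory(traj: TrajectoryMap, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "method": traj.method,
                "source_run_id": traj.source_run_id,
                "anchors": [list(a) for a in traj.anchors],
            },
            fh,
            indent=1,
        )


def load_trajectory(path) -> TrajectoryMap:
    with open(path) as fh:
        doc = json.load(fh)
    return TrajectoryMap(
        anchors=[tuple(a) for a in doc["anchors"]],
        method=doc["method"],
        source_run_id=doc.get("source_run_id", ""),
    )
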