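"""Virtual transmission electron microscope for exercising acquisition logic.

The simulator provides the same contract a hardware control layer would —
stage position and rotation, beam deflectors and blanking, optical modes,
frame acquisition — together with ground-truth geometry, so that every
acquisition algorithm (calibration, eucentric estimation, crystal tracking)
can be tested closed-loop without a microscope.

Geometry model
--------------
Orthographic projection with the goniometer tilt axis along the detector
v (row) axis by default.  A feature at in-plane offset ``(x, y)`` µm from
the tilt axis, at height offset ``h = z_stage − z_euc_true`` µm, projects at
tilt ``α`` to::

    u = s·(x·cosα + h·sinα) + u0 + runout(α) + jitter
    v = s·y + v0

with pixel scale ``s`` (px/µm) and detector centre ``(u0, v0)``.  Mechanical
runout is a deterministic sinusoid of α (the reproducible part of goniometer
error); jitter is seeded Gaussian noise drawn once per exposure (the
non-reproducible part).  An optional in-plane rotation of the tilt axis is
applied after projection.

The detector responds to deflector currents exactly linearly: the beam
centre in pixels is ``centre + R·(i_x, i_y)`` with a fixed 2×2 response
matrix ``R``, so beam-shift calibration has an exact right answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile
import yaml

__all__ = [
    "StageState",
    "BeamState",
    "GonioModel",
    "Crystal",
    "VirtualScene",
    "DetectorFrame",
    "VirtualMicroscope",
    "project_feature",
    "render_frame",
    "advance_rotation",
    "load_scene",
    "save_scene",
]

MODES = ("search", "imaging", "diffraction")


@dataclass
class StageState:
    """Goniometer state: positions in µm, tilt alpha in degrees."""

    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    alpha: float = 0.0
    rotation_speed: float = 2.0  # deg/s
    moving: bool = False
    target_alpha: float = 0.0
    alpha_limit: float = 70.0  # hard tilt limit, ± degrees

    def __post_init__(self) -> None:
        if abs(self.alpha) > self.alpha_limit + 1e-9:
            raise ValueError(f"alpha {self.alpha}° outside ±{self.alpha_limit}° limit")


@dataclass
class BeamState:
    """Illumination state: deflector currents in arbitrary units."""

    deflector_x: float = 0.0
    deflector_y: float = 0.0
    blanked: bool = False
    mode: str = "imaging"
    aperture: float = 300.0  # µm
    convergence_semi_angle: float = 5.0  # µrad

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")


@dataclass
class GonioModel:
    """Ground-truth goniometer imperfections.

    ``runout`` is reproducible (a sinusoid of alpha, identical on every
    rotation cycle — the property record-then-replay tracking relies on);
    ``jitter_sigma`` is non-reproducible Gaussian noise per exposure.
    """

    z_euc_true: float = 0.0  # µm
    tilt_axis_angle: float = 0.0  # deg, in-plane rotation of the axis
    runout_amplitude: float = 0.0  # µm
    runout_phase: float = 0.0  # deg
    jitter_sigma: float = 0.0  # µm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")

    def runout(self, alpha: float) -> float:
        """Reproducible lateral displacement (µm) at tilt ``alpha``."""
        return self.runout_amplitude * math.sin(math.radians(alpha + self.runout_phase))


@dataclass(frozen=True)
class Crystal:
    x: float  # µm, in-plane offset from tilt axis
    y: float  # µm
    size: float = 100.0  # nm


@dataclass
class VirtualScene:
    """Complete ground truth for one simulated experiment."""

    crystals: list[Crystal] = field(default_factory=list)
    gonio: GonioModel = field(default_factory=GonioModel)
    pixel_scale: float = 10.0  # px/µm
    detector_shape: tuple[int, int] = (512, 512)  # (rows, cols)
    gain_map: np.ndarray | None = None
    dead_pixels: frozenset[tuple[int, int]] = frozenset()
    beam_radius_px: float = 12.0  # diffraction-mode illuminated disc
    imaging_beam_radius_px: float | None = 200.0  # None: covers the detector
    beam_response: np.ndarray = field(
        default_factory=lambda: np.array([[180.0, 12.0], [-8.0, -150.0]])
    )  # px per current unit
    illum_rate: float = 2.0  # mean counts/ms inside the illuminated disc
    floor_rate: float = 0.01  # mean counts/ms of stray background

    def __post_init__(self) -> None:
        if self.gain_map is None:
            self.gain_map = np.ones(self.detector_shape)
        self.gain_map = np.asarray(self.gain_map, dtype=float)
        if self.gain_map.shape != tuple(self.detector_shape):
            raise ValueError("gain_map shape must equal detector_shape")
        bad = [
            (r, c)
            for r, c in zip(*np.nonzero(self.gain_map <= 0))
            if (r, c) not in self.dead_pixels
        ]
        if bad:
            raise ValueError(f"gain_map must be > 0 off the dead mask; bad at {bad[:5]}")
        self.beam_response = np.asarray(self.beam_response, dtype=float)

    @property
    def center(self) -> tuple[float, float]:
        """Detector centre as (u, v) = (col, row), 0-based pixel centres."""
        rows, cols = self.detector_shape
        return ((cols - 1) / 2.0, (rows - 1) / 2.0)


@dataclass
class DetectorFrame:
    pixels: np.ndarray  # 2-D uint16
    exposure: float  # ms
    timestamp: float = 0.0  # s, simulated clock
    stage_alpha_at_exposure: float = 0.0  # deg

    def __post_init__(self) -> None:
        if self.exposure <= 0:
            raise ValueError("exposure must be > 0")
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")


def project_feature(
    feature_offset: tuple[float, float],
    height_offset: float,
    alpha: float,
    scene: VirtualScene,
    *,
    jitter_rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Project a specimen feature onto the detector at tilt ``alpha``.

    ``feature_offset`` is the (x, y) in-plane position in µm relative to the
    tilt axis; ``height_offset`` is z_stage − z_euc_true in µm.  Returns the
    (u, v) pixel position.  Jitter is added only when ``jitter_rng`` is given
    (one draw per call, i.e. per exposure).
    """
    x, y = feature_offset
    s = scene.pixel_scale
    a = math.radians(alpha)
    du = s * (x * math.cos(a) + height_offset * math.sin(a)) + s * scene.gonio.runout(alpha)
    dv = s * y
    if jitter_rng is not None and scene.gonio.jitter_sigma > 0:
        du += s * jitter_rng.normal(0.0, scene.gonio.jitter_sigma)
    if scene.gonio.tilt_axis_angle:
        t = math.radians(scene.gonio.tilt_axis_angle)
        du, dv = du * math.cos(t) - dv * math.sin(t), du * math.sin(t) + dv * math.cos(t)
    u0, v0 = scene.center
    return (u0 + du, v0 + dv)


def beam_center_pixel(scene: VirtualScene, beam: BeamState) -> tuple[float, float]:
    """Ground-truth beam-centre pixel for given deflector currents."""
    u0, v0 = scene.center
    shift = scene.beam_response @ np.array([beam.deflector_x, beam.deflector_y])
    return (u0 + shift[0], v0 + shift[1])


def _disc_mask(shape: tuple[int, int], center_uv: tuple[float, float], radius: float) -> np.ndarray:
    rows, cols = shape
    v = np.arange(rows)[:, None]
    u = np.arange(cols)[None, :]
    return (u - center_uv[0]) ** 2 + (v - center_uv[1]) ** 2 <= radius**2


def _gaussian_spot(
    mean: np.ndarray, center_uv: tuple[float, float], sigma: float, amplitude: float
) -> None:
    """Add a circular Gaussian of given peak amplitude in place.

    Evaluated only on a ±6σ window around the centre; the truncated tail is
    below any count level the Poisson stage can resolve.
    """
    rows, cols = mean.shape
    cu, cv = center_uv
    half = int(math.ceil(6.0 * sigma))
    v_lo, v_hi = max(int(cv) - half, 0), min(int(cv) + half + 1, rows)
    u_lo, u_hi = max(int(cu) - half, 0), min(int(cu) + half + 1, cols)
    if v_lo >= v_hi or u_lo >= u_hi:
        return
    v = np.arange(v_lo, v_hi)[:, None]
    u = np.arange(u_lo, u_hi)[None, :]
    r2 = (u - cu) ** 2 + (v - cv) ** 2
    mean[v_lo:v_hi, u_lo:u_hi] += amplitude * np.exp(-r2 / (2.0 * sigma * sigma))


def render_frame(
    scene: VirtualScene,
    stage: StageState,
    beam: BeamState,
    exposure: float,
    *,
    rng: np.random.Generator | None = None,
    timestamp: float = 0.0,
) -> DetectorFrame:
    """Synthesize one detector frame from the scene ground truth.

    Imaging/search mode: an illuminated disc centred on the deflected beam,
    with crystals as dark absorption blobs at their projected positions.
    Diffraction mode: an intense central beam; when a crystal sits inside
    the illuminated disc, a small synthetic reflection lattice appears.
    Per-pixel Poisson noise, multiplicative gain and dead pixels are applied
    in all modes.  A blanked beam leaves only the stray-background floor.
    """
    if exposure <= 0:
        raise ValueError("exposure must be > 0")
    rng = rng if rng is not None else np.random.default_rng(0)
    shape = tuple(scene.detector_shape)
    mean = np.full(shape, scene.floor_rate * exposure, dtype=float)

    h = stage.z - scene.gonio.z_euc_true
    positions = [
        project_feature((c.x, c.y), h, stage.alpha, scene, jitter_rng=rng)
        for c in scene.crystals
    ]
    bc = beam_center_pixel(scene, beam)

    if not beam.blanked:
        if beam.mode in ("imaging", "search"):
            radius = (
                scene.imaging_beam_radius_px
                if scene.imaging_beam_radius_px is not None
                else float(max(shape)) # effectively full-field illumination
            )
            disc = _disc_mask(shape, bc, radius)
            illum = np.where(disc, scene.illum_rate * exposure, 0.0)
            # crystals absorb: multiplicative dark Gaussian blobs
            rows, cols = shape
            v = np.arange(rows)[:, None]
            u = np.arange(cols)[None, :]
            for c, (pu, pv) in zip(scene.crystals, positions):
                sigma = max(2.0, c.size / 1000.0 * scene.pixel_scale)
                r2 = (u - pu) ** 2 + (v - pv) ** 2
                illum *= 1.0 - 0.85 * np.exp(-r2 / (2.0 * sigma * sigma))
            mean += illum
        else:  # diffraction
            amp = scene.illum_rate * exposure * 5.0
            _gaussian_spot(mean, bc, 3.0, amp)
            for c, (pu, pv) in zip(scene.crystals, positions):
                if (pu - bc[0]) ** 2 + (pv - bc[1]) ** 2 <= scene.beam_radius_px**2:
                    _add_spot_lattice(mean, scene, amp)

    pixels = rng.poisson(mean).astype(float)
    pixels *= scene.gain_map
    for r, c in scene.dead_pixels:
        pixels[r, c] = 0
    frame = DetectorFrame(
        pixels=np.clip(np.rint(pixels), 0, 65535).astype(np.uint16),
        exposure=exposure,
        timestamp=timestamp,
        stage_alpha_at_exposure=stage.alpha,
    )
    return frame


def _add_spot_lattice(mean: np.ndarray, scene: VirtualScene, beam_amp: float) -> None:
    """Synthetic reflection lattice around the central beam (diffraction mode)."""
    u0, v0 = scene.center
    spacing = 42.0
    for hh in range(-3, 4):
        for kk in range(-3, 4):
            if hh == 0 and kk == 0:
                continue
            g = math.hypot(hh, kk)
            _gaussian_spot(
                mean,
                (u0 + spacing * hh, v0 + spacing * kk),
                1.8,
                beam_amp * 0.25 * math.exp(-0.35 * g),
            )


def advance_rotation(stage: StageState, dt: float) -> StageState:
    """Advance a rotating stage by ``dt`` seconds, clamping at the target.

    Returns a new state; the ``moving`` flag is cleared on arrival.
    """
    if not stage.moving or dt <= 0:
        return replace(stage)
    direction = 1.0 if stage.target_alpha >= stage.alpha else -1.0
    alpha = stage.alpha + direction * stage.rotation_speed * dt
    if (alpha - stage.target_alpha) * direction >= 0:
        return replace(stage, alpha=stage.target_alpha, moving=False)
    return replace(stage, alpha=alpha)


class VirtualMicroscope:
    """Stateful facade bundling scene, stage, beam and a simulated clock.

    This is the "scope" object the acquisition procedures drive.  All
    randomness (Poisson counts, jitter) flows from the scene seed, so two
    microscopes built from the same scene reproduce each other exactly.
    """

    def __init__(self, scene: VirtualScene, *, alpha_limit: float = 70.0):
        self.scene = scene
        self.stage = StageState(alpha_limit=alpha_limit)
        self.beam = BeamState()
        self.time_s = 0.0
        self.rng = np.random.default_rng(scene.gonio.seed)
        self.camera_length: float = 1000.0  # mm
        self.blanked_time_s = 0.0

    # --- stage ----------------------------------------------------------
    def move_stage(
        self,
        *,
        x: float | None = None,
        y: float | None = None,
        z: float | None = None,
        alpha: float | None = None,
    ) -> None:
        if self.stage.moving:
            raise RuntimeError("cannot reposition stage while rotating")
        if x is not None:
            self.stage.x = x
        if y is not None:
            self.stage.y = y
        if z is not None:
            self.stage.z = z
        if alpha is not None:
            if abs(alpha) > self.stage.alpha_limit + 1e-9:
                raise ValueError(
                    f"alpha {alpha}° outside ±{self.stage.alpha_limit}° stage limit"
                )
            self.stage.alpha = alpha

    def start_rotation(self, target_alpha: float, speed: float) -> None:
        if speed <= 0:
            raise ValueError("rotation speed must be > 0")
        limit = self.stage.alpha_limit
        self.stage.target_alpha = float(np.clip(target_alpha, -limit, limit))
        self.stage.rotation_speed = speed
        self.stage.moving = True

    def wait(self, dt: float) -> None:
        """Let ``dt`` seconds of simulated time pass (stage keeps rotating)."""
        if dt < 0:
            raise ValueError("dt must be >= 0")
        if self.beam.blanked:
            self.blanked_time_s += dt
        self.stage = advance_rotation(self.stage, dt)
        self.time_s += dt

    # --- beam -----------------------------------------------------------
    def set_deflectors(self, ix: float, iy: float) -> None:
        self.beam.deflector_x = ix
        self.beam.deflector_y = iy

    def blank(self, blanked: bool = True) -> None:
        self.beam.blanked = blanked

    def set_mode(self, mode: str) -> None:
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        self.beam.mode = mode

    def beam_center(self) -> tuple[float, float]:
        return beam_center_pixel(self.scene, self.beam)

    # --- acquisition ----------------------------------------------------
    def acquire_frame(self, exposure_ms: float) -> DetectorFrame:
        """Acquire one frame; the stage keeps rotating during the exposure.

        The frame is tagged with the stage alpha at the exposure midpoint.
        """
        if exposure_ms <= 0:
            raise ValueError("exposure must be > 0 ms")
        half = exposure_ms / 2000.0
        self.stage = advance_rotation(self.stage, half)
        mid_stage = replace(self.stage)
        frame = render_frame(
            self.scene,
            mid_stage,
            self.beam,
            exposure_ms,
            rng=self.rng,
            timestamp=self.time_s + half,
        )
        self.stage = advance_rotation(self.stage, half)
        self.time_s += exposure_ms / 1000.0
        return frame

    def crystal_pixel(self, index: int = 0, *, alpha: float | None = None) -> tuple[float, float]:
        """Ground-truth projected position of crystal ``index`` (no jitter)."""
        c = self.scene.crystals[index]
        h = self.stage.z - self.scene.gonio.z_euc_true
        return project_feature(
            (c.x, c.y), h, self.stage.alpha if alpha is None else alpha, self.scene
        )


# --- scene config I/O ----------------------------------------------------

def save_scene(scene: VirtualScene, path) -> None:
    """Write a scene config as YAML.  Gain maps are written as sidecar TIFF."""
    doc: dict = {
        "detector_shape": list(scene.detector_shape),
        "pixel_scale": scene.pixel_scale,
        "beam_radius_px": scene.beam_radius_px,
        "imaging_beam_radius_px": scene.imaging_beam_radius_px,
        "beam_response": np.asarray(scene.beam_response).tolist(),
        "illum_rate": scene.illum_rate,
        "floor_rate": scene.floor_rate,
        "crystals": [{"x": c.x, "y": c.y, "size": c.size} for c in scene.crystals],
        "gonio": {
            "z_euc_true": scene.gonio.z_euc_true,
            "tilt_axis_angle": scene.gonio.tilt_axis_angle,
            "runout_amplitude": scene.gonio.runout_amplitude,
            "runout_phase": scene.gonio.runout_phase,
            "jitter_sigma": scene.gonio.jitter_sigma,
            "seed": scene.gonio.seed,
        },
        "dead_pixels": [list(p) for p in sorted(scene.dead_pixels)],
    }
    path = str(path)
    if not np.all(scene.gain_map == 1.0):
        gain_path = path + ".gain.tif"
        tifffile.imwrite(gain_path, scene.gain_map.astype(np.float32))
        doc["gain_map_file"] = gain_path
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_scene(path) -> VirtualScene:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    gain = None
    if "gain_map_file" in doc:
        gain = tifffile.imread(doc["gain_map_file"]).astype(float)
    return VirtualScene(
        crystals=[Crystal(**c) for c in doc.get("crystals", [])],
        gonio=GonioModel(**doc.get("gonio", {})),
        pixel_scale=doc.get("pixel_scale", 10.0),
        detector_shape=tuple(doc.get("detector_shape", (512, 512))),
        gain_map=gain,
        dead_pixels=frozenset(tuple(p) for p in doc.get("dead_pixels", [])),
        beam_radius_px=doc.get("beam_radius_px", 12.0),
        imaging_beam_radius_px=doc.get("imaging_beam_radius_px"),
        beam_response=np.array(doc.get("beam_response", [[180.0, 12.0], [-8.0, -150.0]])),
        illum_rate=doc.get("illum_rate", 2.0),
        floor_rate=doc.get("floor_rate", 0.01),
    )
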