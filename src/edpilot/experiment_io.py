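"""Presets, dataset bookkeeping, metadata and processing-input generation.

This module owns everything that outlives a single acquisition: the stored
search/imaging/diffraction optical presets, the hierarchical dataset layout
(``Operator/Sample/Date/CrystalNumber``), the metadata sidecar embedded
with every frame stack, same-day persistence of the GUI-level parameters,
and the auto-generated input files for the three diffraction-processing
packages (XDS, PETS2, DIALS).

Every shared quantity — wavelength, oscillation per frame, frame count,
camera length — is drawn from one AcquisitionMetadata instance, so the
three writers can never disagree.
"""

from __future__ import annotations

import datetime as _dt
import json
import os
import re
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import numpy as np
import tifffile

from . import xtal_math
from .virtual_microscope import DetectorFrame, MODES

__all__ = [
    "OpticalPreset",
    "PresetStore",
    "AcquisitionMetadata",
    "DatasetPath",
    "DetectorGeometry",
    "next_dataset_path",
    "persist_settings",
    "restore_settings",
    "write_frames",
    "read_metadata_sidecar",
    "write_xds_inp",
    "write_pets2",
    "write_dials_import",
]


class ExperimentIOError(RuntimeError):
    pass


@dataclass(frozen=True)
class OpticalPreset:
    """Stored condenser/lens configuration for one operating mode."""

    name: str  # search | imaging | diffraction
    aperture: float  # µm
    convergence_semi_angle: float  # µrad
    camera_length: float = 1000.0  # mm
    beam_size: float = 550.0  # nm
    lens_settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in MODES:
            raise ValueError(f"preset name must be one of {MODES}")


class PresetStore:
    """Named optical presets with optional file persistence.

    Mirrors the store/load button pairs of an acquisition GUI: one preset
    per mode, overwritten on re-store, auto-applied by the operations that
    depend on them (Record loads imaging; Track & Acquire and diffraction
    previews load diffraction).
    """

    def __init__(self, path: str | os.PathLike | None = None):
        self._presets: dict[str, OpticalPreset] = {}
        self._path = Path(path) if path is not None else None
        if self._path is not None and self._path.exists():
            self._load_file()

    def store(self, preset: OpticalPreset) -> None:
        self._presets[preset.name] = preset
        if self._path is not None:
            self._save_file()

    def get(self, name: str) -> OpticalPreset | None:
        return self._presets.get(name)

    def load(self, name: str) -> OpticalPreset:
        preset = self.get(name)
        if preset is None:
            raise ExperimentIOError(f"no stored {name!r} preset")
        return preset

    def apply(self, scope, name: str) -> OpticalPreset:
        """Load a preset and push it onto the microscope."""
        preset = self.load(name)
        scope.set_mode(name)
        scope.beam.aperture = preset.aperture
        scope.beam.convergence_semi_angle = preset.convergence_semi_angle
        scope.camera_length = preset.camera_length
        return preset

    def _save_file(self) -> None:
        doc = {name: asdict(p) for name, p in self._presets.items()}
        self._path.write_text(json.dumps(doc, indent=1))

    def _load_file(self) -> None:
        doc = json.loads(self._path.read_text())
        for name, p in doc.items():
            self._presets[name] = OpticalPreset(**p)


@dataclass
class AcquisitionMetadata:
    """Full parameter record of one 3D-ED run, embedded in every output."""

    voltage: float  # kV
    wavelength: float  # Å
    tilt_start: float  # deg
    tilt_end: float  # deg
    rotation_speed: float  # deg/s
    exposure: float  # ms
    n_frames: int
    frame_overhead: float = 21.0  # ms
    aperture: float = 19.0  # µm
    beam_size: float = 550.0  # nm
    convergence_semi_angle: float = 40.0  # µrad
    fluence: float = 0.6  # e⁻/Å²
    mode: str = "cRED"  # or PEDT
    camera_length: float = 1000.0  # mm
    operator: str = ""
    sample: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.mode not in ("cRED", "PEDT"):
            raise ValueError("mode must be 'cRED' or 'PEDT'")
        lam = xtal_math.electron_wavelength(self.voltage)
        if abs(lam - self.wavelength) > 5e-4:
            raise ValueError(
                f"wavelength {self.wavelength} Å inconsistent with {self.voltage} kV"
            )

    @classmethod
    def from_acquisition(
        cls, *, voltage: float, tilt_start: float, tilt_end: float,
        rotation_speed: float, exposure: float, n_frames: int, **extra,
    ) -> "AcquisitionMetadata":
        return cls(
            voltage=voltage,
            wavelength=round(xtal_math.electron_wavelength(voltage), 4),
            tilt_start=tilt_start,
            tilt_end=tilt_end,
            rotation_speed=rotation_speed,
            exposure=exposure,
            n_frames=n_frames,
            **extra,
        )

    @property
    def tilt_range(self) -> float:
        return abs(self.tilt_end - self.tilt_start)

    @property
    def oscillation(self) -> float:
        """Tilt per frame at full precision (integrates over detector dead
        time: range/frames, not speed×exposure)."""
        return xtal_math.oscillation_per_frame(self.tilt_range, self.n_frames)

    @property
    def total_time_s(self) -> float:
        return self.n_frames * (self.exposure + self.frame_overhead) / 1000.0

    # --- sidecar (human-readable, round-trippable) ----------------------
    def to_sidecar_text(self) -> str:
        lines = ["# edpilot acquisition metadata"]
        for f in fields(self):
            lines.append(f"{f.name}: {getattr(self, f.name)!r}")
        lines.append(f"tilt_range: {self.tilt_range!r}")
        lines.append(f"oscillation_deg_per_frame: {self.oscillation!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_sidecar_text(cls, text: str) -> "AcquisitionMetadata":
        import ast

        kv = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition(":")
            kv[key.strip()] = ast.literal_eval(val.strip())
        names = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in kv.items() if k in names})


@dataclass(frozen=True)
class DatasetPath:
    root: Path
    operator: str
    sample: str
    date: str  # ISO yyyy-mm-dd
    crystal_number: int

    @property
    def path(self) -> Path:
        return self.root / self.operator / self.sample / self.date / str(self.crystal_number)


def next_dataset_path(
    root: str | os.PathLike, operator: str, sample: str, date: str | None = None
) -> DatasetPath:
    """Create the next ``Operator/Sample/Date/CrystalNumber`` directory.

    CrystalNumber is max(existing)+1 (gaps are never reused); creation is
    atomic, retrying on a concurrent-creation collision.
    """
    root = Path(root)
    if date is None:
        date = _dt.date.today().isoformat()
    parent = root / operator / sample / date
    parent.mkdir(parents=True, exist_ok=True)
    while True:
        existing = [int(p.name) for p in parent.iterdir() if p.name.isdigit()]
        number = max(existing, default=0) + 1
        try:
            (parent / str(number)).mkdir()  # atomic; fails if raced
        except FileExistsError:
            continue
        return DatasetPath(
            root=root, operator=operator, sample=sample, date=date, crystal_number=number
        )


# --- same-day settings persistence --------------------------------------

def persist_settings(path: str | os.PathLike, settings: dict, date: str | None = None) -> None:
    """Save all GUI-level parameters with the save date."""
    doc = {"saved_on": date or _dt.date.today().isoformat(), "settings": settings}
    Path(path).write_text(json.dumps(doc, indent=1))


def restore_settings(
    path: str | os.PathLike, defaults: dict, today: str | None = None
) -> tuple[dict, str | None]:
    """Reload saved parameters, but only if they were saved today.

    Returns (settings, notice).  ``notice`` is None on a clean same-day
    restore; otherwise it explains why defaults were returned (stale file,
    missing file, corrupt file).  Never raises on a bad file.
    """
    today = today or _dt.date.today().isoformat()
    path = Path(path)
    if not path.exists():
        return dict(defaults), "no saved settings; using defaults"
    try:
        doc = json.loads(path.read_text())
        saved_on = doc["saved_on"]
        settings = doc["settings"]
        if not isinstance(settings, dict):
            raise ValueError("settings block is not a mapping")
    except Exception as exc:  # corrupt file must never crash a session
        return dict(defaults), f"settings file unreadable ({exc}); using defaults"
    if saved_on != today:
        return dict(defaults), f"settings saved on {saved_on}, not today; using defaults"
    return settings, None


# --- frame stack output --------------------------------------------------

FRAME_TEMPLATE = "frame_{:05d}.tif"


def write_frames(
    frames: list[DetectorFrame],
    metadata: AcquisitionMetadata,
    path: str | os.PathLike,
    trajectory=None,
) -> list[Path]:
    """Write numbered 16-bit TIFFs (1-based, zero-padded) plus the metadata
    sidecar and, when given, the tracking trajectory file."""
    if not frames:
        raise ExperimentIOError("empty frame stack")
    shapes = {f.pixels.shape for f in frames}
    if len(shapes) != 1:
        raise ExperimentIOError(f"inconsistent frame shapes in stack: {shapes}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for i, frame in enumerate(frames, start=1):
        fp = path / FRAME_TEMPLATE.format(i)
        tifffile.imwrite(
            fp,
            frame.pixels.astype(np.uint16),
            metadata={
                "exposure_ms": frame.exposure,
                "alpha_deg": frame.stage_alpha_at_exposure,
            },
        )
        written.append(fp)
    (path / "metadata.txt").write_text(metadata.to_sidecar_text())
    if trajectory is not None:
        from .tracking import save_trajectory

        save_trajectory(trajectory, path / "trajectory.json")
    return written


def read_metadata_sidecar(path: str | os.PathLike) -> AcquisitionMetadata:
    return AcquisitionMetadata.from_sidecar_text(Path(path).read_text())


# --- processing-input writers -------------------------------------------

@dataclass(frozen=True)
class DetectorGeometry:
    nx: int = 512
    ny: int = 512
    qx: float = 0.055  # mm pixel pitch
    qy: float = 0.055
    orgx: float = 255.5  # beam centre, px
    orgy: float = 255.5
    rotation_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)

    def validate(self) -> None:
        missing = [k for k in ("nx", "ny", "qx", "qy") if not getattr(self, k)]
        if missing:
            raise ExperimentIOError(f"detector geometry missing fields: {missing}")


def _rotation_axis_for(metadata: AcquisitionMetadata, geometry: DetectorGeometry):
    """Oscillation is written positive; a downhill scan flips the axis."""
    axis = geometry.rotation_axis
    if metadata.tilt_end < metadata.tilt_start:
        axis = tuple(-a for a in axis)
    return axis


def write_xds_inp(
    metadata: AcquisitionMetadata,
    geometry: DetectorGeometry,
    path: str | os.PathLike | None = None,
    frame_template: str = "frame_?????.tif",
) -> str:
    """Generate an XDS.INP for the frame stack.

    OSCILLATION_RANGE is the unrounded tilt_range / n_frames — the quantity
    the acquisition tables print rounded to 2 dp.
    """
    geometry.validate()
    if metadata.n_frames < 1:
        raise ExperimentIOError("n_frames must be >= 1")
    axis = _rotation_axis_for(metadata, geometry)
    lines = [
        "! XDS.INP generated by edpilot",
        "JOB= XYCORR INIT COLSPOT IDXREF DEFPIX INTEGRATE CORRECT",
        f"NAME_TEMPLATE_OF_DATA_FRAMES= {frame_template}",
        f"DATA_RANGE= 1 {metadata.n_frames}",
        f"SPOT_RANGE= 1 {metadata.n_frames}",
        f"STARTING_ANGLE= {metadata.tilt_start}",
        f"OSCILLATION_RANGE= {metadata.oscillation!r}",
        f"X-RAY_WAVELENGTH= {metadata.wavelength}",
        f"DETECTOR_DISTANCE= {metadata.camera_length}",
        f"ORGX= {geometry.orgx}  ORGY= {geometry.orgy}",
        f"NX= {geometry.nx}  NY= {geometry.ny}  QX= {geometry.qx}  QY= {geometry.qy}",
        f"ROTATION_AXIS= {axis[0]} {axis[1]} {axis[2]}",
        "DETECTOR= PILATUS  MINIMUM_VALID_PIXEL_VALUE= 0  OVERLOAD= 65000",
        "TRUSTED_REGION= 0.0 1.4142",
    ]
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def parse_keyword_file(text: str) -> dict[str, str]:
    """Parse a ``KEY= value`` file (XDS dialect) into a dict; later keys win."""
    out: dict[str, str] = {}
    for line in text.splitlines():
        line = line.split("!")[0]
        for m in re.finditer(r"([A-Z_()'\-\.]+=\s*[^=]*?)(?=\s+[A-Z_()'\-\.]+=|$)", line):
            key, _, val = m.group(1).partition("=")
            out[key.strip()] = val.strip()
    return out


def write_pets2(
    metadata: AcquisitionMetadata,
    frame_filenames: list[str],
    path: str | os.PathLike | None = None,
    *,
    noise_parameters: tuple[float, float] = (1.0, 2.0),
) -> str:
    """Generate a PETS2 .pts input: header keywords plus the imagelist block
    pairing each frame with its tilt angle (spaced by the oscillation)."""
    if not frame_filenames:
        raise ExperimentIOError("empty frame list")
    if len(frame_filenames) != metadata.n_frames:
        raise ExperimentIOError(
            f"{len(frame_filenames)} filenames for {metadata.n_frames} frames"
        )
    direction = 1.0 if metadata.tilt_end >= metadata.tilt_start else -1.0
    osc = metadata.oscillation
    # angle at the centre of frame i's oscillation interval
    angles = [
        metadata.tilt_start + direction * (i + 0.5) * osc
        for i in range(metadata.n_frames)
    ]
    lines = [
        "# PETS2 input generated by edpilot",
        f"lambda {metadata.wavelength}",
        f"Aperpixel {0.055 / metadata.camera_length:.6g}",
        "phi 0.0",
        "omega 0.0",
        f"noiseparameters {noise_parameters[0]} {noise_parameters[1]}",
        "imagelist",
    ]
    for fn, ang in zip(frame_filenames, angles):
        lines.append(f"{fn} {ang!r} 0.0")
    lines.append("endimagelist")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def write_dials_import(
    metadata: AcquisitionMetadata,
    geometry: DetectorGeometry,
    path: str | os.PathLike | None = None,
    frame_template: str = "frame_#####.tif",
) -> str:
    """Generate a dials.import parameter file for the stack.

    The oscillation width is the same full-precision value the XDS writer
    emits (single source of truth: the metadata instance).
    """
    geometry.validate()
    if not geometry.orgx or not geometry.orgy:
        raise ExperimentIOError("beam centre (orgx/orgy) required")
    axis = _rotation_axis_for(metadata, geometry)
    lines = [
        "# dials.import parameters generated by edpilot",
        f"input.template={frame_template}",
        f"geometry.scan.oscillation={metadata.tilt_start},{metadata.oscillation!r}",
        f"geometry.scan.image_range=1,{metadata.n_frames}",
        f"geometry.beam.wavelength={metadata.wavelength}",
        f"geometry.detector.distance={metadata.camera_length}",
        f"geometry.detector.pixel_size={geometry.qx},{geometry.qy}",
        f"geometry.detector.beam_centre={geometry.orgx * geometry.qx},"
        f"{geometry.orgy * geometry.qy}",
        f"geometry.goniometer.axis={axis[0]},{axis[1]},{axis[2]}",
    ]
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
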