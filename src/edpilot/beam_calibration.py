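"""Beam-shift calibration: deflector currents ↔ detector pixels.

Three parallel-beam images — a reference, one shifted by +Δ on the x
deflector, one shifted by +Δ on the y deflector — define a 2×2 linear map
``M`` (pixels per current unit).  Inverting ``M`` turns any target pixel
into the deflector deltas that steer the beam there, which is what makes
click-to-position steering and trajectory replay possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .virtual_microscope import DetectorFrame

__all__ = [
    "CalibrationConfig",
    "CalibrationMatrix",
    "measure_beam_center",
    "calibrate",
    "calibrate_on_scope",
    "pixel_to_currents",
    "save_calibration",
    "load_calibration",
]


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class CalibrationConfig:
    """Settings for a calibration run.

    ``delta`` is the current step applied per axis (the GUI "Delta" value);
    ``detection`` selects automatic centroiding or externally supplied marks.
    """

    delta: float = 0.1
    detection: str = "auto-centroid"  # or "manual-marks"
    threshold_fraction: float = 0.5
    collinearity_tolerance: float = 1e-3  # on |det| / (|col1|·|col2|)

    def __post_init__(self) -> None:
        if self.delta == 0:
            raise ValueError("delta must be nonzero")
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ValueError("threshold_fraction must be in (0, 1)")
        if self.detection not in ("auto-centroid", "manual-marks"):
            raise ValueError("detection must be 'auto-centroid' or 'manual-marks'")


@dataclass
class CalibrationMatrix:
    """2×2 map from deflector-current deltas to detector-pixel shifts."""

    M: np.ndarray  # px per current unit, columns = response to x̂, ŷ steps
    ref_currents: tuple[float, float]
    ref_pixel: tuple[float, float]
    condition_number: float = field(init=False)
    mode: str = "imaging"

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float).reshape(2, 2)
        if abs(np.linalg.det(self.M)) == 0:
            raise CalibrationError("degenerate calibration: det(M) = 0")
        self.condition_number = float(np.linalg.cond(self.M))


def measure_beam_center(
    frame: DetectorFrame | np.ndarray, threshold_fraction: float = 0.5
) -> tuple[float, float]:
    """Locate the beam as the intensity-weighted centroid of the largest
    connected component above ``threshold_fraction × max``.

    Component size is pixel count; ties go to the component with the larger
    total intensity (robust against dead-pixel speckle and stray spots).
    Returns (u, v) = (col, row).  Raises if nothing exceeds the threshold.
    """
    pixels = frame.pixels if isinstance(frame, DetectorFrame) else np.asarray(frame)
    peak = float(pixels.max(initial=0))
    if peak <= 0:
        raise CalibrationError("no beam detected: frame is empty")
    mask = pixels >= threshold_fraction * peak
    labels, n = ndimage.label(mask)
    if n == 0:
        raise CalibrationError("no beam detected: nothing above threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    sums = ndimage.sum_labels(pixels.astype(float), labels, index=range(1, n + 1))
    # sort by (size, total intensity); argmax over lexicographic key
    best = max(range(n), key=lambda i: (sizes[i], sums[i]))
    component = labels == best + 1
    weights = np.where(component, pixels.astype(float), 0.0)
    vc, uc = ndimage.center_of_mass(weights)
    return (float(uc), float(vc))


def calibrate(
    ref_frame,
    shifted_x_frame,
    shifted_y_frame,
    config: CalibrationConfig = CalibrationConfig(),
    *,
    ref_currents: tuple[float, float] = (0.0, 0.0),
    marks: list[tuple[float, float]] | None = None,
    mode: str = "imaging",
) -> CalibrationMatrix:
    """Build a CalibrationMatrix from the three calibration images.

    The frames must have been acquired at currents ``(i)``, ``(i + Δ·x̂)``
    and ``(i + Δ·ŷ)``.  In manual-marks mode, ``marks`` supplies the three
    (u, v) beam positions instead of automatic centroiding.
    """
    if config.detection == "manual-marks":
        if marks is None or len(marks) != 3:
            raise CalibrationError("manual-marks detection requires exactly 3 (u, v) marks")
        centers = [np.asarray(m, dtype=float) for m in marks]
    else:
        centers = [
            np.asarray(measure_beam_center(f, config.threshold_fraction))
            for f in (ref_frame, shifted_x_frame, shifted_y_frame)
        ]
    c_ref, c_x, c_y = centers
    col1 = (c_x - c_ref) / config.delta
    col2 = (c_y - c_ref) / config.delta
    n1, n2 = np.linalg.norm(col1), np.linalg.norm(col2)
    det = col1[0] * col2[1] - col1[1] * col2[0]
    if n1 == 0 or n2 == 0 or abs(det) / (n1 * n2) < config.collinearity_tolerance:
        raise CalibrationError("degenerate calibration: shift vectors are collinear")
    return CalibrationMatrix(
        M=np.column_stack([col1, col2]),
        ref_currents=tuple(ref_currents),
        ref_pixel=(float(c_ref[0]), float(c_ref[1])),
        mode=mode,
    )


def calibrate_on_scope(scope, config: CalibrationConfig = CalibrationConfig()) -> CalibrationMatrix:
    """Run the three-image calibration sequence on a (virtual) microscope."""
    i0 = (scope.beam.deflector_x, scope.beam.deflector_y)
    frames = []
    for di, dj in ((0.0, 0.0), (config.delta, 0.0), (0.0, config.delta)):
        scope.set_deflectors(i0[0] + di, i0[1] + dj)
        frames.append(scope.acquire_frame(100.0))
    scope.set_deflectors(*i0)
    return calibrate(*frames, config, ref_currents=i0, mode=scope.beam.mode)


def pixel_to_currents(
    target_pixel: tuple[float, float], calib: CalibrationMatrix
) -> tuple[float, float]:
    """Deflector-current deltas that move the beam from the calibration
    reference pixel to ``target_pixel``:  M⁻¹ · (target − ref_pixel)."""
    if calib.condition_number > 1e8:
        raise CalibrationError("calibration matrix is numerically degenerate")
    rhs = np.asarray(target_pixel, dtype=float) - np.asarray(calib.ref_pixel)
    delta = np.linalg.solve(calib.M, rhs)
    return (float(delta[0]), float(delta[1]))


def save_calibration(calib: CalibrationMatrix, path) -> None:
    """Persist as a small key = value text file."""
    with open(path, "w") as fh:
        fh.write("# edpilot beam-shift calibration\n")
        fh.write(f"mode = {calib.mode}\n")
        fh.write(f"m11 = {float(calib.M[0, 0])!r}\nm12 = {float(calib.M[0, 1])!r}\n")
        fh.write(f"m21 = {float(calib.M[1, 0])!r}\nm22 = {float(calib.M[1, 1])!r}\n")
        fh.write(f"ref_current_x = {float(calib.ref_currents[0])!r}\n")
        fh.write(f"ref_current_y = {float(calib.ref_currents[1])!r}\n")
        fh.write(f"ref_pixel_u = {float(calib.ref_pixel[0])!r}\n")
        fh.write(f"ref_pixel_v = {float(calib.ref_pixel[1])!r}\n")


def load_calibration(path) -> CalibrationMatrix:
    kv: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
    return CalibrationMatrix(
        M=np.array(
            [
                [float(kv["m11"]), float(kv["m12"])],
                [float(kv["m21"]), float(kv["m22"])],
            ]
        ),
        ref_currents=(float(kv["ref_current_x"]), float(kv["ref_current_y"])),
        ref_pixel=(float(kv["ref_pixel_u"]), float(kv["ref_pixel_v"])),
        mode=kv.get("mode", "imaging"),
    )
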