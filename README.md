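# edpilot

Hardware-free automation algorithms for 3D electron diffraction (3D-ED /
microED) data acquisition, exercised against a built-in virtual microscope.

3D-ED determines crystal structures from nanocrystals far too small for
single-crystal X-ray work: a transmission electron microscope rotates the
specimen continuously (cRED) or stepwise with beam precession (PEDT) while a
hybrid-pixel detector records diffraction frames. The hard part is not the
optics but the control logic — keeping a 100 nm crystal inside a sub-µm beam
while the goniometer sweeps 120°, locating the eucentric height, turning
deflector currents into detector pixels, and emitting correct processing
inputs afterwards. `edpilot` implements that control logic as a pure-Python
library + CLI, with a simulator (`virtual_microscope`) providing ground
truth so every closed loop is testable on a desk.

## What is implemented

- **`xtal_math`** — closed-form acquisition arithmetic: relativistic
  electron wavelength λ = h/√(2m₀eV(1 + eV/2m₀c²)), triclinic cell volume
  V = abc·√(1 − cos²α − cos²β − cos²γ + 2cosα cosβ cosγ), oscillation per
  frame Δφ = tilt range / n frames, resolution-ring radius r = Lλ/(d·p),
  formula weights.
- **`virtual_microscope`** — stage/beam/detector simulator with an exactly
  linear beam response, reproducible sinusoidal goniometer runout, seeded
  jitter, gain map and dead pixels; frames as 16-bit TIFF.
- **`beam_calibration`** — three-image calibration of the 2×2 map **M**
  (pixels per deflector-current unit) and its inversion for
  click-to-position beam steering.
- **`eucentric`** — the two-tilt/two-height linear regression
  Δd(z) = m·z + c, z_euc = −c/m, plus the automated closed loop using
  normalized-cross-correlation feature tracking.
- **`tracking`** — record-then-replay crystal tracking: record a low-dose
  tilt series, mark the crystal, interpolate (piecewise linear or natural
  cubic spline in tilt angle), then steer the beam along the trajectory
  during continuous-rotation or stepwise-precession acquisition. One
  recording serves many crystals and many replays.
- **`detector_service`** — TCP client/server acquisition split with a
  documented length-prefixed JSON+binary wire format; flat-field and
  dead-pixel correction; peak finding; multi-position diffraction preview.
- **`experiment_io`** — optical presets, `Operator/Sample/Date/CrystalNumber`
  dataset folders, metadata sidecars, same-day settings persistence, and
  XDS.INP / PETS2 `.pts` / DIALS import generation from a single metadata
  record.

## Worked example

```bash
$ edpilot calc wavelength --kv 120
0.0335
$ edpilot calc volume --cell 8.871,13.045,13.150,65.67,70.86,81.57
1309.8
$ edpilot calc oscillation --tilt-range 121 --frames 116
1.04
```

0.0335 Å is the electron wavelength at a 120 kV accelerating voltage;
1309.8 Å³ is the volume of the triclinic cell with the quoted parameters;
1.04° is the reciprocal-space wedge each detector frame integrates when
121° of rotation is divided over 116 frames.

A full simulated tracking run:

```python
from edpilot.virtual_microscope import VirtualScene, VirtualMicroscope, Crystal, GonioModel
from edpilot.beam_calibration import calibrate_on_scope
from edpilot.tracking import (RecordConfig, AcquireConfig,
                              record_trajectory_images, build_trajectory,
                              track_and_acquire)

scene = VirtualScene(crystals=[Crystal(1.0, 0.5, 300)],
                     gonio=GonioModel(z_euc_true=-25, runout_amplitude=1.5, seed=7))
scope = VirtualMicroscope(scene)
scope.move_stage(z=5.0)                       # deliberately off-eucentric
calib = calibrate_on_scope(scope)
run = record_trajectory_images(scope, RecordConfig(-60, 60, image_interval=2.0))
marks = [(a, *scope.crystal_pixel(0, alpha=a)) for a, _ in run.images]
traj = build_trajectory(marks, "spline")
lo, hi = traj.alpha_range
frames, log = track_and_acquire(scope, traj, calib,
                                AcquireConfig(alpha_start=lo, alpha_end=hi))
print(len(frames), max(e.beam_crystal_distance for e in log))
```

prints `115 0.453...`: 115 diffraction frames over the sweep with the beam
never more than half a pixel from the crystal, against a 12 px beam radius.

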