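# Methods

## The simulator's geometric model

All acquisition algorithms are validated against a virtual microscope whose
ground truth is deliberately minimal: a rigid, flat specimen under
orthographic projection, with the goniometer tilt axis along the detector
v (row) axis by default. A feature at in-plane offset (x, y) µm from the
tilt axis and height offset h = z_stage − z_euc projects to

    u = s·(x·cosα + h·sinα) + u₀ + s·runout(α) + s·jitter
    v = s·y + v₀

with pixel scale s (default 10 px/µm) and detector centre (u₀, v₀). Pixel
convention: origin top-left, u = column, v = row, 0-based, positions at
pixel centres. An optional in-plane rotation of the tilt axis is applied
after projection.

Goniometer error is split into the two components that matter for
record-then-replay tracking: **runout**, a deterministic sinusoid
A·sin(α + φ) of the tilt angle (reproducible on every rotation cycle —
the property the tracking scheme depends on), and **jitter**, zero-mean
Gaussian noise drawn once per exposure from the scene seed (the
non-reproducible remainder). If goniometer error were dominated by jitter
rather than runout, recorded trajectories would not replay; the simulator
makes that failure mode reproducible too by raising `jitter_sigma`.

The detector model: beam centre = detector centre + **R**·(i_x, i_y) with a
fixed 2×2 response matrix **R** per scene, exactly linear in the deflector
currents, so beam-shift calibration has an exact right answer. Frames are
Poisson counts of a mean image (illuminated disc with absorbing crystal
blobs in imaging mode; central beam plus a synthetic reflection lattice
when a crystal sits inside the beam disc in diffraction mode), multiplied
by a per-pixel gain map, with dead pixels forced to zero. Defaults follow
a Timepix-quad-class detector: 512×512 pixels, 55 µm pitch; both are scene
parameters, not constants.

What the simulator does **not** emulate: lens optics and aberrations,
dynamical diffraction, beam damage, focus/astigmatism drift, stage
backlash, detector nonlinearity beyond the static gain map. Passing tests
therefore demonstrate the correctness of the control *logic* under the
stated error model, not robustness to every failure mode of a physical
column.

## Beam-shift calibration

Three beam images — reference, +Δ on the x deflector, +Δ on the y
deflector (Δ defaults to 0.1 current units) — give the two columns of
**M** = (pixel shift)/Δ. Beam centres are the intensity-weighted centroid
of the largest connected component above 0.5×max (ties broken by total
intensity; robust to dead-pixel speckle). Click-to-position steering solves
**M**·δi = target − ref_pixel. A calibration is rejected as degenerate when
the normalized determinant |det|/(‖c₁‖‖c₂‖) falls below 10⁻³ (collinear
shifts). One matrix is stored per optical mode. The calibration beam disc
must lie fully on the detector: a clipped disc biases its centroid, which
is a physical limitation of centroiding, not of the linear model.

## Eucentric height

Displacements d are read along the direction perpendicular to the tilt
axis (u in the canonical geometry); motion along the axis carries no height
information. With readings at two tilts (α₁, α₂) and two heights (z₁, z₂):

    Δd(z) = d(α₂, z) − d(α₁, z),   m = [Δd(z₂) − Δd(z₁)]/(z₂ − z₁),
    c = Δd(z₁) − m·z₁,             z_euc = −c/m.

Under the projection model Δd(z) = s·(z − z_euc)(sinα₂ − sinα₁) +
s·x·(cosα₂ − cosα₁). The slope is independent of the feature's in-plane
offset x, but the intercept is not: an off-axis feature biases z_euc by
−x·(cosα₂ − cosα₁)/(sinα₂ − sinα₁), which vanishes for symmetric tilt
pairs |α₁| = |α₂|. The default design (−10°, +10°) is symmetric for
exactly this reason. |m| < 10⁻⁹ px/µm is rejected as "no height
sensitivity".

The automated loop images the four (tilt, height) states, tracks a feature
by normalized cross-correlation against a template cut from the first
image (sub-pixel peak via a parabolic fit; all four readings share the
same sub-pixel convention so any constant template offset cancels in Δd),
then moves the stage to z_euc. Feature seeding defaults to the darkest
smoothed spot strictly inside the illuminated disc (the mask is eroded by
10 px so the intensity ramp at the disc edge cannot masquerade as a dark
feature).

## Record-then-replay tracking

Record: load the imaging preset, rotate start→end at the recording speed,
snapshot every `image_interval` seconds (count = span/(speed·interval)+1),
tag each frame with the stage angle at the exposure midpoint, then drive
the stage back to the start. With `blank_between` the beam is blanked at
all times except the exposures, including the return leg.

Marks (α, u, v) become a trajectory: duplicate-α marks are averaged,
anchors sorted, interpolation either piecewise-linear or a natural cubic
spline in α (u and v fitted independently). Evaluation outside the anchor
range raises — no silent extrapolation.

Track & Acquire: load the diffraction preset, rotate at `rotation_speed`
and, once per frame, steer the beam to the trajectory evaluated at the
*predicted* exposure-midpoint angle α_now + speed·exposure/2000. One
update per frame is the coarsest faithful cadence; the per-frame angular
footprint is speed·(exposure + overhead). Frame count in continuous mode
is floor(sweep / (speed·(exposure + overhead))). The default per-frame
overhead of 21 ms reproduces the bookkeeping of a 116-frame, 500 ms run
lasting ≈60.4 s; it is a configuration value, not hardware truth.
Stepwise-precession mode pauses at each `step` increment and flags each
frame as precessed; the precession coil physics itself is out of scope and
carried as metadata only.

The per-frame log records commanded beam pixel and (on the simulator) the
true crystal pixel and beam–crystal distance, which is what the replay,
benefit and multi-crystal tests assert on.

## Detector service and corrections

The client/server split mirrors an acquisition setup where the detector
hangs off a second computer. Wire format (an original, documented dialect):
4-byte big-endian payload length, one JSON header line, then an optional
raw little-endian `<u2` pixel payload. Commands: set_exposure,
acquire_single, stream_start/stream_stop (monotone gapless sequence
numbers, one in-flight stream), status. Unknown commands get a structured
error reply and the connection survives.

Corrections run client-side, flat-field first (gain is undefined on dead
pixels): corrected = raw/gain × mean(gain | live), preserving the frame's
mean level; then dead pixels are filled with the median of their non-dead
8-neighbours, iterating so clusters resolve from the outside in. Output
stays uint16; idempotence holds to ±1 count (rounding). Peak finding is
3×3 local maxima above a threshold, greedily pruned to a minimum
separation, strongest first.

## Processing-input writers

XDS.INP, PETS2 `.pts` and the DIALS import file are all generated from one
`AcquisitionMetadata` instance, so shared quantities (wavelength,
oscillation, frame count, distance) are textually identical across files.
Oscillation is written as tilt_range/n_frames at full precision —
integrating over detector dead time — rather than speed×exposure; the
2-dp rounding seen in acquisition tables is presentation only. PETS2 image
list angles are placed at the centre of each frame's oscillation interval.
STARTING_ANGLE = tilt_start; a downhill scan (tilt_end < tilt_start) keeps
the oscillation positive and flips ROTATION_AXIS. Dataset folders follow
`Operator/Sample/Date/CrystalNumber` with ISO dates and max+1 numbering
(gaps never reused); creation is atomic so concurrent sessions cannot
collide. GUI-level settings persist to disk and are restored only if saved
the same calendar day; stale or corrupt files yield defaults with a
notice, never an exception.

## Problem sizes and numerical choices

Closed-loop tests run on the default 512×512 detector. The replay-stability
check performs 12 consecutive Track & Acquire sweeps of ~115 frames each
from a single recording; the tracked-vs-untracked comparison uses a runout
amplitude of 3 beam radii (3.6 µm at 10 px/µm against a 12 px beam disc);
the eucentric Monte Carlo uses 50 seeded runs at 0.2 µm jitter. Angle
tolerances in range checks are 10⁻⁹ deg; the calibration degeneracy
threshold and eucentric slope floor are stated above. Atomic weights come
from gemmi's element tables; physical constants from scipy (CODATA).

## Known limitations

- The linear, orthographic specimen model ignores parallax and beam-tilt
  effects; the faster but coarser beam-tilt eucentric method is not
  implemented.
- Crystal marking is an input (operator clicks or ground truth); automatic
  crystal detection is out of scope, as is defocused-pattern tracking.
- The wire protocol makes no compatibility claim with any vendor dialect.
- Serial-ED scanning acquisition is not implemented.
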