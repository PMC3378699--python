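# Methods

## Scope and data model

`mtpm` implements the analysis side of tissue phase mapping (TPM) for
murine cardiac MRI: from the four complex cine stacks acquired per
short-axis slice (motion-compensated reference plus x-, y-, z-encoded
scans) to voxel velocities, AHA-segment time courses, twist/torsion and
agreement statistics.  Pulse-sequence concerns (gating, black-blood
saturation timing, gradient design) are out of scope; the package starts
at k-space or reconstructed complex images.

All geometry is metric: x grows with the column index (rightward as
displayed), y with the row index (downward), origin at the first voxel
centre, voxel size = FOV / matrix of whichever grid an array lives on.
The slice is viewed foot-to-head, so "clockwise" in this frame is the
positive rotation sense used for tangential velocity and twist.
Velocities are cm/s, lengths mm, times ms.

## Reconstruction

* **Apodization**: radial window H(k) = 1/(1 + (|k|/k_c)^(2n)); H is the
  amplitude multiplier, H(0) = 1 and H(k_c) = 1/2.  Defaults n = 3,
  k_c = acquired Nyquist.  The window is parameterized against the
  acquired matrix so that filtering and zero-filling commute.  The
  defaults exist as configuration because published descriptions of
  "modified" Butterworth filters underdetermine the modification; the
  behaviour class (radial low-pass, half amplitude at cutoff) is fixed.
* **Zero-filling**: the acquired matrix is embedded centred in a
  factor-×2 larger zero matrix before the inverse FFT (sinc
  interpolation; 100 µm reconstructed voxels at 25.6 mm FOV / 128).
  FFTs use centred (fftshift) orthonormal conventions.
* **Velocity**: v = venc·Δφ/π with Δφ = arg(S_ref · conj(S_enc)).  No
  phase unwrapping is attempted — velocities beyond venc alias exactly as
  in the acquisition; a log warning fires when more than 0.5% of
  in-mask voxels lie within 5% of ±venc.  venc applies per axis:
  in-plane venc to x and y, through-plane venc to z.
* **Background correction**: per frame and component, v ≈ a + b·x + c·y
  is fitted by least squares over a static reference mask (the agarose
  tube surrogate) and subtracted from the whole map.  The linear model
  is the default; `constant` and `off` are available.  For noiseless
  data with a truly planar offset the correction is exact to machine
  precision, and the post-correction reference mean is zero by
  construction.

## Kinematic analysis

Bulk motion is removed by subtracting the myocardial-mask mean of each
Cartesian component per frame.  Because this also zeroes the global
longitudinal mean, the *global* v_z time course is computed before bulk
correction; polar maps and all regional statistics use the corrected
field.  The in-plane transform about the per-frame mask centroid is an
orthonormal change of basis (v_r = −v·r̂, v_φ = +v·t̂_clockwise), so
in-plane speed is conserved voxelwise.

Segmentation follows the AHA 16-segment model: 6 equiangular segments on
basal and mid slices, 4 on the apical slice, the apex-only 17th segment
excluded.  No anatomical landmark is imposed for the mouse; by default
the anterior segment is centred at 12 o'clock and ids advance
counterclockwise (foot-to-head view), with the anchor angle exposed as
configuration.  Each segment splits at its median voxel radius into
endo (r < median) and epi (r ≥ median) compartments; with all radii
equal the convention puts every voxel in the epicardial half.

Segmental angular velocity is the region mean of the *voxelwise* ratio
v_φ/r rather than the ratio of region means.  The two differ by the
mean/median radius ratio of the region (≈ 1% for an annulus); the
voxelwise form is exact for rigid-body rotation, which makes the
rotation analysis internally consistent (a rigid slice yields the same
twist in every segment and compartment to machine precision).  The
scalar form v_φ/r is still available (`angular_velocity`) for
median-radius-based workflows, and the per-frame segment median radius
is reported alongside every time course.

Twist integrates v_rot over end-diastole → end-systole by the
trapezoidal rule at the native frame interval (second-order accurate and
telescoping, so twists are additive over adjacent windows).
End-diastole defaults to frame 0 (ECG trigger); end-systole defaults to
the frame of minimum endocardial (cavity) area, overridable via
`es_frame`.  Torsion per wall is apical − basal twist, an exact identity
in the output tables; the six basal/mid segments collapse to the four
apical walls by averaging the two septal and the two lateral segments.
Compartment torsion uses each compartment's own v_rot and radii.  Cohort
time-course averaging rescales each subject's time axis so end-systole
maps to normalized time 1.0 and resamples by linear interpolation; the
amplitude axis is untouched.

Agreement statistics: OLS regression with a two-sided t-test of
slope = 1 (SE = 0 treated as "cannot reject", p = 1), Pearson r, and
Bland–Altman bias with ±2·SD limits of agreement (the ±2 convention,
not 1.96).  Paired series are matched frame-by-frame and truncated to
the shorter cine.  Percent normalization of diseased-heart velocities is
the plain relative difference 100·(v_IR − v_ctrl)/v_ctrl, so a reduced
magnitude reads negative for both positive (systolic radial) and
negative (diastolic, longitudinal) components; a zero control value is
reported missing.  The synchrony map correlates the mean radial velocity
of 24 equiangular sectors with the global series; constant series give
NaN.

## The synthetic phantom

The phantom emulates an ECG-gated short-axis cine at the study's
acquisition regime: 128×128 matrix, 25.6 mm FOV, 4.6 ms frame interval,
20 frames (≈ 92 ms cycle), venc 6/8 cm/s, one static 3.5 mm reference
block near the image corner.  The wall is an annulus with raised-cosine
contraction (systolic fraction 0.6 of the cycle), end-diastolic radii
1.6/2.6 mm (basal, mid) or 1.0/2.0 mm (apical) and radial excursions
0.45 mm (endo) / 0.15 mm (epi), i.e. ≈ 30% systolic wall thickening.
Rotation has a linear transmural profile (endocardium-heavier) with a
sinusoidal systolic lobe and an area-balancing diastolic counter-lobe;
peak amplitudes per slice are sized to give basal twist ≈ +2.5°, mid
≈ +0.4°, apical ≈ −2.6° and peak mean radial velocities ≈ +0.8 cm/s
(systole) / −1.3 cm/s (diastole) — the healthy-mouse regime.
Longitudinal velocity is spatially uniform per frame (base-to-apex
positive).  A piecewise-constant rotation waveform is available for
closed-form checks; the systolic phase is the closed interval
[0, t_sys] so its plateau includes the end-systolic sample.

Signal model: voxel magnitude is the sub-voxel (4×4) area fraction of
tissue or reference block — a softened, partial-volume-like edge rather
than a binary one; voxel phase is the analytic velocity phase at the
voxel centre, with the encoded scans carrying −π·v/venc so that phase
subtraction reconstructs prescribed positive velocities as positive.
The velocity field is continued past the wall borders by clamping the
transmural profile: the phase of zero-signal voxels is unobservable, and
a border voxel's tissue fraction moves with the adjacent wall edge, so
this avoids an artificial phase step at the tissue boundary.  The
background phase plane is applied to the encoded scans only, modelling
the differential eddy-current phase the static-reference correction
exists to remove (a plane common to all four scans would cancel in the
subtraction).  Complex Gaussian noise (default SD 0.05 of the tissue
signal, SNR 20) is seeded; k-space data are the forward FFT of the
sampled image.  The optional artifact model adds one coherent random
phase offset per frame and encoding inside a configurable angular wedge
of the wall — the downstream effect of a pulsatile flow ghost overlay —
which the 24-sector correlation map localizes.  Alternative forward
models (fully band-limited k-space synthesis from a supersampled object;
complex sub-voxel averaging) were evaluated and produce *larger* border
errors, since they reintroduce full Gibbs ringing at the wall edge.

What the phantom does **not** emulate: intravoxel dephasing, blood-pool
signal and saturation-band behaviour, respiratory motion, trigger
jitter, coil sensitivity, T1/T2* weighting, or k-space segmentation
timing.  Passing the closed-loop tests therefore demonstrates the
correctness of the analysis chain for band-limited, rigid-grid,
noise-perturbed data — not robustness to every in vivo artifact.

The flow-tube generator provides the in-silico analogue of a flow-rate
validation: a 1.5 mm-radius tube (12.8 mm FOV for finer rim sampling),
plug or parabolic profile with Q = v·πR² or v_max·πR²/2, peak velocity
checked against venc.  Flow is recovered by summing v_z·voxel-area over
the tube ROI; with SNR 30 the recovered rates at 35/40/45 mL/min are
within 0.3% and the flow SD across noise realizations follows the
per-voxel propagation law σ_v = venc·σ_φ·√2/π (the √2 from the two-scan
subtraction) within a few percent.

## Numerical choices and degenerate inputs

Rasterization uses the even-odd rule on voxel centres; polygons are
implicitly closed and need ≥ 3 distinct vertices.  A voxel coinciding
with the centre of mass has no radial direction and is excluded with a
warning.  Empty segments or compartments propagate as missing (NaN)
into time courses and peaks — never zero-filled, which would bias cohort
statistics.  Segment sectors are half-open `[start, start+width)`;
count-weighted segment means reproduce the global mask mean to 1e−9.
Median splits use the numpy median; ties go to the epicardial side.
Angular-velocity radii must be positive; twist windows must satisfy
ED < ES inside the series.

## Known limitations

* **Wall-border voxels.** Through the full k-space route (apodization +
  zero-filling) the reconstructed velocity at the outermost myocardial
  voxel ring is biased by the point-spread of the tissue/background
  edge combined with the transmural velocity gradient.  On the noiseless
  default phantom every voxel deeper than one reconstructed voxel
  (0.1 mm) from the border recovers the analytic field within 0.52% of
  venc, but the border ring itself peaks at ≈ 1.0% (mid/basal) to 1.5%
  (apical, where radii are small and the diastolic gradient steep).
  This is a resolution/partial-volume limit of the imaging model, not of
  the analysis; practitioners routinely treat TPM border voxels as
  unreliable.
* End-systole detection by minimum cavity area assumes monotone
  contraction to a single minimum; irregular rhythms need `es_frame`.
* The twist integral assumes the segmentation tracks the same wall
  region frame to frame (Eulerian averaging, no material-point
  tracking); strain and strain-rate are out of scope.
* Torsion is reported in degrees (not normalized per mm of inter-slice
  distance).
* Two-encoding (in-plane only) datasets are accepted; longitudinal
  outputs are then reported absent, not zero.
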