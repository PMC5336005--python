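# Methods

## Problem and model

Two tri-axial gyroscopes are mounted over the thumb and index fingernails
with their x-axes along the distal segments.  Each measures the angular
velocity of its own finger, expressed in its own frame.  The package
estimates the relative rotation of the thumb observed from the index-finger
frame and reduces it to one scalar, the tapping angle θ(t): the angle
between the fingers' longitudinal axes about the dominant rotation axis,
zero at contact and largest at full opening.

The kinematic model is *scissor-like*: finger bending is neglected and the
relative motion is treated as a rotation, dominantly about the index y-axis
(transverse to the finger).  This is an approximation of real finger motion,
but it is exactly the regime where a single scalar is clinically meaningful,
and the estimation chain itself never assumes it — the continuous algorithm
tracks the full 3-D relative rotation.

Conventions: right-handed frames; the inter-sensor rotation `[R]` maps thumb
components into index components; all internal units are radians and rad/s
(file I/O uses degrees, the clinical convention); the raw angle is
α = atan2(r₃₁, r₁₁) on (−π, π], so a rotation by β about +y gives α = −β,
and the clinical angle is θ = −α up to the baseline.

## Autocalibration

With fingers pressed together both sensors sense the same angular-velocity
vector, so ω₂ = [R]·ω₁ at every instant.  Solving the per-instant linear
systems directly is ill-conditioned and yields non-orthonormal matrices;
instead `[R]` is parametrized by three Euler angles, [R] = [Rφz][Rφy][Rφx]
(orthonormal by construction), and the summed squared component residuals
over the *whole window* are minimized with Nelder–Mead.  Summation over the
window (rather than using three instants) averages sensor noise and makes
the problem well-posed whenever the motion excites all three axes.

Window detection thresholds (none are dictated by the measurement protocol;
all sit in `CalibrationConfig`): both smoothed magnitudes above 30 deg/s
("vigorous"), relative magnitude mismatch below 10% ("practically equal"),
minimum run 0.5 s, magnitudes smoothed with a 50 ms moving average, search
restricted to the first half of the recording.  Detection resolution is
therefore about half the smoothing window (±5 samples at 200 Hz).

Optimizer policy: start at (0,0,0), `fatol` 1e-10, at most 5000 iterations;
if the achieved cost stays above an estimated noise floor, six deterministic
restarts from ±45° on each axis guard against local minima and the best
result is kept.  Because Nelder–Mead only accepts improvements, the reported
cost never exceeds the initial guess's cost.  A window whose second-moment
matrix Σωωᵀ has a smallest/largest eigenvalue ratio under 0.02 is flagged
(`low_excitation`): rotation purely about one axis leaves the about-axis
Euler angle unidentifiable even though the residual looks fine.

On simulated sessions the recovery error is < 1e-3 rad noise-free and the
95th percentile stays well under 1° at 0.5 deg/s white noise (the acceptance
suite measures both over 100 random mounting rotations within ±60°).

## Angle estimation

**Continuous (AL-C).**  Per 5 ms sample: ω_r = [R]ω₁ − ω₂ (index frame);
Δφ = ω_r Δt; [R] ← [Rz(Δφz)][Ry(Δφy)][Rx(Δφx)][R]; α = atan2(r₃₁, r₁₁) read
*before* the update.  The per-axis factors use exact sines and cosines of the
increments, not first-order truncations; since every factor is orthonormal,
the product stays orthonormal to round-off and no periodic
re-orthonormalization is needed (an optional SVD-based cleanup every N steps
exists for very long runs).  The update is first-order accurate: it agrees
with a quaternion exponential-map integrator exactly for single-axis motion
and to O(Δφ²) cross terms otherwise.  For near-scissor streams (dominant y,
transverse rates ≲ 0.2 rad/s) the two paths agree within 0.1° over 15 s at
200 Hz; for strongly multi-axis streams the schemes genuinely differ at
second order, shrinking linearly with the step (both facts are property
tests).  α is declared undefined (error) when r₁₁² + r₃₁² < 1e-12, i.e. the
thumb axis is parallel to the index y-axis.

**Resetting (AL-R).**  The second row of `[R]` is empirically near-constant
during tapping (exactly constant in the scissor model), so
ω_ry ≈ r₂₁⁰ω₁x + r₂₂⁰ω₁y + r₂₃⁰ω₁z − ω₂y with the calibration row frozen,
integrated by the rectangle rule at Δt.  The sign convention is fixed so
θ(AL-R) matches θ(AL-C) = −α.  AL-R cannot tumble — its only failure mode is
a drift ramp that baseline removal eliminates — at the price of losing
information when the relative rotation leaves the dominant axis (thumb slip,
changing tapping mode).

**Drift rule.**  The final drift is |α(end) − α(tapping start)|; both
instants have the fingers closed by protocol, so the residual is integration
drift.  The resetting algorithm is selected iff drift > 60° (strict).

**Dominant-axis realignment.**  The decision statistic is the eigenstructure
of M = Σ ω_r ω_rᵀ Δt computed with the *calibration rotation held fixed*.
For scissor-like motion this form gives the exact rotation axis regardless
of either sensor's mounting, and — unlike using the continuously integrated
matrix — it cannot be corrupted by AL-C tumbling under strong bias.
Realignment fires only when (a) the principal axis is unambiguous (largest
eigenvalue ≥ 1.5× the next: brief transients such as a thumb slip deposit
comparable energy on a second axis without defining a rotation axis — the
pipeline then warns and keeps the frame), and (b) the axis points > 25° away
from y.  The applied rotation is the minimal (shortest-geodesic) map of the
axis onto y, with the sign of the new y chosen so θ swings predominantly
positive (fingers opening).  For axis-aligned cases the eigen-analysis
reduces to comparing the per-axis squared-velocity integrals.

The tapping segment is everything after the detected calibration window plus
a 0.25 s guard gap.

## Tap segmentation and baseline removal

1. *Period*: first local maximum of the mean-removed autocorrelation of θ
   in lags [0.2 s, 3 s] exceeding 0.3 of the zero-lag value (the prominence
   rule and lag range are configuration, not protocol).
2. *Smoothing*: centered moving average, odd window of period/8 — wide
   enough to kill contact bumps and 5 Hz tremor ripple, narrow enough to
   preserve tap peaks; edges shrink the window symmetrically (zero phase).
3. *Boundary walk*: the period seeds a search window of ±35% of a period
   around each predicted next closure.  Candidates are local minima of the
   smoothed trace, accepted only near the running closure level (previous
   anchor plus a drift slope, within 30% of the typical per-period
   amplitude) — this rejects tremor dips on the slopes and plateau noise
   during a tap held open.  If nothing qualifies the window *grows* by whole
   periods (a held-open skip has no closure for several periods, and a
   growing window cannot land out of phase).  Among accepted candidates the
   earliest within 10% of the deepest wins, so a flat lead-in is preferred
   over the closure ending the first tap.  Boundaries are refined to the raw
   series' minimum within half a smoothing window (undoes smoothing-induced
   phase shift).
4. *Merging*: taps whose smoothed aperture falls below max(25% of the median
   aperture, 1°) are artifacts of flat valleys (taps held nearly closed);
   interior ones merge into their predecessor, first/last ones are dropped.
   Signals whose typical amplitude is below 2° raise a no-taps error.
5. *Baseline*: the piecewise-linear interpolant through (mₖ, θ(mₖ)) is
   subtracted (nearest-anchor extension outside), making θ(mₖ) = 0 exactly.
6. *Features*: duration (mₖ₊₁ − mₖ)Δt; aperture = max − min of θ within the
   tap; peak opening/closing speeds = extrema of the central-difference
   derivative.

Tap counts match the generator's truth on all 11 patterns × 20 seeds at the
default noise level (an acceptance test).

## Marker-board reference

Each finger carries a rigid T-board: markers 1–2 along local x, marker 3
along local y (at (0,0,0), (50,0,0), (0,20,0) mm in the sensor frame).  Per
frame the board frame is built by Gram–Schmidt on x then y — exact for a
rigid board and matching the stated geometry; an SVD/Procrustes fit would
only differ for deformed boards, which the rigidity check flags (pairwise
distance deviation > 2 mm).  The reference rotation is [R] = [R₂]⁻¹[R₁]
(inverse = transpose), the reference angle uses the same atan2 extraction,
and only a constant offset is applied so θ_ref = 0 at the start of tapping
(cameras do not drift).  Whole-hand motion cancels exactly in the relative
rotation; a property test premultiplies both boards by an arbitrary
time-varying rotation and requires ≤ 1e-9 change.

## Agreement metrics

ICC is computed per tap on the paired angle samples and averaged over the
sequence.  The variant is ICC(2,1) — two-way random effects, absolute
agreement, single measures — computed from the ANOVA mean squares; absolute
agreement is the right form because the comparison is of absolute angles,
and a constant offset must be penalized.  (The independent cross-check in
the tests is `pingouin.intraclass_corr`'s ICC(A,1).)  RMS error is likewise
per tap, then averaged.  Aperture errors pair the estimated and reference
tap sets one-to-one by maximal temporal overlap (Hungarian assignment;
zero-overlap pairs dropped); the relative error divides by the reference
aperture, excluding reference apertures under 2° (division guard).  ICC is
undefined (reported missing) when both series have zero variance.

## The simulator

The generator emulates the measurement protocol: 0.5 s rest, 2.0 s of
whole-hand "circle drawing" with fingers pressed together (three sinusoidal
pose angles, 0.7 rad at 1.2 Hz, 120° out of phase, raised-cosine on/off
ramps — vigorous and exciting all axes), a 0.5 s settle pause, then 15 s of
tapping: 18 s and 3600 samples per channel at 200 Hz in total.  The settle
pause exists so that the pipeline's tapping segment (window end + 0.25 s
guard) always starts before the first tap — without it the first tap would
straddle the segment boundary and no segmentation could count it correctly;
subjects likewise pause between the calibration move and tapping.

θ_true(t) is a train of raised-cosine opening pulses (C¹, so gyro rates stay
finite), amplitude = aperture, rate = tap rate, zero at closures.  Pattern
extras superpose: tremor as a sinusoid amplitude-modulated by the
normalized tap envelope (so θ ≥ 0 and closures stay clean); held-open skips
replace a tap by rise/hold/fall over 2–3 periods; held-closed skips append a
flat tail to the preceding tap; impacts add a 30 ms one-sided bump at each
closure whose peak angular rate grazes the ±2000 deg/s full scale; slip adds
a 20°, 100 ms about-z transient at each closure; pattern 5 rolls the whole
hand (30° at 0.2 Hz) during tapping; pattern 7 drifts the thumb frame by 10°
over the sequence.  Default amplitudes/rates per pattern (2 Hz/40°, 3 Hz/60°,
4 Hz/15°, 1 Hz/10° for patterns 1–4; extras on the pattern-1 base) are
engineering defaults for qualitatively described clinical patterns, all
exposed on `PatternSpec`.

Orientations: the index sensor follows the hand pose (times its mounting
rotation), the thumb sensor carries the relative rotation
`M₂ᵀ·Rz(slip)·Ry(θ−θ_contact)·Rx(drift)·M₁`, so the raw angle of
[R₂]ᵀ[R₁] reproduces −(θ − θ_contact) exactly for any hand motion (a 1e-9
property test).  The thumb mounting rotation defaults to a per-seed uniform
draw within ±45° per axis — every session exercises a different calibration
problem.  Body-frame gyro signals come from the rotation log of
R(t−Δt)ᵀR(t+Δt) over 2Δt (exact for constant rates, O(Δt²) otherwise); the
sensor model then adds a constant bias (scalar = uniform draw per sensor,
vector = exact, (2,3) = per-sensor), a bias random walk, white noise,
clipping at ±full scale and quantization to 2·FS/2¹² (0.977 deg/s).
Everything is deterministic per (spec, sensor, seed).

What the simulator does *not* emulate: finger bending and fingertip
translation, soft-tissue wobble of the mounts, camera marker noise and
occlusion, wireless dropouts, and real patients' within-sequence variability
of rate and amplitude.  Passing tests therefore show the *estimation chain*
is correct under the stated kinematics and sensor errors — not that every
clinical recording will reach the same agreement numbers.

## Numerical choices and degenerate inputs

- Angles in radians internally; (−π, π] branch everywhere; α unwrapped
  before differencing on the reference path.
- Raw-angle degeneracy (thumb x ∥ index y) raises a dedicated error; the
  35°-per-axis default motions never approach it.
- The AL-C hot loop is plain 3×3 float arithmetic (~3600 steps per
  sequence); orthonormality after 15 s stays within 1e-9 Frobenius.
- Gimbal lock in the Euler decomposition (|φy| = π/2) is handled by the
  conventional φz = 0 branch; calibration restarts keep the optimizer off
  that set in practice.
- NaN gaps up to 25 ms in gyro CSVs are linearly interpolated with a
  warning; longer runs or edge gaps are format errors.
- CSVs are written with 17 significant digits, and read with the
  round-trip float parser, so files are lossless stores (the deg↔rad
  conversion costs at most one ulp).

## Problem sizes used by the test and acceptance suites

Agreement battery: 22 sessions (two per pattern), 15 s tapping at 200 Hz,
default sensor noise.  Calibration recovery: 100 random mounts noise-free +
100 noisy, 1 s tapping segments (the calibration preamble is what matters).
Oracle equivalence: 20 streams of 15 s.  Segmentation exactness: 11 patterns
× 20 seeds, full pipeline.  These sizes keep the whole suite under a minute
while every statistic is still averaged over hundreds of taps.

## Known limitations

- The 60° switch, the 30 deg/s vigor threshold, the period/8 filter width,
  the ±35% search window, the 0.3 autocorrelation prominence, and the
  realignment margins are operating points chosen for the simulated
  conditions and exposed in the configs; severely impaired recordings may
  need the manual-override hooks.
- AL-C and the quaternion oracle are both first-order integrators; for
  sustained fast multi-axis relative rotation (not scissor-like) the 5 ms
  step itself limits accuracy to the order of a degree over 15 s.
- The energy-fraction realism of the simulator (transverse ≈ 20%/10% of the
  dominant axis for the moderate pattern) is matched only loosely (±50%);
  it emulates the regime, not a specific subject.
- Real camera–gyro temporal alignment is not solved here; the simulator
  emits both on one clock, and real data would need an external offset.
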