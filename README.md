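# fingertap

Quantification of the finger-tapping angle from two fingertip-mounted 3-D
gyroscopes.

The finger-tapping test (repeatedly touching thumb and index fingertips "as
wide and fast as possible") is a standard probe of bradykinesia in
Parkinson's disease and related disorders, usually graded visually.
`fingertap` turns a pair of cheap tri-axial gyroscopes — one over each
fingernail, x-axes along the fingers — into an objective instrument: it
estimates a single scalar **tapping angle** θ(t), the angle between the
longitudinal axes of thumb and index finger about the dominant rotation
axis, zero at finger contact and maximal at full opening, and derives per-tap
duration, aperture and peak opening/closing speeds from it.

## Method

With ω₁, ω₂ the angular-velocity vectors measured in the thumb and index
sensor frames and `[R]` the rotation mapping thumb components into the index
frame:

1. **Autocalibration.** While the fingers are pressed together and the hand
   draws circles, both sensors sense the same vector: ω₂ = [R]·ω₁.  The
   window is detected automatically (both magnitudes vigorous and nearly
   equal), and `[R₀]` is found by Nelder–Mead simplex minimization of
   f(φx,φy,φz) = Σ‖ω₂ − [R(φ)]·ω₁‖² with [R] = [Rφz][Rφy][Rφx], which is
   orthonormal by construction.
2. **Continuous algorithm (AL-C).** Per 5 ms step: the relative angular
   velocity ω_r = [R]ω₁ − ω₂ (index frame), the small-angle update
   [R(n+1)] = [R(Δφz)][R(Δφy)][R(Δφx)][R(n)] with Δφ = ω_r·Δt, and the raw
   angle α = atan2(r₃₁, r₁₁) — the signed angle of the thumb axis projected
   onto the index x–z plane.  The clinical angle is θ = −α plus baseline
   removal.
3. **Resetting algorithm (AL-R).** The second row of [R₀] is frozen and
   ω_ry ≈ r₂₁⁰ω₁x + r₂₂⁰ω₁y + r₂₃⁰ω₁z − ω₂y is integrated directly —
   approximate, but immune to matrix tumbling.  When AL-C's final drift
   (|α| difference between the closed-finger start and end instants) exceeds
   60°, AL-R is selected automatically.
4. **Dominant axis.** If the rotation energy (time-integrals of squared
   ω_r components) is not carried by the index y-axis, the index frame is
   computationally realigned so the principal energy axis becomes y.
5. **Segmentation.** The average tapping period comes from the
   autocorrelation of θ(t); an averaging filter suppresses contact bumps and
   tremor; a local heuristic search places one closure minimum per period
   (robust to skipped taps held open or closed); the piecewise-linear
   baseline through the minima is subtracted so θ = 0 at every closure.
6. **Agreement metrics.** Against a reference (optical marker boards, or the
   simulator's ground truth): per-tap ICC (two-way random, absolute
   agreement, single measures), per-tap RMS error, and absolute/relative
   aperture errors with taps paired by temporal overlap.

A rigid-body simulator generates ground-truth sessions for eleven clinically
observed tapping patterns (moderate, fast/wide, fast/small, slow/small, hand
rotation, tremor, thumb-orientation drift, strong impacts, skips held open or
closed, thumb slip), including a realistic MEMS sensor model and virtual
motion-capture boards, so the complete chain is testable without hardware.

## Worked example

`examples/segment_taps.py` simulates a tremor-overlaid session (pattern 6:
5 Hz, 3° tremor riding on 2 Hz, 40° taps), runs the full pipeline and reads
the per-tap features:

```python
from fingertap import PatternSpec, SensorSpec, generate_session, run_pipeline

synth = generate_session(PatternSpec.preset(6), SensorSpec(), seed=11)
report = run_pipeline(synth.session, reference=None)
res = report.selected_result
```

It prints

```
algorithm selected  : AL-C (AL-C drift 2.0 deg)
estimated period    : 0.500 s
taps found          : 30 (truth: 30)
 tap_index  t_start_s  t_end_s  duration_s  aperture_deg  peak_open_dps  peak_close_dps
         0      2.750    3.500       0.750        42.957        247.730        -246.891
         1      3.500    4.005       0.505        36.972        297.128        -297.055
         2      4.005    4.500       0.495        42.927        246.647        -247.644
```

The drift rule kept the continuous algorithm (final drift 2°, far below the
60° switch); all 30 taps of the 2 Hz sequence were found; apertures scatter
around the 40° ground truth because the tremor broadens the peaks.
Scoring the same pipeline against the virtual marker boards
(`examples/validate_against_reference.py`) prints

```
AL-C: ICC 0.9989 | RMS 1.00 deg | aperture err 0.07 deg (rel 0.001) over 45 taps
AL-R: ICC 0.9989 | RMS 0.99 deg | aperture err 0.07 deg (rel 0.001) over 45 taps
```

i.e. the gyro estimate reproduces the optical reference essentially exactly
on synthetic data.

Each script in `examples/` is a short narrative of one capability:
simulation, calibration + estimation, segmentation, validation.  The same
operations are available from the shell:

```bash
fingertap simulate --pattern 1 --seed 7 --out demo
fingertap estimate demo_gyro.csv --out trace.csv
fingertap validate demo_gyro.csv --truth demo_truth.json --out report.json
```

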