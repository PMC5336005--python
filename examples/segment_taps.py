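"""Segment individual taps and read per-tap clinical features.

Runs the full pipeline on a tremor-overlaid session (pattern 6), then prints
the per-tap table: duration, aperture (max - min angle within the tap), and
peak opening/closing speeds — the quantities a clinician reads off a
finger-tapping exam.
"""

import numpy as np

from fingertap import PatternSpec, SensorSpec, generate_session, run_pipeline

synth = generate_session(PatternSpec.preset(6), SensorSpec(), seed=11)
report = run_pipeline(synth.session, reference=None)

res = report.selected_result
print(f"algorithm selected  : {report.selected} "
      f"(AL-C drift {np.degrees(report.alc.final_drift_rad):.1f} deg)")
print(f"estimated period    : {res.period_s:.3f} s")
print(f"taps found          : {res.taps.n_taps} (truth: {len(synth.taps)})")

table = res.taps.to_frame(res.trace.t)
print(table.head(5).round(3).to_string(index=False))
print(f"mean aperture       : {np.degrees(res.taps.aperture_rad.mean()):.1f} deg")
# The 5 Hz / 3 deg tremor rides on 40 deg taps; the averaging filter keeps
# the count exact while the apertures reflect the tremor-broadened peaks.
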