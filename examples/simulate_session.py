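"""Generate one synthetic tapping session and write it to disk.

Builds a moderate 2 Hz / 40 deg tapping session (pattern 1): 0.5 s rest,
2 s of whole-hand calibration circles with the fingers pressed together,
a short pause, then 15 s of tapping, sampled by two simulated fingertip
gyroscopes (white noise, bias walk, 12-bit quantization, +/-2000 deg/s).
"""

import numpy as np

from fingertap import PatternSpec, SensorSpec, generate_session
from fingertap.session_io import write_gyro_csv, write_marker_csv, write_truth_json

synth = generate_session(PatternSpec.preset(1), SensorSpec(), seed=7)

write_gyro_csv("session_gyro.csv", synth.session)
write_marker_csv("session_markers.csv", synth.session)
write_truth_json("session_truth.json", synth)

print(f"samples per channel : {len(synth.session)} at {synth.session.fs:.0f} Hz")
print(f"true taps           : {len(synth.taps)}")
print(f"tapping starts at   : {synth.session.t[synth.tapping_start]:.2f} s")
print(f"peak thumb rate     : {np.degrees(np.abs(synth.session.w_thumb).max()):.0f} deg/s")
# The CSVs hold deg/s gyro streams and mm marker trajectories; the truth JSON
# carries the noise-free angle every estimate can be scored against.
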