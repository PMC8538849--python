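"""Generate synthetic single-lead strips for the four rhythm classes.

Each strip emulates a 30 s hand-held recording (300 Hz, 0.5-40 Hz
bandwidth, +-5 mV).  The printed RR coefficient of variation separates
the regular sinus rhythm from the irregularly irregular AF strip, and
the P-wave count shows atrial activity present only where synthesized.
"""

import numpy as np

from densecg.synthetic import RhythmSpec, generate_ecg

for cls in ("N", "AF", "O", "X"):
    rec, truth = generate_ecg(RhythmSpec(rhythm_class=cls, seed=42))
    rr = np.diff(truth.r_peaks) / rec.fs
    print(f"class {cls}: {len(truth.r_peaks)} beats, "
          f"RR CV = {rr.std() / rr.mean():.3f}, "
          f"{len(truth.p_peaks)} P-waves, "
          f"peak |mV| = {np.abs(rec.samples).max():.2f}")

print("\nRR CV near 0.03 marks sinus rhythm; >= 0.15 with no P-waves is AF;")
print("the noise strip keeps its beats but buries them under artifact.")
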