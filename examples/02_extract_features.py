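"""Extract the 137 diagnostic features from sinus and AF strips.

Prints a handful of clinically interpretable features side by side:
AF shows high RR irregularity (PNN50%), absent P-waves and measurable
fibrillatory-wave amplitude in the TQ segments, with the TQ spectrum
peaking at the f-wave frequency.
"""

from densecg.features import default_registry, extract_feature_vector
from densecg.synthetic import RhythmSpec, generate_ecg

reg = default_registry()
show = ("PNN50%", "SD1/SD2", "P-wave presence", "MeanPcountRRint",
        "Median_TQamp", "MeanDF", "AF%", "corBeat(mean)")

vectors = {}
for cls in ("N", "AF"):
    rec, _ = generate_ecg(RhythmSpec(rhythm_class=cls, seed=7))
    fv = extract_feature_vector(rec, reg)
    vectors[cls] = dict(zip(reg.names, fv.values))
    print(f"{cls}: {sum(fv.missing_mask)} of 137 features missing "
          f"(imputed 0, masked)")

print(f"\n{'feature':<18}{'sinus':>10}{'AF':>10}")
for name in show:
    print(f"{name:<18}{vectors['N'][name]:>10.3f}{vectors['AF'][name]:>10.3f}")
print("\nMeanDF is the dominant TQ-spectrum frequency (Hz): the AF strip")
print("carries 6 Hz fibrillatory waves; AF% is the RR-irregularity score.")
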