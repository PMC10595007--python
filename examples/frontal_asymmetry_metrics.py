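"""Compute the eight valence/arousal metrics from four band powers.

Builds the alpha/beta band-power quad for the frontal pair (F7 left,
F8 right) and prints the eight frontal-brain-asymmetry metrics. With
alpha power larger on the right (F8), the valence metrics v2 < 0 and
v4 > 0 indicate relative left-alpha suppression — the classical
signature of positively valenced affect.
"""

from eegaffect import BandPowerQuad, valence_arousal

quad = BandPowerQuad(alpha_f7=1.0, alpha_f8=4.0, beta_f7=2.0, beta_f8=2.0)
metrics = valence_arousal(quad)

print("band powers:", quad)
for name, value in metrics.items():
    kind = "valence" if name.startswith("v") else "arousal"
    print(f"  {name} ({kind}) = {value:+.4f}")
print(
    "\nv4 = alpha_F8 - alpha_F7 > 0 and v2 = ln(alpha_F7) - ln(alpha_F8) < 0:\n"
    "right-dominant alpha, i.e. the planted 'positive emotion' pattern."
)
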