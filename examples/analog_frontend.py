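"""Size the analog front end of a wearable ECG sensor.

Computes the band-pass characteristics of the 0.5–250 Hz ECG acquisition
band and the resistor for a 60 Hz mains notch with a 0.1 uF capacitor.
"""

from wearecg import band_pass_characteristics, notch_resistor

bp = band_pass_characteristics(f_high=250.0, f_low=0.5)
print(f"bandwidth   : {bp.bandwidth:.1f} Hz")
print(f"f_resonant  : {bp.f_resonant:.4f} Hz")
print(f"Q factor    : {bp.q_factor:.4f}")
# bandwidth is the passband width; the resonant frequency is the geometric
# mean of the cutoffs, and Q < 1 says this is a wide acquisition band,
# not a sharp resonator.

notch = notch_resistor(f_notch=60.0, capacitance=0.1e-6)
print(f"notch R     : {notch.resistance / 1000:.1f} kOhm")
# the resistor that tunes an RC notch to 60 Hz mains interference.
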