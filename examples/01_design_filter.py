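"""Design the default pre-processing filter and inspect what quantization costs.

Builds the 64th-order linear-phase low-pass FIR used ahead of feature
extraction (pass band to 40 Hz, stop band from 50 Hz) and quantizes its
coefficients to 16-bit fixed point, then reports the realized stop-band
attenuation and pass-band ripple of both versions.
"""

from szdet import fir

spec = fir.design_lowpass(fs=256.0, order=64, f_stop=50.0, min_stop_atten_db=60.0)
q16 = fir.quantize(spec, bits=16)

for label, s in [("float64 design", spec), ("16-bit quantized", q16)]:
    atten = fir.stopband_attenuation_db(s.coefficients, s.fs, s.f_stop)
    ripple = fir.passband_ripple_db(s.coefficients, s.fs, s.f_pass)
    print(f"{label}: {len(s.coefficients)} taps, "
          f"stop-band attenuation {atten:.2f} dB, pass-band ripple {ripple:.3f} dB")

print(f"group delay: {q16.group_delay_samples} samples "
      f"({1000 * q16.group_delay_samples / q16.fs:.0f} ms at {q16.fs:.0f} Hz)")
# Attenuation must stay >= 60 dB from 50 Hz up so power-line interference and
# high-frequency artifacts cannot masquerade as ictal power changes.
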