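"""Power difference and line length on a toy signal.

Shows the two per-channel features on a 2-second, 8 Hz recording: a quiet
first second and a louder, faster second second. PD reacts per sample to
power changes; LL sums absolute first differences per window, so the second
window's value jumps.
"""

import numpy as np

from szdet.features import line_length_windows, power_difference

x = np.concatenate([
    [1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0],   # 1 uV square-ish wobble
    [5.0, -5.0, 5.0, -5.0, 5.0, -5.0, 5.0, -5.0],   # 5x amplitude
])

pd = power_difference(x)
ll = line_length_windows(x, N=8)

print("signal:        ", x.tolist())
print("power diff:    ", pd.tolist())
print("line length/w: ", ll.tolist())
# PD is zero inside each constant-amplitude stretch (consecutive squares are
# equal) and spikes at the amplitude step; LL grows 5-fold with amplitude:
# window 1 pays |x[0]-0| + 7 swings of 2 uV = 15, window 2 has 8 swings of
# ~10 uV reaching back to the previous window's last sample.
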