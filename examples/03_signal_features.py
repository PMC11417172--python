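"""Per-signal feature extraction on a textbook triangular transient.

A 20 s triangular dF/F0 pulse makes every feature value analytically
obvious: amplitude 1, 10-90% rise and 90-10% decay of 8 s, half-width
10 s, duration 20 s, Simpson AUC 10 dF/F0*s.
"""

import numpy as np

from astroroa import Signal, TraceTable, analyze_signal

baseline = np.array([0.1, -0.1, 0.2, 0.0, -0.2])
rise = np.linspace(0.0, 1.0, 11)
fall = np.linspace(0.9, 0.0, 10)
tail = np.array([0.2, -0.1, 0.1, -0.2, 0.0])
dff = TraceTable(
    np.concatenate([baseline, rise, fall, tail])[None, :], "dff", frame_rate=1.0
)

features = analyze_signal(dff, [[Signal(start=5, peak=15, end=25)]])
row = features.iloc[0]
for col in ("amplitude", "rise_time", "decay_time", "half_width",
            "duration", "AUC", "signal_to_noise"):
    print(f"{col:16s}: {row[col]:.3f}")
# signal_to_noise is amplitude over the peak baseline fluctuation (0.2
# here), hence 5.0; crossings are linearly interpolated between samples.
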