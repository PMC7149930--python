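"""ECG round trip: RR series -> synthetic lead-II trace -> QRS detection ->
cleaned NN series.

The generated trace places stylised PQRST complexes at the true beat times;
the derivative/energy detector recovers them, and the NN cleaner excises
the injected ectopic short-long pairs rather than interpolating them.
"""

import numpy as np

from hrnv import RRGeneratorSpec, clean_nn, detect_beats, gen_ecg, gen_rr

series, truth = gen_rr(RRGeneratorSpec(
    hf_amp=25.0, jitter_sd=12.0, ectopic_rate=1.0, duration=120.0, seed=9))
trace = gen_ecg(series, fs=250.0)
beats = detect_beats(trace)
clean = clean_nn(beats)

recovered = np.diff(beats) * 1000.0
print(f"generated beats    : {len(series) + 1} ({len(truth['ectopic_indices'])} ectopic events)")
print(f"detected beats     : {len(beats)}")
print(f"max |interval error|: {np.max(np.abs(recovered - series.intervals)):.1f} ms "
      f"(within 2 samples at 250 Hz = 8 ms)")
print(f"cleaned NN intervals: {len(clean)} "
      f"({clean.removed_fraction:.1%} removed as ectopic/out-of-bounds)")
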