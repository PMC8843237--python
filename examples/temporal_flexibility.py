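"""Shift, rescale and re-tempo a learned sequence without touching weights.

All three manipulations are inputs to the basal-ganglia module: an additive
current to the first Go node (shifting), a constant multiplicative gain on
all Go nodes (rescaling), and a piecewise-constant gain trace
(compositionality -- playing the sequence on an entirely new tempo grid).
"""

import numpy as np

from acdc import (ModelParams, fixture_sequence, make_rescale_signal,
                  make_shift_signal, run_composition_experiment,
                  run_learning_experiment, simulate_trial, sum_of_ratios)

params = ModelParams()
trained, base = run_learning_experiment(fixture_sequence("sim1"), params, seed=1)
w, arch = trained.weights, trained.arch

print("baseline events (ms):", np.round(base.event_times, 1))

for amp, label in ((+1.0, "earlier"), (-1.0, "later")):
    sig = make_shift_signal(amp, 100.0, 6, window_ms=1300.0)
    rec = simulate_trial(w, arch, params, modulation=sig, duration_ms=1300.0)
    print(f"shift {amp:+.0f} ({label}):  ", np.round(rec.event_times, 1))

for rho in (1.2, 0.9):
    sig = make_rescale_signal(rho, 6, window_ms=1300.0)
    rec = simulate_trial(w, arch, params, modulation=sig, duration_ms=1300.0)
    print(f"gain rho={rho}:", np.round(rec.event_times, 1),
          " sum-of-ratios:", round(sum_of_ratios(rec.event_times), 2))

desired = np.array([250., 320., 500., 780., 860., 980.])
rec, dev = run_composition_experiment(trained, desired)
print("new tempo grid:  ", desired)
print("produced events: ", np.round(rec.event_times, 1))
print("max |deviation|: ", round(np.nanmax(np.abs(dev)), 1), "ms")

# Shifting moves the whole sequence by ~the input duration with intervals
# intact; rescaling compresses/dilates it while the sum-of-ratios structure
# statistic stays put; the tempo trace re-times every interval at once.
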