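"""Two routes to sustained action execution (held notes).

Either damp the NoGo node's drive with a weak multiplicative gain during
the interval to sustain (a flexible, input-based route), or lower that
action's Action->NoGo coupling (a learning-based route).
"""

import numpy as np

from acdc import (ModelParams, fixture_sequence, make_sustain_signal,
                  run_learning_experiment, simulate_trial,
                  sustainability_auc, weaken_an_coupling)

params = ModelParams()
trained, base = run_learning_experiment(fixture_sequence("sim1"), params, seed=1)
w, arch = trained.weights, trained.arch

def span(rec, j):
    above = np.flatnonzero(rec.a[:, j] > 0.5)
    return (above.min(), above.max()) if above.size else None

print("baseline: action 1 supra-threshold", span(base, 1), "ms")

sig = make_sustain_signal(1, base.event_times[1] - 10.0, base.event_times[2],
                          6, rho=0.1)
rec = simulate_trial(w, arch, params, modulation=sig, duration_ms=1000.0)
print("NoGo gain 0.1: action 1 supra-threshold", span(rec, 1), "ms")
print("sustainability:", round(sustainability_auc(base), 3), "->",
      round(sustainability_auc(rec), 3))

weak = weaken_an_coupling(params, 2, 0.05, 6)
rec2 = simulate_trial(w, arch, weak, duration_ms=1000.0)
print("weak Action->NoGo: action 2 supra-threshold", span(rec2, 2), "ms",
      "(baseline", span(base, 2), ")")

# The second action stays active until the third executes; the third is
# held when its NoGo coupling is lowered -- both without changing the
# learned sequence or its timing.
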