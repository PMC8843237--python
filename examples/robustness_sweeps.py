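"""Model regimes and robustness: weight planes, gain plane, input overlap.

Hand-wired networks map which Go->Action couplings yield complete
sequences (and how the Action->NoGo coupling grades sustainability);
the trained model probes the feedback-gain inequality and the tolerance
to overlapping feedback projections.
"""

import numpy as np

from acdc import (ModelParams, fixture_sequence, run_learning_experiment,
                  sweep_gamma, sweep_overlap, sweep_regime,
                  sweep_sustainability)

params = ModelParams()

regime = sweep_regime(ga_grid=np.linspace(0.5, 12, 8),
                      rec_grid=np.linspace(0.25, 1.0, 4), params=params)
print("actions executed vs Go->Action coupling (rows) x recurrent weight:")
print(regime.outcomes.astype(int))

sust = sweep_sustainability(an_grid=np.linspace(0.05, 2.0, 6),
                            ga_grid=np.array([6.0, 10.0]), params=params)
print("\nsustainability vs Action->NoGo coupling (rows):")
print(np.round(sust.outcomes, 3))

trained, _ = run_learning_experiment(fixture_sequence("sim1"), params, seed=1)
gam = sweep_gamma(trained, ge_grid=np.linspace(20, 23, 4),
                  gi_grid=np.linspace(20.2, 23.2, 4))
print("\nactions vs gamma_e (rows) x gamma_i (cols):")
print(gam.outcomes.astype(int))

over = sweep_overlap(params=params, seed=1)
print("\nactions vs feedback overlap:")
for f, c in zip(over.grids[0], over.outcomes):
    print(f"  {f:.0%}: {int(c)}")

# The action count follows the Go->Action coupling (not the recurrent
# weight); sustainability is graded by the Action->NoGo coupling; full
# sequences need the excitatory feedback gain to exceed the inhibitory
# one; and the switch tolerates moderate projection overlap before the
# sequence truncates.
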