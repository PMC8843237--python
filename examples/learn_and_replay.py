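"""Learn a six-action asynchronous sequence, then replay it frozen.

The model is trained stage by stage on targets at 200, 250, 400, 700, 750
and 900 ms: fast Hebbian learning forms one cell assembly per ordinal
position within trials, while a slow delta rule tunes each Go->Action
coupling between trials until the timing error is below phi = 10 ms.
"""

import numpy as np

from acdc import ModelParams, fixture_sequence, run_learning_experiment, selectivity_index

spec = fixture_sequence("sim1")
trained, record = run_learning_experiment(spec, ModelParams(), seed=1)

print("targets (ms):      ", np.asarray(spec.target_times_ms))
print("frozen events (ms):", np.round(record.event_times, 1))
print("training trials per stage:", trained.trials_per_stage)
print("final Go->Action couplings:", np.round(trained.weights.w_ga, 2))
print("Go-node selectivity:", np.round(selectivity_index(trained.weights.w_rnn_go, trained.arch), 2))

# Each frozen event lands within a few ms of its target; the selectivity
# index near 1 shows each Go node listens almost exclusively to its own
# learned cluster, i.e. order (cortex) and timing (basal ganglia) are
# stored in separate weights.
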