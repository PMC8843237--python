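"""Scalar variability: RT dispersion grows with the timed interval.

Single-action models trained at 200-800 ms produce noisy reaction times;
the accumulation-to-bound architecture makes the RT standard deviation
increase with the interval, more steeply at higher noise.
"""

from acdc import ModelParams, run_scalar_variability

df = run_scalar_variability(params=ModelParams(), seed=1,
                            n_rts=50, n_sims=5)  # small demo sizes
summary = df.groupby(["noise_sd", "interval_ms"]).sd_ms.mean().unstack()
print("mean RT standard deviation (ms) per trained interval:")
print(summary.round(2))

# Each row increases left to right (longer intervals -> more accumulated
# noise before the bound) and the higher-noise row is uniformly larger.
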