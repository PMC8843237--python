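alpha1_rnn: 0.01
alpha2_rnn: 0.1
wmax_rnn: 1.0
alpha1_rnn_go: 2.0e-05
alpha2_rnn_go: 0.4
wmax_rnn_go: 0.05
b: 0.5
eta: 0.4
phi: 0.01
j_ie: 0.1
j_ei: 1.0
j_ea: 1.0
j_ia: 1.0
j_gn: 1.0
j_na: 1.0
gamma_e: 21.4
gamma_i: 21.0
tau_rnn: 1.0
tau_a: 10.0
tau_n: 10.0
tau_g: 1000.0
tau_w: 1.0
x_in: 1.0
lambda_rnn: 10.0
lambda_a: 10000.0
dt: 1.0
noise_sd: 0.0
noise_mode: net_input
input_pulse_ms: 100.0
rt_threshold: 0.5
onset_threshold: 0.05
context_until_onset: true
hebbian_rec_scale: 1.0
hebbian_go_scale: 1.0
ltp_volley_fraction: 0.85
zero_self_connections: false
go_gain_on_drive_only: false
j_na_per_action: null
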