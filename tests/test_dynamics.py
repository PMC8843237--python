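"""Nonlinearity, single steps, whole trials, event detection, determinism."""

import numpy as np
import pytest

from acdc import (ModelParams, NetworkState, StepInputs, build_architecture,
                  detect_action_times, initialize_weights, lowpass_update,
                  simulate_trial, step_network, theta)
from acdc.experiments import ideal_weights


# ---------------------------------------------------------------- theta ----

def test_theta_zero_at_origin_and_below():
    assert theta(0.0, 10.0) == 0.0
    assert theta(-5.0, 10.0) == 0.0
    assert theta(-1e6, 10000.0) == 0.0


def test_theta_known_value():
    # 2 / (1 + e^-10) - 1 = tanh(5)
    assert theta(1.0, 10.0) == pytest.approx(0.9999092, abs=1e-7)


def test_theta_monotone_and_bounded():
    x = np.linspace(-2, 5, 200)
    y = theta(x, 10.0)
    assert np.all(np.diff(y) >= 0)
    assert np.all((y >= 0) & (y < 1.0 + 1e-12))


def test_theta_rejects_nonfinite_and_bad_gain():
    with pytest.raises(ValueError):
        theta(np.nan, 10.0)
    with pytest.raises(ValueError):
        theta(1.0, 0.0)


# ------------------------------------------------------------- lowpass ----

def test_lowpass_fixed_points_and_euler_step():
    p = ModelParams(dt=1.0, tau_w=2.0)
    assert lowpass_update(0.0, 0.0, p) == 0.0
    # one Euler step from trace=1 with zero input and tau_w = 2 halves it
    assert lowpass_update(1.0, 0.0, p) == pytest.approx(0.5)
    trace = 0.0
    for _ in range(100):
        trace = lowpass_update(trace, 1.0, p)
    assert trace == pytest.approx(1.0, abs=1e-6)


# ------------------------------------------------------------- stepping ----

@pytest.fixture()
def small_net():
    arch = build_architecture(60, 10, 2, 0.0, seed=0)
    params = ModelParams()
    weights = initialize_weights(arch, params, seed=0)
    return arch, params, weights


def test_origin_is_fixed_point(small_net):
    """Zero weights, zero input, zero noise: the state stays exactly zero."""
    arch, params, weights = small_net
    weights.w_rec[:] = 0.0
    weights.w_rnn_go[:] = 0.0
    state = NetworkState.zeros(arch)
    for _ in range(50):
        state = step_network(state, weights, arch, params,
                             StepInputs.quiet(arch.n_actions, context=0.0))
    assert not state.x.any() and not state.g.any() and not state.a.any()
    assert state.x_inh == 0.0 and not state.n.any()

    rec = simulate_trial(weights, arch, params.replace(x_in=0.0),
                         duration_ms=100.0)
    assert not rec.a.any() and not rec.x.any() and rec.n_executed == 0


def test_go_steady_state_matches_constant_drive(small_net):
    """With constant net drive c and no NoGo, g relaxes to c (Eq fixed point)."""
    arch, params, weights = small_net
    weights.w_ga[:] = 0.0  # keep the Action/NoGo loop silent
    state = NetworkState.zeros(arch)
    c = 0.37
    inputs = StepInputs(additive_go=np.full(2, c), gain_go=np.ones(2),
                        gain_nogo=np.ones(2), context=0.0)
    p = params.replace(tau_g=20.0)  # faster relaxation, same fixed point
    for _ in range(400):
        state = step_network(state, weights, arch, p, inputs)
    assert state.g == pytest.approx(np.full(2, c), abs=1e-4)


def test_action_node_accumulation_to_bound(small_net):
    """a stays 0 while J^AG g < b, then rises toward 1 within ~5 tau_a."""
    arch, p, weights = small_net
    params = p.replace(j_na=0.0)  # silence the NoGo loop: pure accumulation
    state = NetworkState.zeros(arch)
    inputs = StepInputs(additive_go=np.array([0.6, 0.0]), gain_go=np.ones(2),
                        gain_nogo=np.ones(2), context=0.0)
    weights.w_ga[:] = 2.0
    crossed = None
    for t in range(1000):
        state = step_network(state, weights, arch, params, inputs)
        if crossed is None:
            if state.g[0] * weights.w_ga[0] < params.b:
                assert state.a[0] < 1e-6  # silent until the bound is reached
            else:
                crossed = t
        if crossed is not None and t == crossed + 50:  # ~5 tau_a later
            assert state.a[0] > 0.99
            break
    assert crossed is not None


def test_kernel_matches_reference_step(small_net):
    """The compiled trial kernel and the numpy reference agree numerically."""
    arch, params, weights = small_net
    weights.w_rec[:] = 0.3 * np.random.default_rng(0).random(weights.w_rec.shape)
    fast = simulate_trial(weights, arch, params, duration_ms=300.0)
    slow = simulate_trial(weights, arch, params, duration_ms=300.0,
                          plasticity=lambda s, w, p: None)
    np.testing.assert_allclose(fast.a, slow.a, atol=1e-10)
    np.testing.assert_allclose(fast.x, slow.x, atol=1e-10)
    np.testing.assert_allclose(fast.g, slow.g, atol=1e-10)
    np.testing.assert_allclose(fast.inh, slow.inh, atol=1e-10)


def test_kernel_matches_reference_with_noise(small_net):
    """Same seed, same noise draws: the two routes stay numerically equal."""
    arch, params, weights = small_net
    noisy = params.replace(noise_sd=0.01)
    fast = simulate_trial(weights, arch, noisy, duration_ms=200.0, seed=5)
    slow = simulate_trial(weights, arch, noisy, duration_ms=200.0, seed=5,
                          plasticity=lambda s, w, p: None)
    np.testing.assert_allclose(fast.a, slow.a, atol=1e-10)
    np.testing.assert_allclose(fast.x, slow.x, atol=1e-10)


def test_rates_bounded_over_trained_trial(trained_sim1):
    """Excitatory, Go, NoGo and Action rates stay within [0, 1.05]."""
    _, record = trained_sim1
    for name in ("x", "g", "n", "a"):
        tr = getattr(record, name)
        assert tr.min() >= -1e-9, name
        assert tr.max() <= 1.05, name


def test_bitwise_determinism(small_net):
    arch, params, weights = small_net
    noisy = params.replace(noise_sd=0.02)
    a = simulate_trial(weights.copy(), arch, noisy, duration_ms=250.0, seed=9)
    b = simulate_trial(weights.copy(), arch, noisy, duration_ms=250.0, seed=9)
    assert np.array_equal(a.a, b.a) and np.array_equal(a.x, b.x)
    c = simulate_trial(weights.copy(), arch, noisy, duration_ms=250.0, seed=10)
    assert not np.array_equal(a.x, c.x)


def test_duration_must_be_step_multiple(small_net):
    arch, params, weights = small_net
    with pytest.raises(ValueError, match="multiple"):
        simulate_trial(weights, arch, params, duration_ms=100.25)


# ------------------------------------------------------------ detection ----

def _record_params():
    return ModelParams()


def test_detection_step_trace():
    p = _record_params()
    a = np.zeros((1001, 2))
    a[200:, 0] = 1.0
    times, counts = detect_action_times(a, p)
    # the crossing is bracketed by samples 199 (0.0) and 200 (1.0); the
    # interpolated time lies within half a step of 200 ms
    assert abs(times[0] - 200.0) <= 0.5
    assert counts[0] == 1
    assert np.isnan(times[1]) and counts[1] == 0


def test_detection_counts_multiple_pulses():
    p = _record_params()
    a = np.zeros((1001, 1))
    a[100:150, 0] = 1.0
    a[600:620, 0] = 1.0
    times, counts = detect_action_times(a, p)
    assert abs(times[0] - 100.0) <= 0.5
    assert counts[0] == 2


def test_detection_interpolates_between_samples():
    p = _record_params()
    a = np.zeros((11, 1))
    a[5, 0] = 0.4
    a[6:, 0] = 0.8
    times, _ = detect_action_times(a, p)
    # crossing of 0.5 between samples 5 (0.4) and 6 (0.8): 5.25 ms
    assert times[0] == pytest.approx(5.25)


# ---------------------------------------------------- attractor switches ----

def _wired_net(params, n_actions=3):
    arch = build_architecture(200, 20, n_actions, 0.0, seed=2)
    gaps = np.full(n_actions, 200.0)
    gstar = 1.0 - np.exp(-gaps / params.tau_g)
    w = ideal_weights(arch, params, ga_weight=0.5 / gstar)
    return arch, w


def test_attractor_persistence_without_feedback(params):
    """A formed cluster excited by the context pulse persists all trial."""
    arch, w = _wired_net(params)
    w.w_ga[:] = 0.0  # no action can fire -> no feedback
    rec = simulate_trial(w, arch, params, duration_ms=1000.0)
    cluster0 = rec.x[:, arch.input_targets].mean(axis=1)
    assert np.all(cluster0[50:] > 0.5)
    assert rec.n_executed == 0


def test_switch_requires_excitatory_gain_advantage(params):
    """An Action volley extinguishes the active cluster and ignites its
    target when gamma_e > gamma_i; with gamma_e < gamma_i the target fails.
    (At exact equality the measured boundary still switches, via the
    inhibitory unit's one-step tracking lag.)"""
    arch, w = _wired_net(params)
    rec = simulate_trial(w, arch, params, duration_ms=1000.0)
    t0 = rec.event_times[0]
    assert not np.isnan(t0)
    old = rec.x[:, arch.input_targets].mean(axis=1)
    new = rec.x[:, arch.feedback_targets[0]].mean(axis=1)
    idx = int(t0 / params.dt)
    assert old[idx + 100] < 0.1            # extinguished within 100 ms
    assert new[idx + 100] > 0.5            # ignited and persistent

    weaker = params.replace(gamma_e=20.0, gamma_i=21.0)
    rec2 = simulate_trial(w, arch, weaker, duration_ms=1000.0)
    t0 = rec2.event_times[0]
    assert not np.isnan(t0)
    new2 = rec2.x[:, arch.feedback_targets[0]].mean(axis=1)
    assert new2[int(t0 / params.dt) + 100:].max() < 0.5
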