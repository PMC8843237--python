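"""Modulation signals and the temporal-flexibility behaviours they produce."""

import numpy as np
import pytest

from acdc import (ModulationSignal, make_rescale_signal, make_shift_signal,
                  make_sustain_signal, make_tempo_signal, simulate_trial,
                  sustainability_auc, weaken_an_coupling)


# --------------------------------------------------------- construction ----

def test_identity_signal_is_identity():
    sig = ModulationSignal.identity(1000.0, 6)
    assert sig.is_identity()
    assert sig.n_steps == 1000 and sig.n_actions == 6


def test_zero_amplitude_shift_is_identity():
    assert make_shift_signal(0.0, 100.0, 6).is_identity()


def test_shift_signal_targets_first_go_node():
    sig = make_shift_signal(-1.0, 100.0, 6)
    assert np.all(sig.additive_go[:100, 0] == -1.0)
    assert not sig.additive_go[100:].any()
    assert not sig.additive_go[:, 1:].any()
    assert np.all(sig.gain_go == 1.0)


def test_rescale_signal_uniform_gain():
    sig = make_rescale_signal(1.2, 6)
    assert np.all(sig.gain_go == 1.2)
    sig = make_rescale_signal(1.2, 6, spare_first=True)
    assert np.all(sig.gain_go[:, 0] == 1.0)
    assert np.all(sig.gain_go[:, 1:] == 1.2)
    with pytest.raises(ValueError):
        make_rescale_signal(0.0, 6)


def test_tempo_signal_identity_grid_is_unit_gain():
    trained = [200.0, 400.0, 700.0]
    sig = make_tempo_signal(trained, trained, 1000.0)
    np.testing.assert_allclose(sig.gain_go, 1.0)


def test_tempo_signal_halves_gain_for_doubled_intervals():
    trained = np.array([100.0, 200.0, 300.0])
    sig = make_tempo_signal(trained, 2 * trained, 800.0, correction="linear")
    np.testing.assert_allclose(sig.gain_go[:600], 0.5)


def test_tempo_signal_validation():
    with pytest.raises(ValueError):
        make_tempo_signal([100.0], [100.0, 200.0], 1000.0)
    with pytest.raises(ValueError):
        make_tempo_signal([100.0, 200.0], [200.0, 100.0], 1000.0)
    with pytest.raises(ValueError):
        make_tempo_signal([100.0], [2000.0], 1000.0)


def test_sustain_signal_targets_one_nogo_interval():
    sig = make_sustain_signal(1, 250.0, 400.0, 6, rho=0.1)
    assert np.all(sig.gain_nogo[250:400, 1] == 0.1)
    assert np.all(sig.gain_nogo[:250, 1] == 1.0)
    assert np.all(sig.gain_nogo[:, 0] == 1.0)
    go_variant = make_sustain_signal(1, 250.0, 400.0, 6, rho=0.1, target="go")
    assert np.all(go_variant.gain_go[250:400, 1] == 0.1)
    assert np.all(go_variant.gain_nogo == 1.0)


def test_weaken_an_coupling_overrides_one_pair(params):
    p = weaken_an_coupling(params, 2, 0.05, 6)
    np.testing.assert_allclose(p.j_na_vector(6), [1, 1, 0.05, 1, 1, 1])
    assert params.j_na_per_action is None  # original untouched
    with pytest.raises(IndexError):
        weaken_an_coupling(params, 9, 0.05, 6)


def test_modulation_file_round_trip(tmp_path):
    """Piecewise-constant signals round-trip exactly through the text file."""
    trained = [200.0, 400.0, 700.0]
    sig = make_tempo_signal(trained, [260.0, 500.0, 800.0], 1000.0)
    sig.additive_go[:100, 0] = -1.0
    sig.gain_nogo[250:400, 1] = 0.1
    path = tmp_path / "tempo.tsv"
    sig.to_file(path)
    back = ModulationSignal.from_file(path)
    assert back.n_steps == sig.n_steps and back.dt == sig.dt
    np.testing.assert_array_equal(back.gain_go, sig.gain_go)
    np.testing.assert_array_equal(back.gain_nogo, sig.gain_nogo)
    np.testing.assert_array_equal(back.additive_go, sig.additive_go)


# ----------------------------------------------------------- behaviour ----

def test_identity_signal_reproduces_unmodulated_trial(trained_sim1, params):
    """Bitwise-identical record under the explicit identity signal."""
    trained, _ = trained_sim1
    base = simulate_trial(trained.weights, trained.arch, params,
                          duration_ms=1000.0)
    sig = ModulationSignal.identity(1000.0, 6)
    mod = simulate_trial(trained.weights, trained.arch, params,
                         modulation=sig, duration_ms=1000.0)
    assert np.array_equal(base.a, mod.a)
    assert np.array_equal(base.x, mod.x)


def test_shift_moves_sequence_without_reordering(trained_sim1, params):
    """Positive input starts the sequence earlier, negative later; the
    inter-action structure and order are preserved."""
    trained, _ = trained_sim1
    w, arch = trained.weights, trained.arch
    base = simulate_trial(w, arch, params, duration_ms=1300.0)
    for amp, direction in ((1.0, -1), (-1.0, +1)):
        sig = make_shift_signal(amp, 100.0, 6, window_ms=1300.0)
        rec = simulate_trial(w, arch, params, modulation=sig,
                             duration_ms=1300.0)
        assert rec.n_executed == 6
        shift = rec.event_times[0] - base.event_times[0]
        assert np.sign(shift) == direction
        assert 50.0 < abs(shift) < 150.0
        np.testing.assert_allclose(np.diff(rec.event_times),
                                   np.diff(base.event_times), atol=5.0)
        assert list(rec.event_order) == list(base.event_order)


def test_rescale_compresses_and_dilates(trained_sim1, params):
    trained, _ = trained_sim1
    w, arch = trained.weights, trained.arch
    base = simulate_trial(w, arch, params, duration_ms=1300.0)
    fast = simulate_trial(w, arch, params, duration_ms=1300.0,
                          modulation=make_rescale_signal(1.2, 6, window_ms=1300.0))
    slow = simulate_trial(w, arch, params, duration_ms=1300.0,
                          modulation=make_rescale_signal(0.9, 6, window_ms=1300.0))
    assert fast.n_executed == slow.n_executed == 6
    assert fast.event_times[-1] < base.event_times[-1] < slow.event_times[-1]
    assert list(fast.event_order) == list(slow.event_order) == [0, 1, 2, 3, 4, 5]


def test_rescaling_preserves_interval_ratios(trained_sim1, params):
    """The inter-event-interval ratio vector is gain-invariant (within
    tolerance) across the tested gain range."""
    trained, _ = trained_sim1
    w, arch = trained.weights, trained.arch
    ratio_vectors = []
    for rho in (0.9, 1.0, 1.1, 1.2):
        sig = make_rescale_signal(rho, 6, window_ms=1300.0)
        rec = simulate_trial(w, arch, params, modulation=sig,
                             duration_ms=1300.0)
        iv = np.diff(rec.event_times)
        ratio_vectors.append(iv / iv.sum())
    ref = ratio_vectors[0]
    for v in ratio_vectors[1:]:
        np.testing.assert_allclose(v, ref, atol=0.03)


def test_sustain_signal_extends_action_until_successor(trained_sim1, params):
    """A weak NoGo gain sustains the second action's activity up to the
    third execution and strictly increases the sustainability measure."""
    trained, _ = trained_sim1
    w, arch = trained.weights, trained.arch
    base = simulate_trial(w, arch, params, duration_ms=1000.0)
    t1, t2 = base.event_times[1], base.event_times[2]
    sig = make_sustain_signal(1, t1 - 10.0, t2, 6, rho=0.1)
    rec = simulate_trial(w, arch, params, modulation=sig, duration_ms=1000.0)
    a1 = rec.a[:, 1]
    # supra-threshold from its execution until (just before) the third action
    span = np.flatnonzero(a1 > 0.5)
    assert span.min() <= t1 + 5
    assert span.max() >= rec.event_times[2] - 25.0
    assert sustainability_auc(rec) > sustainability_auc(base)


def test_weakened_an_coupling_sustains_and_is_monotone(trained_sim1, params):
    """Lower Action->NoGo coupling lengthens the supra-threshold span of its
    action; the span is monotone non-increasing in the coupling."""
    trained, _ = trained_sim1
    w, arch = trained.weights, trained.arch
    spans = []
    for j_na in (0.05, 0.3, 1.0):
        p = weaken_an_coupling(params, 2, j_na, 6)
        rec = simulate_trial(w, arch, p, duration_ms=1000.0)
        assert rec.n_executed == 6
        spans.append(int((rec.a[:, 2] > 0.5).sum()))
    assert spans[0] >= spans[1] >= spans[2]
    assert spans[0] > spans[2]
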