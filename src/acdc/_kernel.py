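"""Numba kernel for whole-trial Euler integration (hot path).

The same equations are implemented, vectorised in numpy, by
:func:`acdc.dynamics.step_network`; a test asserts numerical agreement
between the two routes. Activity vectors in the RNN are sparse (one cluster
of ~20 units active at a time), which the inner loops exploit by skipping
silent presynaptic units both in the drive sums and in the Hebbian update.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_trial_kernel"]

_EPS = 1e-12


@njit(cache=True, fastmath=False)
def _theta(v, lam):
    """Rectified sigmoid Theta(v) = max(0, 2 / (1 + exp(-lam v)) - 1)."""
    z = lam * v
    if z <= 0.0:
        return 0.0
    if z > 700.0:
        return 1.0
    t = 2.0 / (1.0 + np.exp(-z)) - 1.0
    return t if t > 0.0 else 0.0


@njit(cache=True, fastmath=False)
def run_trial_kernel(w_rec, w_go, w_ga,
                     fb_proj, input_mask, j_na_vec,
                     add_go, gain_go, gain_nogo, context,
                     noise_x, noise_i, noise_g, noise_n,
                     use_noise, noise_in_net,
                     plastic_rec, n_plastic_go, record_full, zero_diag,
                     gain_drive_only, gate_threshold, plateau_level,
                     context_until_onset,
                     ltp_fb_threshold, ltp_ctx_threshold,
                     dt_rec_learn, dt_go_learn,
                     dt, tau_rnn, tau_w, tau_g, tau_a, tau_n,
                     j_ei, j_ie, j_ia, j_gn, b,
                     lam_rnn, lam_a, x_in, gamma_i,
                     a1r, a2r, wmaxr, a1g, a2g, wmaxg):
    """Integrate one trial of T = len(context) Euler steps from a zero state.

    Weight arrays are updated in place when plasticity is enabled.
    ``plastic_rec`` switches the recurrent Hebbian site (globally on within a
    training trial); ``n_plastic_go`` is the number of recruited RNN->Go
    rows (0 .. n_plastic_go-1). A recruited row m potentiates only inside
    its association window -- after all predecessor actions have executed
    and before action m itself has -- and is depression-only outside it;
    rows not yet recruited stay frozen.

    Recurrent LTP additionally requires external feedforward drive on the
    postsynaptic unit: a thalamic feedback volley near its plateau
    (``ltp_fb_threshold``) or the context input (``ltp_ctx_threshold``).
    Assemblies therefore wire during the volley that recruits them --
    which, by the gamma_e/gamma_i geometry, opens only after the previous
    assembly has shut down -- while incidental co-activity (switch
    transients, cold-start flashes) leaves no potentiation.

    Action onsets are tracked against ``gate_threshold`` (well below the
    execution threshold, because the attractor switch begins while the
    Action node is still rising); the onset flags close/open the
    association windows and, when ``context_until_onset`` is set, withdraw
    the context input once the sequence has started.

    The two Hebbian sites integrate with their own learning steps
    (``dt_rec_learn`` for the recurrent site, ``dt_go_learn`` for RNN->Go):
    assembly formation is slow (rate constants per second, spanning trials)
    while Go recruitment is fast (per millisecond, maturing within a trial).
    A fast recurrent site would chain successive assemblies together during
    the ~15 ms of residual co-activity at every attractor switch.

    Returns (x_tr, xi_tr, g_tr, n_tr, a_tr): Action traces always span the
    trial; the other traces are recorded only when ``record_full`` is True.
    """
    n = w_rec.shape[0]
    k = w_ga.shape[0]
    t_steps = context.shape[0]

    x = np.zeros(n)
    xbar = np.zeros(n)
    xi = 0.0
    g = np.zeros(k)
    a = np.zeros(k)
    ng = np.zeros(k)

    a_tr = np.zeros((t_steps + 1, k))
    if record_full:
        x_tr = np.zeros((t_steps + 1, n))
        xi_tr = np.zeros(t_steps + 1)
        g_tr = np.zeros((t_steps + 1, k))
        n_tr = np.zeros((t_steps + 1, k))
    else:
        x_tr = np.zeros((1, n))
        xi_tr = np.zeros(1)
        g_tr = np.zeros((1, k))
        n_tr = np.zeros((1, k))

    drive = np.empty(n)
    ext = np.empty(n)
    x_new = np.empty(n)
    g_new = np.empty(k)
    a_new = np.empty(k)
    n_new = np.empty(k)
    fired = np.zeros(k, dtype=np.bool_)      # action onset reached (a >= gate)
    plateau = np.zeros(k, dtype=np.bool_)    # volley plateau reached

    for t in range(t_steps):
        # ---- excitatory RNN drive: recurrent + Action feedback + context ----
        for i in range(n):
            drive[i] = 0.0
            ext[i] = 0.0
        for j in range(n):
            xj = x[j]
            if xj > _EPS:
                for i in range(n):
                    drive[i] += w_rec[i, j] * xj
        for m in range(k):
            am = a[m]
            if am > _EPS:
                for i in range(n):
                    drive[i] += fb_proj[i, m] * am
                    ext[i] += fb_proj[i, m] * am
        cin = context[t] * x_in
        if context_until_onset and fired[0]:
            cin = 0.0

        sx = 0.0
        for i in range(n):
            sx += x[i]
        sa = 0.0
        for m in range(k):
            sa += a[m]

        # ---- excitatory units (Eq: tau_rnn dx = -x + Theta(net)) ----
        for i in range(n):
            net = drive[i] - j_ei * xi + cin * input_mask[i]
            th = _theta(net, lam_rnn)
            upd = (dt / tau_rnn) * (th - x[i])
            if use_noise:
                if noise_in_net:
                    upd += (dt / tau_rnn) * noise_x[t, i]
                else:
                    upd += noise_x[t, i]
            x_new[i] = x[i] + upd

        # ---- shared inhibitory unit ----
        net_i = j_ie * sx + j_ia * gamma_i * sa
        upd_i = (dt / tau_rnn) * (net_i - xi)
        if use_noise:
            if noise_in_net:
                upd_i += (dt / tau_rnn) * noise_i[t]
            else:
                upd_i += noise_i[t]
        xi_new = xi + upd_i

        # ---- Go accumulators (rectified) ----
        for m in range(k):
            gd = 0.0
            for j in range(n):
                xj = x[j]
                if xj > _EPS:
                    gd += w_go[m, j] * xj
            if gain_drive_only:
                net = gain_go[t, m] * gd - j_gn * ng[m] + add_go[t, m]
            else:
                net = gain_go[t, m] * (gd - j_gn * ng[m]) + add_go[t, m]
            upd = (dt / tau_g) * (net - g[m])
            if use_noise:
                if noise_in_net:
                    upd += (dt / tau_g) * noise_g[t, m]
                else:
                    upd += noise_g[t, m]
            gm = g[m] + upd
            g_new[m] = gm if gm > 0.0 else 0.0

        # ---- Action nodes (near-binary sigmoid; no noise) ----
        for m in range(k):
            th = _theta(w_ga[m] * g[m] - b, lam_a)
            anm = a[m] + (dt / tau_a) * (th - a[m])
            if anm >= gate_threshold:
                fired[m] = True
            if anm >= plateau_level:
                plateau[m] = True
            a_new[m] = anm

        # ---- NoGo nodes ----
        for m in range(k):
            net = gain_nogo[t, m] * (j_na_vec[m] * a[m])
            upd = (dt / tau_n) * (net - ng[m])
            if use_noise:
                if noise_in_net:
                    upd += (dt / tau_n) * noise_n[t, m]
                else:
                    upd += noise_n[t, m]
            n_new[m] = ng[m] + upd

        # ---- presynaptic low-pass trace ----
        for i in range(n):
            xbar[i] += (dt / tau_w) * (x[i] - xbar[i])

        for i in range(n):
            x[i] = x_new[i]
        xi = xi_new
        for m in range(k):
            g[m] = g_new[m]
            a[m] = a_new[m]
            ng[m] = n_new[m]

        # ---- fast Hebbian plasticity, clamped to [0, wmax] ----
        if plastic_rec or n_plastic_go > 0:
            # association window of row m: opens at the predecessor's volley
            # plateau (its cluster is then already extinguished), closes at
            # action m's own onset
            first_open = k
            for m in range(k):
                if not fired[m]:
                    if m == 0 or plateau[m - 1]:
                        first_open = m
                    break
            for j in range(n):
                pj = xbar[j]
                if pj > _EPS:
                    if plastic_rec:
                        for i in range(n):
                            if zero_diag and i == j:
                                continue
                            w = w_rec[i, j]
                            dw = -a1r * (1.0 - x[i]) * pj * dt_rec_learn
                            # LTP needs coincident feedforward drive (context
                            # or near-plateau thalamic volley) onto the
                            # postsynaptic unit
                            if (ltp_fb_threshold <= 0.0
                                    or ext[i] >= ltp_fb_threshold
                                    or cin * input_mask[i] >= ltp_ctx_threshold):
                                dw += a2r * x[i] * pj * (wmaxr - w) * dt_rec_learn
                            w += dw
                            if w < 0.0:
                                w = 0.0
                            elif w > wmaxr:
                                w = wmaxr
                            w_rec[i, j] = w
                    for m in range(n_plastic_go):
                        w = w_go[m, j]
                        dw = -a1g * (1.0 - g[m]) * pj * dt_go_learn
                        if m == first_open:  # potentiation is tutor-gated
                            dw += a2g * g[m] * pj * (wmaxg - w) * dt_go_learn
                        w += dw
                        if w < 0.0:
                            w = 0.0
                        elif w > wmaxg:
                            w = wmaxg
                        w_go[m, j] = w

        # ---- record ----
        for m in range(k):
            a_tr[t + 1, m] = a[m]
        if record_full:
            for i in range(n):
                x_tr[t + 1, i] = x[i]
            xi_tr[t + 1] = xi
            for m in range(k):
                g_tr[t + 1, m] = g[m]
                n_tr[t + 1, m] = ng[m]

    return x_tr, xi_tr, g_tr, n_tr, a_tr
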