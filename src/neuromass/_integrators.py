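"""Compiled inner loops (numba) for the network RK4 and microscopic QIF runs.

These kernels are deliberately free of Python objects: they take plain
arrays/scalars and fill preallocated output buffers.  Wrappers in
:mod:`neuromass.model` and :mod:`neuromass.qif` own validation, recording
grids and error handling.
"""
from __future__ import annotations

import numpy as np
from numba import njit

PI = np.pi


@njit(cache=True)
def _network_deriv(r, v, J, eta, i_const, i_stim, tau_m, delta, dr, dv):
    n = r.shape[0]
    coupling = np.dot(J, r)
    for k in range(n):
        dr[k] = (delta / (tau_m * PI) + 2.0 * r[k] * v[k]) / tau_m
        dv[k] = (
            v[k] * v[k]
            + eta[k]
            + i_const
            + i_stim[k]
            - (PI * tau_m * r[k]) ** 2
            + tau_m * coupling[k]
        ) / tau_m


@njit(cache=True)
def rk4_network(
    r,
    v,
    J,
    eta,
    i_const,
    tau_m,
    delta,
    dt,
    n_steps,
    stim_amp,
    stim_mask,
    on_step,
    off_step,
    stride,
    rec_r,
    rec_v,
):
    """Fixed-step RK4 of the multipopulation neural mass.

    The rectangular stimulus is constant within a step and active for
    ``on_step <= step < off_step``.  State is recorded every ``stride``
    steps (slot ``step // stride``) plus the final state in the last slot.
    Returns the step index of blow-up, or -1 on success.
    """
    n = r.shape[0]
    dr1 = np.empty(n)
    dv1 = np.empty(n)
    dr2 = np.empty(n)
    dv2 = np.empty(n)
    dr3 = np.empty(n)
    dv3 = np.empty(n)
    dr4 = np.empty(n)
    dv4 = np.empty(n)
    rt = np.empty(n)
    vt = np.empty(n)
    i_stim = np.zeros(n)

    rec_r[0] = r
    rec_v[0] = v
    n_rec = rec_r.shape[0]

    for step in range(n_steps):
        active = on_step <= step < off_step
        for k in range(n):
            i_stim[k] = stim_amp * stim_mask[k] if active else 0.0

        _network_deriv(r, v, J, eta, i_const, i_stim, tau_m, delta, dr1, dv1)
        for k in range(n):
            rt[k] = r[k] + 0.5 * dt * dr1[k]
            vt[k] = v[k] + 0.5 * dt * dv1[k]
        _network_deriv(rt, vt, J, eta, i_const, i_stim, tau_m, delta, dr2, dv2)
        for k in range(n):
            rt[k] = r[k] + 0.5 * dt * dr2[k]
            vt[k] = v[k] + 0.5 * dt * dv2[k]
        _network_deriv(rt, vt, J, eta, i_const, i_stim, tau_m, delta, dr3, dv3)
        for k in range(n):
            rt[k] = r[k] + dt * dr3[k]
            vt[k] = v[k] + dt * dv3[k]
        _network_deriv(rt, vt, J, eta, i_const, i_stim, tau_m, delta, dr4, dv4)
        ok = True
        for k in range(n):
            r[k] += dt / 6.0 * (dr1[k] + 2.0 * dr2[k] + 2.0 * dr3[k] + dr4[k])
            v[k] += dt / 6.0 * (dv1[k] + 2.0 * dv2[k] + 2.0 * dv3[k] + dv4[k])
            if not (np.isfinite(r[k]) and np.isfinite(v[k])):
                ok = False
        if not ok:
            return step
        slot = (step + 1) // stride
        if (step + 1) % stride == 0 and slot < n_rec:
            rec_r[slot] = r
            rec_v[slot] = v
    rec_r[n_rec - 1] = r
    rec_v[n_rec - 1] = v
    return -1


@njit(cache=True)
def qif_exact_map(
    V,
    eta,
    J,
    tau_m,
    i_const,
    dt,
    n_steps,
    V_clip,
    on_step,
    off_step,
    I_S,
    bin_steps,
    spike_bins,
    v_mean,
    v_median,
):
    """Exact per-step update of the all-to-all QIF network.

    Between synaptic kicks each membrane obeys tau_m dV/dt = V^2 + c with
    c = eta_i + I(t) constant over a step, a Riccati equation with closed
    form: for c > 0 the phase phi = atan(V/sqrt(c)) advances linearly and
    a spike is emitted at every wrap through pi/2 (the ideal infinite
    threshold/reset); for c < 0 the quantity atanh(V/a) (|V| < a = sqrt(-c))
    or atanh(a/V) (|V| > a) decreases linearly, spiking when the latter
    crosses zero.  Synaptic kicks of J/N per presynaptic spike (no
    autapses) are applied once per step.  The population-mean voltage is
    accumulated over V clipped to [-V_clip, V_clip], the numerical stand-in
    for the principal-value mean of the heavy-tailed voltage distribution;
    the per-bin sample median (``v_median``) estimates the centre of the
    Lorentzian voltage distribution directly and is the preferred
    finite-N estimator of the macroscopic v.  Returns -1 (the map cannot
    overflow).
    """
    N = V.shape[0]
    kick = J / N
    dtt = dt / tau_m
    n_bins = spike_bins.shape[0]
    mean_acc = np.zeros(n_bins)
    cnt = np.zeros(n_bins)
    own = np.zeros(N, dtype=np.int64)
    HALF_PI = 0.5 * np.pi

    for step in range(n_steps):
        b = step // bin_steps
        if b >= n_bins:
            b = n_bins - 1
        I_ext = i_const + (I_S if on_step <= step < off_step else 0.0)

        s = 0.0
        for i in range(N):
            Vi = V[i]
            if Vi > V_clip:
                Vi = V_clip
            elif Vi < -V_clip:
                Vi = -V_clip
            s += Vi
        mean_acc[b] += s / N
        if step % bin_steps == 0:
            v_median[b] = np.median(V)
        cnt[b] += 1.0

        n_spikes = 0
        for i in range(N):
            own[i] = 0
            c = eta[i] + I_ext
            Vi = V[i]
            if c > 1e-12:
                rc = np.sqrt(c)
                phi = np.arctan(Vi / rc) + rc * dtt
                if phi >= HALF_PI:
                    wraps = int((phi + HALF_PI) // np.pi)
                    spike_bins[b] += wraps
                    n_spikes += wraps
                    own[i] = wraps
                    phi -= np.pi * wraps
                V[i] = rc * np.tan(phi)
            elif c < -1e-12:
                a = np.sqrt(-c)
                if Vi > a:
                    u = np.arctanh(a / Vi) - a * dtt
                    if u <= 0.0:
                        spike_bins[b] += 1
                        n_spikes += 1
                        own[i] = 1
                        if u == 0.0:
                            u = -1e-300
                    V[i] = a / np.tanh(u)
                elif Vi < -a:
                    u = np.arctanh(a / Vi) - a * dtt
                    V[i] = a / np.tanh(u)
                else:
                    w = np.arctanh(Vi / a) - a * dtt
                    V[i] = a * np.tanh(w)
            else:
                # c ~ 0: dV/dt = V^2/tau, 1/V decreases linearly
                inv = 1.0 / Vi if Vi != 0.0 else 1e300
                inv -= dtt
                if Vi > 0.0 and inv <= 0.0:
                    spike_bins[b] += 1
                    n_spikes += 1
                    own[i] = 1
                    if inv == 0.0:
                        inv = -1e-300
                V[i] = 1.0 / inv

        if n_spikes > 0 and kick != 0.0:
            # no autapses: each neuron receives the other spikes only
            for i in range(N):
                V[i] += kick * (n_spikes - own[i])

    for b in range(n_bins):
        if cnt[b] > 0:
            v_mean[b] = mean_acc[b] / cnt[b]
    return -1


@njit(cache=True)
def qif_euler(
    V,
    eta,
    J,
    tau_m,
    i_const,
    dt,
    n_steps,
    V_peak,
    on_step,
    off_step,
    I_S,
    n_hold,
    phase,
    hold_left,
    bin_steps,
    spike_bins,
    v_mean,
    v_mean_masked,
):
    """Euler stepping of the all-to-all QIF network without autapses.

    Each presynaptic spike kicks every *other* membrane potential by J/N.
    A spiking neuron is held at +V_peak for ``n_hold`` steps and then at
    -V_peak for ``n_hold`` steps, emulating the excursion of the ideal
    neuron beyond the finite threshold (total 2*tau_m/V_peak ms); with
    ``n_hold = 0`` the reset is immediate.  Spikes are accumulated into
    1-ms bins (``spike_bins``) and the population-mean voltage is recorded
    per bin both over all neurons (``v_mean``) and excluding held neurons
    (``v_mean_masked``).  Returns the step of overflow, or -1.
    """
    N = V.shape[0]
    kick = J / N
    inv_tau = 1.0 / tau_m
    n_bins = spike_bins.shape[0]
    mean_acc = np.zeros(n_bins)
    mean_acc_masked = np.zeros(n_bins)
    mask_count = np.zeros(n_bins)
    spiked = np.zeros(N, dtype=np.uint8)

    for step in range(n_steps):
        b = step // bin_steps
        if b >= n_bins:
            b = n_bins - 1
        I_ext = i_const + (I_S if on_step <= step < off_step else 0.0)

        # record state at the start of the step
        s_all = 0.0
        s_masked = 0.0
        m = 0.0
        for i in range(N):
            s_all += V[i]
            if hold_left[i] == 0:
                s_masked += V[i]
                m += 1.0
        mean_acc[b] += s_all / N
        if m > 0:
            mean_acc_masked[b] += s_masked / m
        mask_count[b] += 1.0

        # advance free neurons; progress holds
        n_spikes = 0
        for i in range(N):
            spiked[i] = 0
            if hold_left[i] > 0:
                hold_left[i] -= 1
                if hold_left[i] == 0:
                    if phase[i] == 1 and n_hold > 0:
                        # switch from the +V_peak tail to the -V_peak tail
                        phase[i] = 2
                        V[i] = -V_peak
                        hold_left[i] = n_hold
                    else:
                        phase[i] = 0
                continue
            Vi = V[i]
            Vi = Vi + dt * (Vi * Vi + eta[i] + I_ext) * inv_tau
            if not np.isfinite(Vi):
                return step
            if Vi >= V_peak:
                n_spikes += 1
                spike_bins[b] += 1
                spiked[i] = 1
                if n_hold > 0:
                    V[i] = V_peak
                    phase[i] = 1
                    hold_left[i] = n_hold
                else:
                    V[i] = -V_peak
            else:
                V[i] = Vi

        if n_spikes > 0 and kick != 0.0:
            # no autapses: a spiking neuron receives the other spikes only;
            # held neurons (excursion beyond +/-V_peak) are insensitive to
            # finite synaptic input
            for i in range(N):
                if hold_left[i] == 0:
                    V[i] += kick * (n_spikes - spiked[i])

    for b in range(n_bins):
        if mask_count[b] > 0:
            v_mean[b] = mean_acc[b] / mask_count[b]
            v_mean_masked[b] = mean_acc_masked[b] / mask_count[b]
    return -1
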