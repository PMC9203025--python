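"""Numba-compiled time-stepping kernels (Euler–Maruyama, ms units).

Single-threaded and seeded through numba's np.random for bit-exact
reproducibility. Not part of the public API.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def lif_run(
    tau, E_L, E_thr, E_reset, E_Glu,
    g_Glu, g_GABA, E_GABA, sigma,
    dt, n_steps, seed, v0, record_stride,
):
    """Integrate one LIF neuron with constant conductances and white noise.

    Returns (spike_steps, spike_count, trace) where trace holds v sampled
    every ``record_stride`` steps (first sample is the initial condition).
    """
    np.random.seed(seed)
    v = v0
    spike_steps = np.empty(n_steps, dtype=np.int64)
    count = 0
    n_rec = n_steps // record_stride + 1
    trace = np.empty(n_rec, dtype=np.float64)
    trace[0] = v
    rec = 1
    noise_amp = sigma * np.sqrt(dt / tau)
    for step in range(n_steps):
        drift = -(v - E_L) - g_GABA * (v - E_GABA) - g_Glu * (v - E_Glu)
        v = v + (dt / tau) * drift
        if sigma > 0.0:
            v = v + noise_amp * np.random.normal()
        if v >= E_thr:
            spike_steps[count] = step
            count += 1
            v = E_reset
        if (step + 1) % record_stride == 0 and rec < n_rec:
            trace[rec] = v
            rec += 1
    return spike_steps[:count], count, trace[:rec]


@njit(cache=True)
def eif_kir_run(
    tau, E_L, E_reset, E_Glu,
    Delta_T, V_T, g_K, K, V_P, E_K,
    g_Glu, g_GABA, E_GABA, I_const, sigma,
    dt, n_steps, seed, v0, V_cut, record_stride,
):
    """Integrate one EIF-Kir neuron; spike when v >= V_cut, reset to E_reset.

    Returns (spike_steps, count, trace, max_overshoot) where max_overshoot is
    the largest v reached by a single step starting below V_T (a step-size
    diagnostic: the spike upswing itself always overshoots V_cut, but a jump
    from the sub-threshold region past V_cut means dt cannot resolve it).
    """
    np.random.seed(seed)
    v = v0
    spike_steps = np.empty(n_steps, dtype=np.int64)
    count = 0
    n_rec = n_steps // record_stride + 1
    trace = np.empty(n_rec, dtype=np.float64)
    trace[0] = v
    rec = 1
    noise_amp = sigma * np.sqrt(dt / tau)
    max_overshoot = v0
    for step in range(n_steps):
        v_prev = v
        arg = (v - V_T) / Delta_T
        if arg > 30.0:  # exponential already dominates; avoid overflow
            arg = 30.0
        I_exp = Delta_T * np.exp(arg)
        kir_g = g_K / (1.0 + np.exp((v - V_P) / K))
        drift = (
            -(v - E_L)
            - g_GABA * (v - E_GABA)
            - g_Glu * (v - E_Glu)
            + I_exp
            - kir_g * (v - E_K)
            + I_const
        )
        v = v + (dt / tau) * drift
        if sigma > 0.0:
            v = v + noise_amp * np.random.normal()
        if v >= V_cut:
            if v_prev < V_T and v > max_overshoot:
                max_overshoot = v
            spike_steps[count] = step
            count += 1
            v = E_reset
        if (step + 1) % record_stride == 0 and rec < n_rec:
            trace[rec] = v
            rec += 1
    return spike_steps[:count], count, trace[:rec], max_overshoot


@njit(cache=True)
def network_run(
    # neuron constants
    tau, E_L, E_thr, E_reset, E_Glu,
    # per-neuron arrays
    E_GABA_arr, amp_arr, v0_arr,
    # Poisson drive
    rate_per_ms, tau_kernel,
    # GABA PSC kernel
    tau1, tau2,
    # connectivity, CSR by presynaptic neuron: edges j -> post_idx[ptr[j]:ptr[j+1]]
    indptr, post_idx, weights,
    # integration
    dt, n_steps, transient_steps, seed,
    # recording
    vm_stride, record_vm, max_spikes,
):
    """Integrate the recurrent GABAergic network with filtered-Poisson drive.

    Each neuron receives an independent Poisson spike train (``rate_per_ms``
    events/ms) filtered by a first-order exponential kernel (``tau_kernel``)
    and scaled by its population's amplitude; recurrent spikes increment the
    two states of a difference-of-exponentials conductance kernel on their
    postsynaptic targets. Spike times are recorded up to ``max_spikes`` (counts
    are always complete); membrane potentials are sampled every ``vm_stride``
    steps after the transient when ``record_vm``.

    Returns (spike_t, spike_id, n_spikes_recorded, counts, vm, mean_gaba,
    mean_glu) where counts are post-transient per-neuron spike counts and the
    conductance means are post-transient time averages.
    """
    np.random.seed(seed)
    N = v0_arr.shape[0]
    v = v0_arr.copy()
    s1 = np.zeros(N)
    s2 = np.zeros(N)
    g_drive = np.zeros(N)

    decay_k = np.exp(-dt / tau_kernel)
    decay_1 = np.exp(-dt / tau1)
    decay_2 = np.exp(-dt / tau2)

    spike_t = np.empty(max_spikes, dtype=np.float64)
    spike_id = np.empty(max_spikes, dtype=np.int32)
    n_rec_spikes = 0
    counts = np.zeros(N, dtype=np.int64)

    n_vm = (n_steps - transient_steps) // vm_stride if record_vm else 0
    vm = np.empty((n_vm, N), dtype=np.float32)
    vm_row = 0

    mean_gaba = np.zeros(N)
    mean_glu = np.zeros(N)
    n_avg = 0

    for step in range(n_steps):
        post_transient = step >= transient_steps
        for i in range(N):
            k = np.random.poisson(rate_per_ms * dt)
            if k > 0:
                g_drive[i] += amp_arr[i] * k
            g_gaba = s1[i] - s2[i]
            drift = (
                -(v[i] - E_L)
                - g_gaba * (v[i] - E_GABA_arr[i])
                - g_drive[i] * (v[i] - E_Glu)
            )
            v[i] = v[i] + (dt / tau) * drift
            if post_transient:
                mean_gaba[i] += g_gaba
                mean_glu[i] += g_drive[i]
        if post_transient:
            n_avg += 1
            if record_vm and (step - transient_steps) % vm_stride == 0 and vm_row < n_vm:
                for i in range(N):
                    vm[vm_row, i] = v[i]
                vm_row += 1
        # decay synaptic states, then handle threshold crossings and propagate
        for i in range(N):
            s1[i] *= decay_1
            s2[i] *= decay_2
            g_drive[i] *= decay_k
        t_now = (step + 1) * dt
        for i in range(N):
            if v[i] >= E_thr:
                v[i] = E_reset
                if post_transient:
                    counts[i] += 1
                if n_rec_spikes < max_spikes:
                    spike_t[n_rec_spikes] = t_now
                    spike_id[n_rec_spikes] = i
                    n_rec_spikes += 1
                for e in range(indptr[i], indptr[i + 1]):
                    j = post_idx[e]
                    s1[j] += weights[e]
                    s2[j] += weights[e]
    for i in range(N):
        if n_avg > 0:
            mean_gaba[i] /= n_avg
            mean_glu[i] /= n_avg
    return (
        spike_t[:n_rec_spikes], spike_id[:n_rec_spikes], n_rec_spikes,
        counts, vm[:vm_row], mean_gaba, mean_glu,
    )
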