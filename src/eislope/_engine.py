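"""Compiled time-stepping kernel for the conductance-based LIF network.

The synapse is the alpha conductance g(t) = g_max (t/tau) exp(-t/tau),
integrated exactly per step through its equivalent two-state linear system

    dz/dt = -z/tau + (g_max/tau) * sum_k delta(t - t_k)
    dg/dt = -g/tau + z

whose step-h propagator is z' = d z, g' = d (g + h z) with d = exp(-h/tau).
Superposition over spikes is therefore exact to machine precision.  The
membrane equation C dV/dt = -g_L (V - V_rest) + sum_c g_c (E_c - V) + I_ext
is advanced with an exponential update (default; exact with conductances
frozen over the step), forward Euler, or RK4 evaluating the synaptic
conductances analytically at the substeps.

Threshold crossings are located by linear interpolation within the step;
the sub-step residual is carried as a time credit and integrated into the
first post-refractory step, so the per-spike phase error does not
accumulate (the step-halving contract: halving the step moves spike times
by less than the step itself).
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_UNSTABLE = 1


@njit(cache=True)
def run_network(
    n_steps,
    h,
    V,
    refr,
    z,
    g,
    decay,
    decay_half,
    tau,
    E_rev,
    exc_mask,
    V_th,
    V_reset,
    V_rest,
    g_L,
    C_m,
    I_ext,
    t_ref_steps,
    edge_ptr,
    edge_tgt,
    edge_chan,
    edge_amp,
    edge_delay,
    ring,
    drive_counts,
    drive_col0,
    drive_n,
    drive_tgt0,
    drive_chan,
    drive_amp,
    rec_ids,
    rec_every,
    V_out,
    Gex_out,
    Gin_out,
    spike_t,
    spike_id,
    V_lo,
    V_hi,
    method,
):
    N, C = g.shape
    t_extra = np.zeros(N)
    L = ring.shape[0]
    n_rec = rec_ids.shape[0]
    n_drives = drive_col0.shape[0]
    n_sp = 0
    samp = 0
    status = STATUS_OK
    bad_neuron = -1
    bad_step = -1

    for n in range(n_steps):
        slot = n % L
        # deliver delayed recurrent spikes scheduled for this step
        for i in range(N):
            for c in range(C):
                if ring[slot, i, c] != 0.0:
                    z[i, c] += ring[slot, i, c]
                    ring[slot, i, c] = 0.0
        # external Poisson drives (impulses at step start)
        for d in range(n_drives):
            c = drive_chan[d]
            a = drive_amp[d]
            t0 = drive_tgt0[d]
            c0 = drive_col0[d]
            for k in range(drive_n[d]):
                cnt = drive_counts[n, c0 + k]
                if cnt != 0:
                    z[t0 + k, c] += cnt * a
        # sample recorded traces at t = n*h (pre-update state)
        if n % rec_every == 0:
            for r in range(n_rec):
                i = rec_ids[r]
                V_out[samp, r] = V[i]
                ge = 0.0
                gi = 0.0
                for c in range(C):
                    if exc_mask[i, c]:
                        ge += g[i, c]
                    else:
                        gi += g[i, c]
                Gex_out[samp, r] = ge
                Gin_out[samp, r] = gi
            samp += 1
        # membrane update using start-of-step synaptic state
        for i in range(N):
            if refr[i] > 0:
                refr[i] -= 1
                V[i] = V_reset[i]
                continue
            v0 = V[i]
            v = v0
            hh = h + t_extra[i]
            t_extra[i] = 0.0
            if method == 0:
                # exponential update: exact for the membrane ODE with the
                # conductances frozen at their start-of-step values
                gtot = g_L[i]
                num = g_L[i] * V_rest[i] + I_ext[i]
                for c in range(C):
                    gtot += g[i, c]
                    num += g[i, c] * E_rev[i, c]
                vinf = num / gtot
                v = vinf + (v0 - vinf) * np.exp(-hh * gtot / C_m[i])
            elif method == 2:
                # conductances at substeps from the exact alpha solution
                gs0 = 0.0
                es0 = 0.0
                gsh = 0.0
                esh = 0.0
                gs1 = 0.0
                es1 = 0.0
                for c in range(C):
                    g0 = g[i, c]
                    z0 = z[i, c]
                    gh = decay_half[i, c] * (g0 + 0.5 * h * z0)
                    g1 = decay[i, c] * (g0 + h * z0)
                    gs0 += g0
                    es0 += g0 * E_rev[i, c]
                    gsh += gh
                    esh += gh * E_rev[i, c]
                    gs1 += g1
                    es1 += g1 * E_rev[i, c]
                inv_c = 1.0 / C_m[i]
                k1 = (-g_L[i] * (v - V_rest[i]) + es0 - gs0 * v + I_ext[i]) * inv_c
                v2 = v + 0.5 * hh * k1
                k2 = (-g_L[i] * (v2 - V_rest[i]) + esh - gsh * v2 + I_ext[i]) * inv_c
                v3 = v + 0.5 * hh * k2
                k3 = (-g_L[i] * (v3 - V_rest[i]) + esh - gsh * v3 + I_ext[i]) * inv_c
                v4 = v + hh * k3
                k4 = (-g_L[i] * (v4 - V_rest[i]) + es1 - gs1 * v4 + I_ext[i]) * inv_c
                v = v + hh * (k1 + 2.0 * k2 + 2.0 * k3 + k4) / 6.0
            else:
                isyn = 0.0
                for c in range(C):
                    isyn += g[i, c] * (E_rev[i, c] - v)
                v = v + hh * (-g_L[i] * (v - V_rest[i]) + isyn + I_ext[i]) / C_m[i]
            if v < V_lo or v > V_hi:
                status = STATUS_UNSTABLE
                bad_neuron = i
                bad_step = n
                return n_sp, samp, status, bad_neuron, bad_step
            if v >= V_th[i]:
                dv = v - v0
                theta = (V_th[i] - v0) / dv if dv > 1e-12 else 1.0
                resid = (1.0 - theta) * hh  # time past threshold, < one step
                spike_t[n_sp] = (n + 1) * h - resid
                spike_id[n_sp] = i
                n_sp += 1
                t_extra[i] = resid
                V[i] = V_reset[i]
                refr[i] = t_ref_steps[i]
                for e in range(edge_ptr[i], edge_ptr[i + 1]):
                    ring[(n + edge_delay[e]) % L, edge_tgt[e], edge_chan[e]] += edge_amp[e]
            else:
                V[i] = v
        # exact alpha-synapse update over [n h, (n+1) h]
        for i in range(N):
            for c in range(C):
                d0 = decay[i, c]
                g[i, c] = d0 * (g[i, c] + h * z[i, c])
                z[i, c] = d0 * z[i, c]

    return n_sp, samp, status, bad_neuron, bad_step


@njit(cache=True)
def alpha_train(spike_steps, amps, n_steps, h, tau):
    """Exact discrete conductance trace for a train of input impulses.

    ``spike_steps`` are integer step indices; ``amps`` the z-impulse
    amplitudes (g_max/tau per spike).  Returns g sampled at every step.
    Shares the propagator of :func:`run_network`, so it is the engine's own
    single-synapse restriction (used for shot-noise generation and tests).
    """
    d = np.exp(-h / tau)
    g = 0.0
    zz = 0.0
    out = np.zeros(n_steps)
    k = 0
    m = spike_steps.shape[0]
    for n in range(n_steps):
        while k < m and spike_steps[k] == n:
            zz += amps[k]
            k += 1
        out[n] = g
        gn = d * (g + h * zz)
        zz = d * zz
        g = gn
    return out
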