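"""Numba inner loops for the spiking and rate network simulations.

One compiled kernel advances a closed-loop network (static reservoir plus
low-rank learned feedback) for a block of forward-Euler steps, optionally
applying recursive-least-squares decoder updates on a fixed stride.  The
static reservoir matrix-vector product dominates the runtime and is
evaluated as a dense float32 BLAS product (at the sparsities studied here
the matrix is 30-40% filled, where dense SIMD beats sparse gathers);
everything else — neuron state, synaptic filters, decoder, and the RLS
inverse-correlation matrix — is float64.

All times inside the kernel are milliseconds.
"""

from __future__ import annotations

import numpy as np
from numba import njit

KIND_SPIKING = 0
KIND_RATE = 1

STATUS_OK = 0
STATUS_NONFINITE = 1
STATUS_RLS_BREAKDOWN = 2

#: guard above threshold below which the transfer function returns zero (mV)
RATE_EPS = 1e-12

#: RLS updates between defensive re-symmetrizations of P
SYM_EVERY = 100

#: conversion from spikes/ms (the unit of the transfer function with ms
#: constants) to spikes/s.  The synaptic filters carry this factor so the
#: postsynaptic currents r are firing rates in Hz — the scale on which the
#: RLS learning rates alpha are calibrated (identical to integrating the
#: filter equations in SI seconds).
RATE_SCALE = 1000.0


@njit(cache=True)
def rate_transfer_scalar(I, tau_ref, tau_m, v_reset, v_th):
    if I <= v_th + RATE_EPS:
        return 0.0
    return 1.0 / (tau_ref - tau_m * np.log((I - v_th) / (I - v_reset)))


@njit(cache=True)
def simulate_block(
    kind,
    n_steps,
    dt,
    # static weights: dense G * omega0 (float32, BLAS matvec), and Q * eta
    w32,
    qeta,
    # decoder (N, M), updated in place when do_rls
    phi,
    # external input: ext_enc (N, n_in), ext (n_in, n_steps); n_in may be 0
    ext_enc,
    ext,
    # neuron parameters (ms / mV)
    tau_r,
    tau_d,
    tau_m,
    tau_ref,
    v_reset,
    v_th,
    i_bias,
    # state vectors (N,), updated in place; v/refrac ignored for rate kind
    v,
    refrac,
    h,
    r,
    # RLS training
    do_rls,
    P,
    target,
    rls_every,
    # recording
    readout_out,  # (M, n_steps)
    sample_idx,  # (S,) int64 neuron indices
    sample_stride,
    sample_r_out,  # (S, n_samp)
    sample_i_out,  # (S, n_samp) or (0, 0)
    record_spikes,
    spike_neuron,  # (cap,) int32
    spike_step,  # (cap,) int64
    # per-update decoder diagnostics; sized (n_updates,) or (0,)
    phi_norm_out,
    dphi_norm_out,
    err_out,
    # full decoder snapshots every snap_every updates; (n_snap, N, M) or (0,0,0)
    phi_snap_out,
    snap_every,
):
    N = r.shape[0]
    M = phi.shape[1]
    n_in = ext_enc.shape[1]
    S = sample_idx.shape[0]
    cap = spike_neuron.shape[0]

    r32 = np.empty(N, dtype=np.float32)
    I = np.empty(N, dtype=np.float64)
    xhat = np.empty(M, dtype=np.float64)
    e = np.empty(M, dtype=np.float64)

    n_spikes = 0
    n_updates = 0
    n_since_sym = 0
    status = STATUS_OK
    bad_step = -1
    spiked = np.zeros(N, dtype=np.bool_)

    inv_tau_m = 1.0 / tau_m
    h_jump = RATE_SCALE / (tau_r * tau_d)
    drive = RATE_SCALE / (tau_r * tau_d)

    for t in range(n_steps):
        # readout from the basis entering this step
        finite = True
        for m in range(M):
            s = 0.0
            for i in range(N):
                s += phi[i, m] * r[i]
            xhat[m] = s
            readout_out[m, t] = s
            if not np.isfinite(s):
                finite = False
        if not finite:
            status = STATUS_NONFINITE
            bad_step = t
            break

        # input current: bias + G*omega0 @ r + Q*eta @ xhat + external
        for i in range(N):
            r32[i] = r[i]
        Iw = np.dot(w32, r32)
        for i in range(N):
            acc = Iw[i] + i_bias
            for m in range(M):
                acc += qeta[i, m] * xhat[m]
            for j in range(n_in):
                acc += ext_enc[i, j] * ext[j, t]
            I[i] = acc

        # sampled traces (state entering the step)
        if S > 0 and t % sample_stride == 0:
            ks = t // sample_stride
            for s_i in range(S):
                sample_r_out[s_i, ks] = r[sample_idx[s_i]]
            if sample_i_out.shape[0] > 0:
                for s_i in range(S):
                    sample_i_out[s_i, ks] = I[sample_idx[s_i]]

        # RLS decoder update on its own clock, using the same (r, xhat) pair
        if do_rls and t % rls_every == 0:
            Pr = np.dot(P, r)
            rPr = 0.0
            for i in range(N):
                rPr += r[i] * Pr[i]
            denom = 1.0 + rPr
            if denom <= 0.0 or not np.isfinite(denom):
                status = STATUS_RLS_BREAKDOWN
                bad_step = t
                break
            inv_den = 1.0 / denom
            # P <- P - Pr Pr^T / denom, row-wise (contiguous, vectorizable);
            # the rank-1 term is exactly symmetric, so asymmetry only
            # accumulates from round-off (~1e-16/update) and is scrubbed
            # by a periodic defensive symmetrization
            for i in range(N):
                pri = Pr[i] * inv_den
                for j in range(N):
                    P[i, j] -= pri * Pr[j]
            n_since_sym += 1
            if n_since_sym >= SYM_EVERY:
                n_since_sym = 0
                for i in range(N):
                    for j in range(i + 1, N):
                        val = 0.5 * (P[i, j] + P[j, i])
                        P[i, j] = val
                        P[j, i] = val
            dphi_sq = 0.0
            err_sq = 0.0
            for m in range(M):
                e[m] = xhat[m] - target[m, t]
                err_sq += e[m] * e[m]
            for i in range(N):
                ci = Pr[i] * inv_den
                for m in range(M):
                    upd = ci * e[m]
                    phi[i, m] -= upd
                    dphi_sq += upd * upd
            if phi_norm_out.shape[0] > 0:
                pn = 0.0
                for i in range(N):
                    for m in range(M):
                        pn += phi[i, m] * phi[i, m]
                phi_norm_out[n_updates] = np.sqrt(pn)
                dphi_norm_out[n_updates] = np.sqrt(dphi_sq)
                err_out[n_updates] = np.sqrt(err_sq)
            if snap_every > 0 and n_updates % snap_every == 0:
                ks = n_updates // snap_every
                if ks < phi_snap_out.shape[0]:
                    for i in range(N):
                        for m in range(M):
                            phi_snap_out[ks, i, m] = phi[i, m]
            n_updates += 1

        # neuron update
        if kind == KIND_SPIKING:
            for i in range(N):
                if refrac[i] > 0.0:
                    refrac[i] -= dt
                    v[i] = v_reset
                    spiked[i] = False
                else:
                    v[i] += dt * (I[i] - v[i]) * inv_tau_m
                    if v[i] >= v_th:
                        spiked[i] = True
                        v[i] = v_reset
                        refrac[i] = tau_ref
                        if record_spikes and n_spikes < cap:
                            spike_neuron[n_spikes] = i
                            spike_step[n_spikes] = t
                        n_spikes += 1
                    else:
                        spiked[i] = False
            decay_h = 1.0 - dt / tau_r
            decay_r = 1.0 - dt / tau_d
            for i in range(N):
                h[i] *= decay_h
                if spiked[i]:
                    h[i] += h_jump
                r[i] = r[i] * decay_r + dt * h[i]
        else:
            decay_h = 1.0 - dt / tau_r
            decay_r = 1.0 - dt / tau_d
            for i in range(N):
                R = rate_transfer_scalar(I[i], tau_ref, tau_m, v_reset, v_th)
                h[i] = h[i] * decay_h + dt * R * drive
                r[i] = r[i] * decay_r + dt * h[i]

    return n_spikes, n_updates, status, bad_step
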