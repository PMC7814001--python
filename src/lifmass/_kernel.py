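"""Numba inner loop of the Euler-Maruyama LIF integration.

Kept free of Python objects so the whole time-stepping loop compiles to
machine code.  Single-threaded on purpose: bit-level reproducibility of
the RNG stream matters more here than parallel speed-up.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_lif_kernel"]


@njit(nogil=True)
def run_lif_kernel(
    seed,
    n_steps,
    dt,
    v0,
    is_exc,
    sub_mask,
    out_indptr,
    out_indices,
    ext_lam,
    v_leak,
    v_thres,
    v_reset,
    v_rev_exc,
    v_rev_inh,
    v_rev_ext,
    tau_mem,
    tau_e,
    tau_i,
    tau_x,
    n_ref_steps,
    g_leak,
    ghat_e,
    ghat_i,
    ghat_x,
    noise_amp,
    g_ext_clamp,
):
    np.random.seed(seed)
    n = v0.size
    n_sub = 0
    for i in range(n):
        if sub_mask[i]:
            n_sub += 1

    v = v0.copy()
    g_e = np.zeros(n)
    g_i = np.zeros(n)
    g_x = np.zeros(n)
    if g_ext_clamp >= 0.0:
        for i in range(n):
            g_x[i] = g_ext_clamp
    refr = np.zeros(n, dtype=np.int64)
    c_e = np.zeros(n)
    c_i = np.zeros(n)
    c_x = np.zeros(n)

    phi_e = np.zeros(n_steps)
    phi_i = np.zeros(n_steps)
    phi_x = np.zeros(n_steps)
    vtrace = np.zeros(n_steps + 1)

    acc0 = 0.0
    for i in range(n):
        if sub_mask[i]:
            acc0 += v[i]
    vtrace[0] = acc0 / n_sub

    cap = 1024
    sp_unit = np.empty(cap, dtype=np.int64)
    sp_step = np.empty(cap, dtype=np.int64)
    n_sp = 0

    inv_sub_dt = 1.0 / (n_sub * dt)
    clamp_ext = g_ext_clamp >= 0.0
    use_noise = noise_amp > 0.0

    for k in range(n_steps):
        # external Poisson arrivals for bin k
        tot_x = 0.0
        for i in range(n):
            if ext_lam[i] > 0.0:
                c = np.random.poisson(ext_lam[i])
                c_x[i] = c
                if sub_mask[i]:
                    tot_x += c
            else:
                c_x[i] = 0.0
        phi_x[k] = tot_x * inv_sub_dt

        tot_e = 0.0
        tot_i = 0.0
        for i in range(n):
            if sub_mask[i]:
                tot_e += c_e[i]
                tot_i += c_i[i]
        phi_e[k] = tot_e * inv_sub_dt
        phi_i[k] = tot_i * inv_sub_dt

        # membrane update with conductances at the left endpoint
        for i in range(n):
            if refr[i] > 0:
                refr[i] -= 1
                v[i] = v_reset
            else:
                syn = (
                    g_e[i] * (v[i] - v_rev_exc)
                    + g_i[i] * (v[i] - v_rev_inh)
                    + g_x[i] * (v[i] - v_rev_ext)
                )
                dv = (-(v[i] - v_leak) - syn / g_leak) * dt / tau_mem
                if use_noise:
                    dv += noise_amp * np.random.normal()
                v[i] += dv
                if not np.isfinite(v[i]):
                    return (
                        sp_unit[:n_sp],
                        sp_step[:n_sp],
                        phi_e,
                        phi_i,
                        phi_x,
                        vtrace,
                        k,
                        i,
                    )

        # exponential synapse relaxation plus per-spike jump ghat/tau
        for i in range(n):
            g_e[i] += (dt / tau_e) * (-g_e[i]) + (ghat_e / tau_e) * c_e[i]
            g_i[i] += (dt / tau_i) * (-g_i[i]) + (ghat_i / tau_i) * c_i[i]
            if not clamp_ext:
                g_x[i] += (dt / tau_x) * (-g_x[i]) + (ghat_x / tau_x) * c_x[i]
            c_e[i] = 0.0
            c_i[i] = 0.0

        # threshold crossings: spike at t_{k+1}, delivered during bin k+1
        for i in range(n):
            if refr[i] == 0 and v[i] >= v_thres:
                v[i] = v_reset
                refr[i] = n_ref_steps
                if n_sp == cap:
                    cap *= 2
                    new_u = np.empty(cap, dtype=np.int64)
                    new_s = np.empty(cap, dtype=np.int64)
                    new_u[:n_sp] = sp_unit
                    new_s[:n_sp] = sp_step
                    sp_unit = new_u
                    sp_step = new_s
                sp_unit[n_sp] = i
                sp_step[n_sp] = k + 1
                n_sp += 1
                exc = is_exc[i]
                for j in range(out_indptr[i], out_indptr[i + 1]):
                    t = out_indices[j]
                    if exc:
                        c_e[t] += 1.0
                    else:
                        c_i[t] += 1.0

        acc = 0.0
        for i in range(n):
            if sub_mask[i]:
                acc += v[i]
        vtrace[k + 1] = acc / n_sub

    return (
        sp_unit[:n_sp].copy(),
        sp_step[:n_sp].copy(),
        phi_e,
        phi_i,
        phi_x,
        vtrace,
        -1,
        -1,
    )
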