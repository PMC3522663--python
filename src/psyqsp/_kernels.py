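"""Numba-compiled integration kernels.

Two fixed-step integrators live here:

* ``synapse_cycle`` — mass-action receptor competition in a well-stirred
  synaptic cleft.  Free neurotransmitter (NT) is driven by spike-triggered
  release pulses and first-order clearance; an arbitrary number of receptor
  *pools* (postsynaptic subtypes plus an optional autoreceptor pool) bind the
  NT and any number of clamped-concentration ligands (drug species, tracer).
  Autoreceptor activation feeds back onto release through a sigmoid gain.

* ``msn_step_run`` — single-compartment Hodgkin-Huxley medium spiny neuron
  with instantaneous Na activation, Na inactivation and delayed-rectifier
  gates, an inward-rectifier (Kir2) Boltzmann conductance, an exponential
  excitatory synapse driven by a precomputed afferent impulse train, and a
  background current.  Gates and voltage advance by exponential Euler, which
  is unconditionally stable at the 0.2 ms default step.

Both kernels are deterministic: all stochasticity (afferent spike trains)
is generated outside and passed in as arrays.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Synapse competition kernel
# ---------------------------------------------------------------------------


@njit(cache=False)
def synapse_cycle(
    state,            # (2 + P*L,) [C_ext, C_cleft, b_flat...]
    n_steps,
    dt,
    release_pulses,   # (n_steps,) NT amount (nM) added per step before feedback scaling
    clearance,        # per s (extrasynaptic; low-concentration limit)
    clearance_km,     # nM; 0 disables transporter saturation (extrasynaptic)
    cleft_scale,      # release scale factor for the cleft compartment
    cleft_clearance,  # per s, first-order (diffusional) cleft clearance
    kon,              # (P, L) per nM per s
    koff,             # (P, L) per s
    conc,             # (L,) clamped ligand concentrations; entry 0 (NT) ignored
    pool_comp,        # (P,) 0 = extrasynaptic compartment, 1 = cleft
    auto_pool,        # int, -1 if no autoreceptor feedback
    act_weight,       # (L,) activation weight of each ligand at the autoreceptor
    gain, a_half, a_width,
    continuous,       # bool: treat release as a continuous infusion rate
    record,           # bool: fill the series outputs
    c_series,         # (n_steps, 2)
    b_series,         # (n_steps, P, L)
):
    """Integrate one period; returns (final_state, b_avg(P,L), c_avg(2,))."""
    P, L = kon.shape
    C = state[0]
    C2 = state[1]
    b = state[2:].copy().reshape(P, L)
    out_state = np.empty_like(state)
    b_sum = np.zeros((P, L))
    c_sum = 0.0
    c2_sum = 0.0
    decay = math.exp(-clearance * dt)
    decay2 = math.exp(-cleft_clearance * dt)
    # per-ligand relaxation factors for clamped concentrations (l >= 1):
    # db/dt = A - B*b with B = kon*c + koff constant -> exact exponential step
    bdec = np.empty((P, L))
    brate = np.empty((P, L))
    for p in range(P):
        for l in range(1, L):
            brate[p, l] = kon[p, l] * conc[l] + koff[p, l]
            bdec[p, l] = math.exp(-brate[p, l] * dt)
    for i in range(n_steps):
        # autoreceptor feedback on release
        s = 1.0
        if auto_pool >= 0 and gain != 0.0:
            a = 0.0
            for l in range(L):
                a += act_weight[l] * b[auto_pool, l]
            s = 1.0 + gain / (1.0 + math.exp((a - a_half) / a_width))
        if continuous:
            rate = release_pulses[i] * s / dt
            # exact update for constant infusion + first-order cleft clearance
            C2 = C2 * decay2 + (rate * cleft_scale / cleft_clearance) * (1.0 - decay2)
            if clearance_km == 0.0:
                C = C * decay + (rate / clearance) * (1.0 - decay)
        elif release_pulses[i] > 0.0:
            C += release_pulses[i] * s
            C2 += release_pulses[i] * s * cleft_scale
        # receptor binding: per-ligand exact exponential step with the other
        # ligands' occupancies frozen (quasi-static).  The running total is
        # refreshed after each ligand (Gauss-Seidel sweep), which keeps the
        # sweep stable when several fast ligands equilibrate within one step;
        # the fixed point is the exact competitive equilibrium either way.
        for p in range(P):
            btot = 0.0
            for l in range(L):
                btot += b[p, l]
            C_here = C2 if pool_comp[p] == 1 else C
            for l in range(L):
                c_l = C_here if l == 0 else conc[l]
                free_excl = 1.0 - (btot - b[p, l])
                if free_excl < 0.0:
                    free_excl = 0.0
                if l == 0:
                    B = kon[p, 0] * c_l + koff[p, 0]
                    dec_l = math.exp(-B * dt)
                else:
                    B = brate[p, l]
                    dec_l = bdec[p, l]
                if B > 0.0:
                    A = kon[p, l] * c_l * free_excl
                    bnew = b[p, l] * dec_l + (A / B) * (1.0 - dec_l)
                    btot += bnew - b[p, l]
                    b[p, l] = bnew
        # clearance: saturable transporter (Michaelis-Menten) or first-order
        if clearance_km > 0.0:
            C -= dt * clearance * clearance_km * C / (clearance_km + C)
            if C < 0.0:
                C = 0.0
            elif C > 1e9:
                # ceiling for the fully disinhibited, transporter-saturated
                # regime (release exceeding clearance capacity); keeps the
                # cycle map finite -- receptors are saturated long before this
                C = 1e9
        elif not continuous:
            C *= decay
        if not continuous:
            C2 *= decay2
        c_sum += C
        c2_sum += C2
        for p in range(P):
            for l in range(L):
                b_sum[p, l] += b[p, l]
        if record:
            c_series[i, 0] = C
            c_series[i, 1] = C2
            for p in range(P):
                for l in range(L):
                    b_series[i, p, l] = b[p, l]
    out_state[0] = C
    out_state[1] = C2
    out_state[2:] = b.ravel()
    c_avg = np.empty(2)
    c_avg[0] = c_sum / n_steps
    c_avg[1] = c2_sum / n_steps
    return out_state, b_sum / n_steps, c_avg


# ---------------------------------------------------------------------------
# MSN Hodgkin-Huxley kernel
# ---------------------------------------------------------------------------


@njit(cache=False, fastmath=True)
def _vtrap(x, y):
    # x / (1 - exp(-x/y)) with the removable singularity handled
    if abs(x / y) < 1e-6:
        return y * (1.0 - x / y / 2.0) ** -1
    return x / (1.0 - math.exp(-x / y))


@njit(cache=False, fastmath=True)
def msn_step_run(
    n_steps,
    dt_ms,            # integration step, ms
    g_imp,            # (n_steps,) excitatory conductance increments (mS/cm^2)
    i_bg,             # background current, uA/cm^2
    cm,               # uF/cm^2
    g_na, e_na,
    g_kdr, e_k,
    g_leak, e_leak,
    g_kir, kir_vh, kir_vc, kir_mod,
    tau_syn_ms, e_syn,
    v0,
    spike_thresh_mv,
    refrac_ms,
    v_series,         # (n_steps,) filled if record
    record,
):
    """Integrate the MSN; returns spike count over the window."""
    V = v0
    # gate initial conditions at steady state for v0
    am = 0.32 * _vtrap(V + 54.0, 4.0)
    bm = 0.28 * _vtrap(-(V + 27.0), 5.0)
    ah = 0.128 * math.exp(-(V + 50.0) / 18.0)
    bh = 4.0 / (1.0 + math.exp(-(V + 27.0) / 5.0))
    an = 0.032 * _vtrap(V + 52.0, 5.0)
    bn = 0.5 * math.exp(-(V + 57.0) / 40.0)
    h = ah / (ah + bh)
    n = an / (an + bn)
    g_e = 0.0
    syn_decay = math.exp(-dt_ms / tau_syn_ms)
    n_spikes = 0
    refrac_until = -1.0
    prev_above = V >= spike_thresh_mv
    t = 0.0
    for i in range(n_steps):
        g_e = g_e * syn_decay + g_imp[i]
        # rate constants (1/ms)
        am = 0.32 * _vtrap(V + 54.0, 4.0)
        bm = 0.28 * _vtrap(-(V + 27.0), 5.0)
        ah = 0.128 * math.exp(-(V + 50.0) / 18.0)
        bh = 4.0 / (1.0 + math.exp(-(V + 27.0) / 5.0))
        an = 0.032 * _vtrap(V + 52.0, 5.0)
        bn = 0.5 * math.exp(-(V + 57.0) / 40.0)
        m = am / (am + bm)  # instantaneous activation
        # exponential Euler on h, n
        tau_h = 1.0 / (ah + bh)
        h_inf = ah * tau_h
        h += (h_inf - h) * (1.0 - math.exp(-dt_ms / tau_h))
        tau_n = 1.0 / (an + bn)
        n_inf = an * tau_n
        n += (n_inf - n) * (1.0 - math.exp(-dt_ms / tau_n))
        # conductances
        gna = g_na * m * m * m * h
        gkdr = g_kdr * n * n * n * n
        gkir = g_kir * kir_mod / (1.0 + math.exp((V - kir_vh) / kir_vc))
        g_tot = gna + gkdr + gkir + g_leak + g_e
        i_drive = (
            gna * e_na + (gkdr + gkir) * e_k + g_leak * e_leak + g_e * e_syn + i_bg
        )
        v_inf = i_drive / g_tot
        V += (v_inf - V) * (1.0 - math.exp(-dt_ms * g_tot / cm))
        above = V >= spike_thresh_mv
        if above and not prev_above and t >= refrac_until:
            n_spikes += 1
            refrac_until = t + refrac_ms
        prev_above = above
        if record:
            v_series[i] = V
        t += dt_ms
    return n_spikes


V_TABLE_MIN = -130.0
V_TABLE_MAX = 60.0
V_TABLE_STEP = 0.02


def build_msn_tables(dt_ms, kir_vh, kir_vc):
    """Voltage-grid tables for the MSN gate kinetics and Kir2 activation.

    The gate rate functions depend only on V and dt, the Kir2 Boltzmann only
    on V and its fixed half/slope parameters, so the tables are reusable
    across coupling evaluations (conductance scalings multiply outside).
    Returns (m3, h_inf, h_dec, n_inf, n_dec, kir_act).
    """
    v = np.arange(V_TABLE_MIN, V_TABLE_MAX + V_TABLE_STEP, V_TABLE_STEP)

    def vtrap(x, y):
        out = np.empty_like(x)
        small = np.abs(x / y) < 1e-6
        out[~small] = x[~small] / (1.0 - np.exp(-x[~small] / y))
        out[small] = y / (1.0 - x[small] / y / 2.0)
        return out

    am = 0.32 * vtrap(v + 54.0, 4.0)
    bm = 0.28 * vtrap(-(v + 27.0), 5.0)
    ah = 0.128 * np.exp(-(v + 50.0) / 18.0)
    bh = 4.0 / (1.0 + np.exp(-(v + 27.0) / 5.0))
    an = 0.032 * vtrap(v + 52.0, 5.0)
    bn = 0.5 * np.exp(-(v + 57.0) / 40.0)
    m = am / (am + bm)
    tau_h = 1.0 / (ah + bh)
    tau_n = 1.0 / (an + bn)
    return (
        m**3,
        ah * tau_h,
        1.0 - np.exp(-dt_ms / tau_h),
        an * tau_n,
        1.0 - np.exp(-dt_ms / tau_n),
        1.0 / (1.0 + np.exp((v - kir_vh) / kir_vc)),
    )


@njit(cache=False, fastmath=True)
def msn_table_run(
    n_steps,
    dt_ms,
    g_imp,            # (n_steps,) excitatory conductance increments (mS/cm^2)
    i_bg,
    cm,
    g_na, e_na,
    g_kdr, e_k,
    g_leak, e_leak,
    g_kir_eff,        # kir2_gmax * modulation factor
    tau_syn_ms, e_syn,
    v0,
    spike_thresh_mv,
    refrac_ms,
    m3_t, hinf_t, hdec_t, ninf_t, ndec_t, kir_t,
    v_series,
    record,
):
    """Table-driven variant of :func:`msn_step_run` (same dynamics)."""
    inv_step = 1.0 / V_TABLE_STEP
    n_tab = len(m3_t)
    V = v0
    idx = int((V - V_TABLE_MIN) * inv_step)
    h = hinf_t[idx]
    n = ninf_t[idx]
    g_e = 0.0
    syn_decay = math.exp(-dt_ms / tau_syn_ms)
    n_spikes = 0
    refrac_until = -1.0
    prev_above = V >= spike_thresh_mv
    t = 0.0
    for i in range(n_steps):
        g_e = g_e * syn_decay + g_imp[i]
        idx = int((V - V_TABLE_MIN) * inv_step)
        if idx < 0:
            idx = 0
        elif idx >= n_tab:
            idx = n_tab - 1
        h += (hinf_t[idx] - h) * hdec_t[idx]
        n += (ninf_t[idx] - n) * ndec_t[idx]
        gna = g_na * m3_t[idx] * h
        gkdr = g_kdr * n * n * n * n
        gkir = g_kir_eff * kir_t[idx]
        g_tot = gna + gkdr + gkir + g_leak + g_e
        i_drive = (
            gna * e_na + (gkdr + gkir) * e_k + g_leak * e_leak + g_e * e_syn + i_bg
        )
        v_inf = i_drive / g_tot
        V += (v_inf - V) * (1.0 - math.exp(-dt_ms * g_tot / cm))
        above = V >= spike_thresh_mv
        if above and not prev_above and t >= refrac_until:
            n_spikes += 1
            refrac_until = t + refrac_ms
        prev_above = above
        if record:
            v_series[i] = V
        t += dt_ms
    return n_spikes


def warmup():
    """Force JIT compilation of both kernels (small dummy problems)."""
    state = np.zeros(2 + 2 * 2)
    synapse_cycle(
        state, 10, 1e-3, np.zeros(10), 25.0, 0.0, 1.0, 25.0,
        np.full((2, 2), 1e-3), np.full((2, 2), 1e-2), np.zeros(2),
        np.zeros(2, dtype=np.int64),
        -1, np.zeros(2), 0.0, 0.5, 0.05,
        False, False, np.zeros((10, 2)), np.zeros((10, 2, 2)),
    )
    msn_step_run(
        10, 0.2, np.zeros(10), 0.0, 1.0,
        100.0, 50.0, 80.0, -90.0, 0.1, -67.0,
        1.2, -111.0, -11.0, 1.0, 3.0, 0.0,
        -85.0, 0.0, 2.0, np.zeros(10), False,
    )
    tabs = build_msn_tables(0.2, -111.0, -11.0)
    msn_table_run(
        10, 0.2, np.zeros(10), 0.0, 1.0,
        100.0, 50.0, 80.0, -90.0, 0.1, -67.0,
        1.2, 3.0, 0.0, -85.0, 0.0, 2.0,
        *tabs, np.zeros(10), False,
    )
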