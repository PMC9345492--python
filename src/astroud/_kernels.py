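"""Numba kernels for the rate and spiking simulators.

The kernels are deliberately free of Python objects: parameters are passed
as scalars and preallocated arrays so numba can compile tight loops.  The
public API in :mod:`astroud.rate_model` and :mod:`astroud.spiking_model`
wraps them with typed containers and validation.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Fast inline Gaussian sampler for the spiking kernel.
#
# The network draws one Gaussian per cell per 0.1 ms step (~3.5e8 draws for a
# 20 s run of the default 7000-cell network), which makes the noise generator
# the single hottest spot of the whole package.  We use the classic
# Marsaglia-Tsang ziggurat (128 layers) over a xorshift128+ stream, both
# inlined into the kernel; the sampler is validated against the moments and
# tail mass of the standard normal in the test suite.
# ---------------------------------------------------------------------------

_U64_MASK = np.uint64(0xFFFFFFFFFFFFFFFF)
_ZIG_R = 3.442619855899


def _build_ziggurat():
    m1 = 2147483648.0
    dn = 3.442619855899
    tn = dn
    vn = 9.91256303526217e-3
    kn = np.zeros(128, dtype=np.int64)
    wn = np.zeros(128)
    fn = np.zeros(128)
    q = vn / math.exp(-0.5 * dn * dn)
    kn[0] = np.int64((dn / q) * m1)
    kn[1] = 0
    wn[0] = q / m1
    wn[127] = dn / m1
    fn[0] = 1.0
    fn[127] = math.exp(-0.5 * dn * dn)
    for i in range(126, 0, -1):
        dn = math.sqrt(-2.0 * math.log(vn / dn + math.exp(-0.5 * dn * dn)))
        kn[i + 1] = np.int64((dn / tn) * m1)
        tn = dn
        fn[i] = math.exp(-0.5 * dn * dn)
        wn[i] = dn / m1
    return kn, wn, fn


_ZIG_KN, _ZIG_WN, _ZIG_FN = _build_ziggurat()
_INV_2_53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=False)
def _seed_state(seed):
    """Two xorshift128+ state words from one integer seed (splitmix64)."""
    z = np.uint64(seed)
    out = np.empty(2, dtype=np.uint64)
    for k in range(2):
        z = (z + np.uint64(0x9E3779B97F4A7C15)) & _U64_MASK
        w = z
        w = ((w ^ (w >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & _U64_MASK
        w = ((w ^ (w >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & _U64_MASK
        w = w ^ (w >> np.uint64(31))
        out[k] = w if w != np.uint64(0) else np.uint64(0xDEADBEEF)
    return out[0], out[1]


@njit(cache=False, inline="always")
def _next_u64(s0, s1):
    x = s0
    y = s1
    s0 = y
    x = x ^ ((x << np.uint64(23)) & _U64_MASK)
    s1 = x ^ y ^ (x >> np.uint64(17)) ^ (y >> np.uint64(26))
    return (s1 + y) & _U64_MASK, s0, s1


@njit(cache=False, inline="always")
def _rand_uniform(s0, s1):
    """Uniform double in [0, 1)."""
    v, s0, s1 = _next_u64(s0, s1)
    return float(v >> np.uint64(11)) * _INV_2_53, s0, s1


@njit(cache=False, inline="always")
def _randn(s0, s1):
    """Standard normal via the 128-layer ziggurat."""
    while True:
        v, s0, s1 = _next_u64(s0, s1)
        hz = np.int64(np.int32(v & np.uint64(0xFFFFFFFF)))
        iz = hz & np.int64(127)
        ahz = -hz if hz < 0 else hz
        if ahz < _ZIG_KN[iz]:
            return hz * _ZIG_WN[iz], s0, s1
        if iz == 0:
            # tail beyond the base strip
            while True:
                u1, s0, s1 = _rand_uniform(s0, s1)
                u2, s0, s1 = _rand_uniform(s0, s1)
                x = -math.log(u1 + 5e-324) / _ZIG_R
                y = -math.log(u2 + 5e-324)
                if y + y >= x * x:
                    val = _ZIG_R + x
                    return (val if hz > 0 else -val), s0, s1
        else:
            x = hz * _ZIG_WN[iz]
            u, s0, s1 = _rand_uniform(s0, s1)
            if _ZIG_FN[iz] + u * (_ZIG_FN[iz - 1] - _ZIG_FN[iz]) < math.exp(-0.5 * x * x):
                return x, s0, s1


@njit(cache=False)
def sample_normals(seed, n):
    """n ziggurat normals from one seed (exposed for distribution tests)."""
    s0, s1 = _seed_state(seed)
    out = np.empty(n)
    for i in range(n):
        out[i], s0, s1 = _randn(s0, s1)
    return out


@njit(cache=False)
def rate_kernel(
    y0,
    n_steps,
    dt,
    record_every,
    tau_E,
    tau_I,
    tau_A,
    tau_a,
    g_E,
    g_I,
    g_A,
    theta_E,
    theta_I,
    theta_A,
    beta,
    sigma,
    tau_ou,
    J,
    innovations,
):
    """Forward Euler integration of the three-population rate model.

    ``y0`` is ``(r_E, r_I, r_A, a, xi_E, xi_I, xi_A)``.  The OU noise states
    are advanced with their exact discretization (decay ``exp(-dt/tau_ou)``,
    innovation std ``sigma_unit = sqrt(1 - exp(-2 dt/tau_ou))`` on the
    unit-variance process); ``innovations`` holds pre-drawn standard normals
    of shape ``(n_steps, 3)`` so that each noise stream comes from its own
    generator.  Returns the recorded states, shape ``(n_rec + 1, 7)``,
    sampled every ``record_every`` steps starting at t=0.
    """
    rE, rI, rA, a = y0[0], y0[1], y0[2], y0[3]
    xiE, xiI, xiA = y0[4], y0[5], y0[6]

    f = np.exp(-dt / tau_ou)
    q = np.sqrt(1.0 - f * f)

    n_rec = n_steps // record_every
    out = np.empty((n_rec + 1, 7))
    out[0, 0], out[0, 1], out[0, 2], out[0, 3] = rE, rI, rA, a
    out[0, 4], out[0, 5], out[0, 6] = xiE, xiI, xiA

    for n in range(n_steps):
        IE = J[0, 0] * rE + J[0, 1] * rI + J[0, 2] * rA
        II = J[1, 0] * rE + J[1, 1] * rI + J[1, 2] * rA
        IA = J[2, 0] * rE + J[2, 1] * rI + J[2, 2] * rA

        argE = IE - a + sigma * xiE - theta_E
        argI = II + sigma * xiI - theta_I
        argA = IA + sigma * xiA - theta_A

        phiE = g_E * argE if argE > 0.0 else 0.0
        phiI = g_I * argI if argI > 0.0 else 0.0
        phiA = g_A * argA if argA > 0.0 else 0.0

        rE_new = rE + dt / tau_E * (-rE + phiE)
        rI_new = rI + dt / tau_I * (-rI + phiI)
        rA_new = rA + dt / tau_A * (-rA + phiA)
        a_new = a + dt / tau_a * (-a + beta * rE)

        xiE = f * xiE + q * innovations[n, 0]
        xiI = f * xiI + q * innovations[n, 1]
        xiA = f * xiA + q * innovations[n, 2]

        rE, rI, rA, a = rE_new, rI_new, rA_new, a_new

        if (n + 1) % record_every == 0:
            k = (n + 1) // record_every
            out[k, 0], out[k, 1], out[k, 2], out[k, 3] = rE, rI, rA, a
            out[k, 4], out[k, 5], out[k, 6] = xiE, xiI, xiA

    return out


@njit(cache=False)
def spiking_kernel(
    V_E,
    V_I,
    G,
    I_a,
    glio_E,
    glio_I,
    n_steps,
    dt,
    seed,
    record_every,
    tau_E,
    tau_I,
    tau_A,
    tau_a,
    tbar_E,
    tbar_I,
    tbar_A,
    tr_E,
    tr_I,
    tr_A,
    td_E,
    td_I,
    td_A,
    J_EE,
    J_EI,
    J_EA,
    J_IE,
    J_II,
    J_IA,
    beta,
    K_a,
    sig_E,
    sig_I,
    sig_A,
    V_r,
    V_th,
    V_L_E,
    V_L_I,
    G_r,
    G_th,
    G_L,
    dmin_E,
    dmax_E,
    dmin_I,
    dmax_I,
    dmin_A,
    dmax_A,
    s_AE_w,
    s_AI_w,
    J_AA,
    astro_in,
    q_E,
    q_I,
    q_A,
    syn0,
    max_events,
    ex_E,
    ex_I,
    ex_A,
    ex_E_glio,
):
    """Euler integration of the LIF network with threshold-release astrocytes.

    State arrays are updated in place.  ``q_X`` are time-bucketed delay ring
    buffers (one bucket per dt); ``syn0`` holds the initial
    ``(u_E, s_E, u_I, s_I, u_A, s_A)``.  ``glio_E``/``glio_I`` are 0/1 masks of
    the neurons contacted by astrocytes, ``astro_in`` the 0/1 mask of
    astrocytes receiving neuronal input; ``s_AE_w = J_AE`` and
    ``s_AI_w = J_AI``.  Spikes and release events are recorded as
    ``(population, cell, time)`` with population 0=E, 1=I, 2=A.

    Returns ``(pop, cell, t, n_events, traces, syn, matured, overflow)``.
    ``traces`` rows are sampled every ``record_every`` steps:
    ``(t, u_E, s_E, u_I, s_I, u_A, s_A, mean_AHP, V[ex_E], V[ex_I], G[ex_A],
    V[ex_E_glio])``.
    """
    s0, s1 = _seed_state(seed)

    N_E = V_E.shape[0]
    N_I = V_I.shape[0]
    N_A = G.shape[0]

    u_E, s_E = syn0[0], syn0[1]
    u_I, s_I = syn0[2], syn0[3]
    u_A, s_A = syn0[4], syn0[5]

    L_E = q_E.shape[0]
    L_I = q_I.shape[0]
    L_A = q_A.shape[0]
    p_E = 0
    p_I = 0
    p_A = 0

    ev_pop = np.empty(max_events, dtype=np.int8)
    ev_cell = np.empty(max_events, dtype=np.int32)
    ev_t = np.empty(max_events, dtype=np.float64)
    n_ev = 0
    overflow = False

    matured = np.zeros(3)

    c_E = sig_E * np.sqrt(dt / tau_E)
    c_I = sig_I * np.sqrt(dt / tau_I)
    c_A = sig_A * np.sqrt(dt / tau_A)
    jump_E = tbar_E / tr_E
    jump_I = tbar_I / tr_I
    jump_A = tbar_A / tr_A
    ahp_jump = beta / tau_a

    n_rec = n_steps // record_every
    traces = np.empty((n_rec, 12))
    rec_i = 0

    for n in range(n_steps):
        # mature delayed events into the population u variables
        inc_E = q_E[p_E] * jump_E
        inc_I = q_I[p_I] * jump_I
        inc_A = q_A[p_A] * jump_A
        matured[0] += q_E[p_E]
        matured[1] += q_I[p_I]
        matured[2] += q_A[p_A]
        q_E[p_E] = 0.0
        q_I[p_I] = 0.0
        q_A[p_A] = 0.0

        # synaptic variables: s integrates u, u decays plus matured jumps
        s_E_new = s_E + dt / td_E * (u_E - s_E)
        s_I_new = s_I + dt / td_I * (u_I - s_I)
        s_A_new = s_A + dt / td_A * (u_A - s_A)
        u_E = u_E - dt / tr_E * u_E + inc_E
        u_I = u_I - dt / tr_I * u_I + inc_I
        u_A = u_A - dt / tr_A * u_A + inc_A
        s_E, s_I, s_A = s_E_new, s_I_new, s_A_new

        t_spk = (n + 1) * dt

        rec_base_E = J_EE * s_E + J_EI * s_I
        rec_base_I = J_IE * s_E + J_II * s_I
        rec_base_A = J_AA * s_A
        rec_neur_A = s_AE_w * s_E + s_AI_w * s_I

        ahp_sum = 0.0
        for i in range(N_E):
            I_rec = rec_base_E + glio_E[i] * J_EA * s_A
            eta, s0, s1 = _randn(s0, s1)
            V_E[i] += dt / tau_E * (-(V_E[i] - V_L_E) + I_rec - K_a * I_a[i]) + c_E * eta
            I_a[i] -= dt / tau_a * I_a[i]
            if V_E[i] >= V_th:
                V_E[i] = V_r
                I_a[i] += ahp_jump
                if n_ev < max_events:
                    ev_pop[n_ev] = 0
                    ev_cell[n_ev] = i
                    ev_t[n_ev] = t_spk
                    n_ev += 1
                else:
                    overflow = True
                u, s0, s1 = _rand_uniform(s0, s1)
                d = dmin_E + (dmax_E - dmin_E) * u
                b = int(d / dt + 0.5)
                q_E[(p_E + 1 + b) % L_E] += 1.0
            ahp_sum += K_a * I_a[i]

        for i in range(N_I):
            eta, s0, s1 = _randn(s0, s1)
            V_I[i] += dt / tau_I * (-(V_I[i] - V_L_I) + rec_base_I + glio_I[i] * J_IA * s_A) + c_I * eta
            if V_I[i] >= V_th:
                V_I[i] = V_r
                if n_ev < max_events:
                    ev_pop[n_ev] = 1
                    ev_cell[n_ev] = i
                    ev_t[n_ev] = t_spk
                    n_ev += 1
                else:
                    overflow = True
                u, s0, s1 = _rand_uniform(s0, s1)
                d = dmin_I + (dmax_I - dmin_I) * u
                b = int(d / dt + 0.5)
                q_I[(p_I + 1 + b) % L_I] += 1.0

        for i in range(N_A):
            eta, s0, s1 = _randn(s0, s1)
            G[i] += dt / tau_A * (-(G[i] - G_L) + rec_base_A + astro_in[i] * rec_neur_A) + c_A * eta
            if G[i] >= G_th:
                G[i] = G_r
                if n_ev < max_events:
                    ev_pop[n_ev] = 2
                    ev_cell[n_ev] = i
                    ev_t[n_ev] = t_spk
                    n_ev += 1
                else:
                    overflow = True
                u, s0, s1 = _rand_uniform(s0, s1)
                d = dmin_A + (dmax_A - dmin_A) * u
                b = int(d / dt + 0.5)
                q_A[(p_A + 1 + b) % L_A] += 1.0

        p_E = (p_E + 1) % L_E
        p_I = (p_I + 1) % L_I
        p_A = (p_A + 1) % L_A

        if (n + 1) % record_every == 0 and rec_i < n_rec:
            traces[rec_i, 0] = t_spk
            traces[rec_i, 1] = u_E
            traces[rec_i, 2] = s_E
            traces[rec_i, 3] = u_I
            traces[rec_i, 4] = s_I
            traces[rec_i, 5] = u_A
            traces[rec_i, 6] = s_A
            traces[rec_i, 7] = ahp_sum / N_E
            traces[rec_i, 8] = V_E[ex_E]
            traces[rec_i, 9] = V_I[ex_I]
            traces[rec_i, 10] = G[ex_A]
            traces[rec_i, 11] = V_E[ex_E_glio]
            rec_i += 1

    syn = np.array([u_E, s_E, u_I, s_I, u_A, s_A])
    # roll queues so that index 0 is the next bucket to mature (caller can resume)
    q_E_out = np.empty_like(q_E)
    q_I_out = np.empty_like(q_I)
    q_A_out = np.empty_like(q_A)
    for k in range(L_E):
        q_E_out[k] = q_E[(p_E + k) % L_E]
    for k in range(L_I):
        q_I_out[k] = q_I[(p_I + k) % L_I]
    for k in range(L_A):
        q_A_out[k] = q_A[(p_A + k) % L_A]
    q_E[:] = q_E_out
    q_I[:] = q_I_out
    q_A[:] = q_A_out

    return (
        ev_pop[:n_ev],
        ev_cell[:n_ev],
        ev_t[:n_ev],
        n_ev,
        traces,
        syn,
        matured,
        overflow,
    )
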