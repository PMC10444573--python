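"""Numba-compiled right-hand sides for the two neuron models.

These kernels are the hot loops behind :mod:`hnburst.full_model` and
:mod:`hnburst.reduced_model`; the public modules wrap them with validated
parameter containers.  Parameters arrive as flat float64 vectors so that a
single compilation serves every parameter set.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NERNST_RT_F = 0.02526
_CAP = 500.0


@njit(cache=True, inline="always")
def _exp(x):
    if x > _CAP:
        x = _CAP
    elif x < -_CAP:
        x = -_CAP
    return np.exp(x)


@njit(cache=True, inline="always")
def _f_inf(A, B, V):
    return 1.0 / (1.0 + _exp(A * (V + B)))


@njit(cache=True, inline="always")
def _tau(A, B, C, D, V):
    return C + D / (1.0 + _exp(A * (V + B)))


# --- full (spiking) model -------------------------------------------------
# state: [V, Nai, mNaF, hNaF, mNaP, mNaPn, mK1, hK1, mK2, mKA, hKA, mh,
#         mCaF, hCaF, mCaS, hCaS]
# params: [gNaF, gNaP, gNaPn, gK1, gK2, gKA, gh, gCaF, gCaS, gleak,
#          EK, Eh, ECa, Eleak, IpumpMax, IpumpMaxNative, Naih, Nais, Nao,
#          Cm, vF, Iapp]

N_FULL_STATE = 16


@njit(cache=True)
def full_gating_inf(V):
    """Steady-state values of the 14 gating variables at voltage V."""
    out = np.empty(14)
    out[0] = _f_inf(-150.0, 0.029, V)   # mNaF
    out[1] = _f_inf(500.0, 0.03, V)     # hNaF
    out[2] = _f_inf(-120.0, 0.039, V)   # mNaP
    out[3] = _f_inf(-120.0, 0.039, V)   # mNaP native
    out[4] = _f_inf(-143.0, 0.021, V)   # mK1
    out[5] = _f_inf(111.0, 0.028, V)    # hK1
    out[6] = _f_inf(-83.0, 0.02, V)     # mK2
    out[7] = _f_inf(-130.0, 0.044, V)   # mKA
    out[8] = _f_inf(160.0, 0.063, V)    # hKA
    out[9] = 1.0 / (1.0 + 2.0 * _exp(180.0 * (V + 0.047))
                    + _exp(500.0 * (V + 0.047)))  # mh
    out[10] = _f_inf(-600.0, 0.0467, V)  # mCaF
    out[11] = _f_inf(350.0, 0.055, V)    # hCaF
    out[12] = _f_inf(-420.0, 0.0472, V)  # mCaS
    out[13] = _f_inf(360.0, 0.055, V)    # hCaS
    return out


@njit(cache=True)
def full_currents(y, p):
    """Per-current breakdown (nA), ordered as the voltage-equation sum:

    [INaF, INaP, INaP_native, IK1, IK2, IKA, Ih, ICaF, ICaS,
     Ipump, Ipump_native, Ileak]
    """
    V = y[0]
    nai = y[1]
    ena = NERNST_RT_F * np.log(p[18] / nai)
    out = np.empty(12)
    out[0] = p[0] * y[2] ** 3 * y[3] * (V - ena)          # INaF
    out[1] = p[1] * y[4] * (V - ena)                      # INaP (injected)
    out[2] = p[2] * y[5] * (V - ena)                      # INaP native
    out[3] = p[3] * y[6] ** 2 * y[7] * (V - p[10])        # IK1
    out[4] = p[4] * y[8] ** 2 * (V - p[10])               # IK2
    out[5] = p[5] * y[9] ** 2 * y[10] * (V - p[10])       # IKA
    out[6] = p[6] * y[11] ** 2 * (V - p[11])              # Ih
    out[7] = p[7] * y[12] ** 2 * y[13] * (V - p[12])      # ICaF
    out[8] = p[8] * y[14] ** 2 * y[15] * (V - p[12])      # ICaS
    act = 1.0 / (1.0 + _exp((p[16] - nai) / p[17]))
    out[9] = p[14] * act                                  # Ipump (injected)
    out[10] = p[15] * act                                 # Ipump native
    out[11] = p[9] * (V - p[13])                          # Ileak
    return out


@njit(cache=True)
def full_rhs_kernel(t, y, p, noise, dt_noise):
    V = y[0]
    cur = full_currents(y, p)
    i_noise = 0.0
    if noise.size > 0:
        k = int(t / dt_noise)
        if k >= noise.size:
            k = noise.size - 1
        i_noise = noise[k]
    dy = np.empty(N_FULL_STATE)
    # the native pump (cur[10]) is estimated for Na+ bookkeeping only and
    # does not enter the current balance
    dy[0] = (-(cur[0] + cur[1] + cur[2] + cur[3] + cur[4] + cur[5] + cur[6]
               + cur[7] + cur[8] + cur[9] + cur[11])
             + p[21] + i_noise) / p[19]
    # Na+ bookkeeping: Na-carrying conductance currents plus 3x both pump
    # terms; leak and h fluxes are deliberately not counted.
    dy[1] = -(cur[1] + cur[2] + cur[0] + 3.0 * cur[9] + 3.0 * cur[10]) / p[20]
    inf = full_gating_inf(V)
    dy[2] = (inf[0] - y[2]) / 0.0001
    tau_h = (0.004 + 0.02 / np.cosh(300.0 * (V + 0.0027))
             + 0.006 / (1.0 + _exp(500.0 * (V + 0.028))))
    dy[3] = (inf[1] - y[3]) / tau_h
    dy[4] = (inf[2] - y[4]) / _tau(400.0, 0.057, 0.01, 0.2, V)
    dy[5] = (inf[3] - y[5]) / _tau(400.0, 0.057, 0.01, 0.2, V)
    dy[6] = (inf[4] - y[6]) / _tau(150.0, 0.016, 0.001, 0.011, V)
    dy[7] = (inf[5] - y[7]) / _tau(-143.0, 0.013, 0.5, 0.2, V)
    dy[8] = (inf[6] - y[8]) / _tau(200.0, 0.035, 0.057, 0.043, V)
    dy[9] = (inf[7] - y[9]) / _tau(200.0, 0.03, 0.005, 0.011, V)
    dy[10] = (inf[8] - y[10]) / _tau(-300.0, 0.055, 0.026, 0.0085, V)
    dy[11] = (inf[9] - y[11]) / _tau(-100.0, 0.073, 0.7, 1.7, V)
    dy[12] = (inf[10] - y[12]) / _tau(-330.0, 0.0467, 0.011, 0.024, V)
    dy[13] = (inf[11] - y[13]) / _tau(270.0, 0.055, 0.06, 0.31, V)
    dy[14] = (inf[12] - y[14]) / _tau(-400.0, 0.0487, 0.005, 0.134, V)
    dy[15] = (inf[13] - y[15]) / _tau(-250.0, 0.043, 0.2, 5.25, V)
    return dy


# --- reduced two-variable model -------------------------------------------
# state: [V, Nai]
# params: [gNaPn, gNaP, gNaF, gh, gK2, gleakNa, gleakK,
#          A_NaPn, B_NaPn, A_NaP, B_NaP, A_mNaF, B_mNaF, A_hNaF, B_hNaF,
#          a1_h, a2_h, half_h, A_K2, B_K2,
#          Eh, EK, EleakK, IpumpMax, Naih, Nais, Nao, Cm, vF]

N_RED_PAR = 29


@njit(cache=True)
def reduced_currents(V, nai, p):
    """Per-current breakdown (nA):

    [INaP_native, INaP, INaF, Ih_Na, Ih_K, IK2, Ileak_Na, Ileak_K, Ipump]
    """
    ena = NERNST_RT_F * np.log(p[26] / nai)
    m_napn = _f_inf(p[7], p[8], V)
    m_nap = _f_inf(p[9], p[10], V)
    m_naf = _f_inf(p[11], p[12], V)
    h_naf = _f_inf(p[13], p[14], V)
    m_h = 1.0 / (1.0 + 2.0 * _exp(p[15] * (V + p[17]))
                 + _exp(p[16] * (V + p[17])))
    m_k2 = _f_inf(p[18], p[19], V)
    out = np.empty(9)
    out[0] = p[0] * m_napn * (V - ena)
    out[1] = p[1] * m_nap * (V - ena)
    out[2] = p[2] * m_naf ** 3 * h_naf * (V - ena)
    ih = p[3] * m_h ** 2 * (V - p[20])
    out[3] = ih * (3.0 / 7.0)
    out[4] = ih * (4.0 / 7.0)
    out[5] = p[4] * m_k2 ** 2 * (V - p[21])
    out[6] = p[5] * (V - ena)
    out[7] = p[6] * (V - p[22])
    out[8] = p[23] / (1.0 + _exp((p[24] - nai) / p[25]))
    return out


@njit(cache=True)
def reduced_rhs_kernel(t, y, p):
    cur = reduced_currents(y[0], y[1], p)
    dv = -(cur[0] + cur[1] + cur[8] + cur[2] + cur[3] + cur[4]
           + cur[5] + cur[6] + cur[7]) / p[27]
    dna = -(cur[0] + cur[1] + 3.0 * cur[8] + cur[2] + cur[3] + cur[6]) / p[28]
    return np.array((dv, dna))


@njit(cache=True)
def reduced_total_current(V, nai, p):
    cur = reduced_currents(V, nai, p)
    return (cur[0] + cur[1] + cur[8] + cur[2] + cur[3] + cur[4]
            + cur[5] + cur[6] + cur[7])


@njit(cache=True)
def reduced_na_flux(V, nai, p):
    """d[Na+]_i/dt (M/s) from the Na+ bookkeeping balance."""
    cur = reduced_currents(V, nai, p)
    return -(cur[0] + cur[1] + 3.0 * cur[8] + cur[2] + cur[3] + cur[6]) / p[28]


@njit(cache=True)
def reduced_rk4(y0, p, duration, dt):
    """Fixed-step RK4 integration sampled once per step.

    With dt well below the membrane time constant (C_m / total conductance,
    several ms) this matches the adaptive path to a fraction of a percent in
    burst timing while running entirely in compiled code; it is the fast
    path used inside the evolutionary fit.
    """
    n = int(duration / dt)
    out = np.empty((2, n))
    y = y0.copy()
    for i in range(n):
        out[0, i] = y[0]
        out[1, i] = y[1]
        k1 = reduced_rhs_kernel(0.0, y, p)
        k2 = reduced_rhs_kernel(0.0, y + 0.5 * dt * k1, p)
        k3 = reduced_rhs_kernel(0.0, y + 0.5 * dt * k2, p)
        k4 = reduced_rhs_kernel(0.0, y + dt * k3, p)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return out


@njit(cache=True)
def _full_rhs_inplace(t, y, p, noise, dt_noise, dy):
    """Allocation-free variant of :func:`full_rhs_kernel` for the RK4 loop."""
    V = y[0]
    nai = y[1]
    ena = NERNST_RT_F * np.log(p[18] / nai)
    i_naf = p[0] * y[2] ** 3 * y[3] * (V - ena)
    i_nap = p[1] * y[4] * (V - ena)
    i_napn = p[2] * y[5] * (V - ena)
    i_k1 = p[3] * y[6] ** 2 * y[7] * (V - p[10])
    i_k2 = p[4] * y[8] ** 2 * (V - p[10])
    i_ka = p[5] * y[9] ** 2 * y[10] * (V - p[10])
    i_h = p[6] * y[11] ** 2 * (V - p[11])
    i_caf = p[7] * y[12] ** 2 * y[13] * (V - p[12])
    i_cas = p[8] * y[14] ** 2 * y[15] * (V - p[12])
    act = 1.0 / (1.0 + _exp((p[16] - nai) / p[17]))
    i_p = p[14] * act
    i_pn = p[15] * act
    i_l = p[9] * (V - p[13])
    i_noise = 0.0
    if noise.size > 0:
        k = int(t / dt_noise)
        if k >= noise.size:
            k = noise.size - 1
        i_noise = noise[k]
    dy[0] = (-(i_naf + i_nap + i_napn + i_k1 + i_k2 + i_ka + i_h + i_caf
               + i_cas + i_p + i_l) + p[21] + i_noise) / p[19]
    dy[1] = -(i_nap + i_napn + i_naf + 3.0 * i_p + 3.0 * i_pn) / p[20]
    dy[2] = (_f_inf(-150.0, 0.029, V) - y[2]) / 0.0001
    tau_h = (0.004 + 0.02 / np.cosh(300.0 * (V + 0.0027))
             + 0.006 / (1.0 + _exp(500.0 * (V + 0.028))))
    dy[3] = (_f_inf(500.0, 0.03, V) - y[3]) / tau_h
    dy[4] = (_f_inf(-120.0, 0.039, V) - y[4]) / _tau(400.0, 0.057, 0.01, 0.2, V)
    dy[5] = (_f_inf(-120.0, 0.039, V) - y[5]) / _tau(400.0, 0.057, 0.01, 0.2, V)
    dy[6] = (_f_inf(-143.0, 0.021, V) - y[6]) / _tau(150.0, 0.016, 0.001, 0.011, V)
    dy[7] = (_f_inf(111.0, 0.028, V) - y[7]) / _tau(-143.0, 0.013, 0.5, 0.2, V)
    dy[8] = (_f_inf(-83.0, 0.02, V) - y[8]) / _tau(200.0, 0.035, 0.057, 0.043, V)
    dy[9] = (_f_inf(-130.0, 0.044, V) - y[9]) / _tau(200.0, 0.03, 0.005, 0.011, V)
    dy[10] = (_f_inf(160.0, 0.063, V) - y[10]) / _tau(-300.0, 0.055, 0.026, 0.0085, V)
    fh = 1.0 / (1.0 + 2.0 * _exp(180.0 * (V + 0.047))
                + _exp(500.0 * (V + 0.047)))
    dy[11] = (fh - y[11]) / _tau(-100.0, 0.073, 0.7, 1.7, V)
    dy[12] = (_f_inf(-600.0, 0.0467, V) - y[12]) / _tau(-330.0, 0.0467, 0.011, 0.024, V)
    dy[13] = (_f_inf(350.0, 0.055, V) - y[13]) / _tau(270.0, 0.055, 0.06, 0.31, V)
    dy[14] = (_f_inf(-420.0, 0.0472, V) - y[14]) / _tau(-400.0, 0.0487, 0.005, 0.134, V)
    dy[15] = (_f_inf(360.0, 0.055, V) - y[15]) / _tau(-250.0, 0.043, 0.2, 5.25, V)


@njit(cache=True)
def full_rk4(y0, p, duration, dt, sample_every, noise, dt_noise):
    """Fixed-step RK4 for the full model, recording every k-th step.

    dt must sit well below the fastest gating time constant (0.1 ms); the
    default driver uses 20 us.  Runs entirely in compiled code -- the fast
    path for long protocol sweeps where the adaptive solver's per-step
    Python overhead dominates.
    """
    n_steps = int(duration / dt)
    n_out = n_steps // sample_every
    out = np.empty((N_FULL_STATE, n_out))
    y = y0.copy()
    yt = np.empty(N_FULL_STATE)
    k1 = np.empty(N_FULL_STATE)
    k2 = np.empty(N_FULL_STATE)
    k3 = np.empty(N_FULL_STATE)
    k4 = np.empty(N_FULL_STATE)
    t = 0.0
    j = 0
    for i in range(n_steps):
        if i % sample_every == 0 and j < n_out:
            for k in range(N_FULL_STATE):
                out[k, j] = y[k]
            j += 1
        _full_rhs_inplace(t, y, p, noise, dt_noise, k1)
        for k in range(N_FULL_STATE):
            yt[k] = y[k] + 0.5 * dt * k1[k]
        _full_rhs_inplace(t + 0.5 * dt, yt, p, noise, dt_noise, k2)
        for k in range(N_FULL_STATE):
            yt[k] = y[k] + 0.5 * dt * k2[k]
        _full_rhs_inplace(t + 0.5 * dt, yt, p, noise, dt_noise, k3)
        for k in range(N_FULL_STATE):
            yt[k] = y[k] + dt * k3[k]
        _full_rhs_inplace(t + dt, yt, p, noise, dt_noise, k4)
        for k in range(N_FULL_STATE):
            y[k] = y[k] + (dt / 6.0) * (k1[k] + 2.0 * k2[k] + 2.0 * k3[k]
                                        + k4[k])
        t += dt
    return out
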