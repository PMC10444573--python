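"""Two-variable (V_m, [Na+]_i) model of pump/persistent-Na+ bursting.

With all gating instantaneous, the membrane potential relaxes quickly to a
balance of nine currents while intracellular Na+ integrates the Na+-carrying
fluxes slowly -- a classic slow-fast relaxation oscillator.  The membrane
carries the native persistent Na+ current, a fast Na+ window current, the
hyperpolarization-activated current split 3/7 Na+ : 4/7 K+, a non-inactivating
K+ current, split leak currents, the Na+/K+ pump, and the two dynamic-clamp
injected currents (persistent Na+ of conductance ``g_nap`` and pump scaled by
``ipump_max``).  Unlike the full model's bookkeeping, the Na+ balance here
includes every Na+-carrying conductance current (native, fast, h- and leak
components), with only the pump flux multiplied by 3.

The fast Na+ current cannot generate spikes here (its activation is
instantaneous), contributing only a window current; the model's voltage
waveform is the slow envelope of bursting, not the spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernels
from .trace import Trace

__all__ = [
    "ReducedModelParams",
    "ReducedState",
    "currents_2d",
    "total_current",
    "na_flux",
    "rhs_2d",
    "simulate_2d",
    "measure_2d_cycle",
    "CycleSummary",
]


@dataclass
class ReducedModelParams:
    """Parameters of the reduced model (defaults: published fitted set).

    Conductances in nS, potentials in V, concentrations in M.  Steady-state
    (in)activations are ``1/(1+exp(A*(V+B)))`` with steepness ``A`` (1/V) and
    offset ``B`` (V); the h-current uses the double-exponential form with
    coefficients ``h_a1``, ``h_a2`` and offset ``h_half``.  Activation
    exponents are structural (persistent Na+: m; fast Na+: m^3 h; h and K+:
    m^2) and not exposed as parameters.

    ``vf`` converts net Na+-carrying current (nA) into d[Na+]_i/dt (M/s);
    the default is the reciprocal of the printed dimensionless factor 0.0038,
    i.e. a cytosolic reservoir of roughly 2.7 pl.
    """

    g_nap_native: float = 9.85
    g_nap: float = 6.0            # dynamic-clamp injected
    g_naf: float = 150.0
    g_h: float = 6.0
    g_k2: float = 138.0
    g_leak_na: float = 1.1
    g_leak_k: float = 8.8
    a_nap_native: float = -160.0
    b_nap_native: float = 0.0376
    a_nap: float = -120.0
    b_nap: float = 0.04
    a_m_naf: float = -210.0
    b_m_naf: float = 0.032
    a_h_naf: float = 500.0
    b_h_naf: float = 0.04
    h_a1: float = 184.14
    h_a2: float = 511.5
    h_half: float = 0.057
    a_k2: float = -83.0
    b_k2: float = 0.0285
    e_h: float = -0.021
    e_k: float = -0.07
    e_leak_k: float = -0.07
    ipump_max: float = 0.3
    na_ih: float = 0.012
    na_is: float = 0.0016
    na_o: float = 0.115
    c_m: float = 0.25
    vf: float = 1.0 / 0.0038

    def __post_init__(self):
        for f in fields(self):
            if f.name.startswith("g_") and getattr(self, f.name) < 0:
                raise ValueError(f"conductance {f.name} must be >= 0")
        if self.na_is <= 0 or self.na_o <= 0:
            raise ValueError("na_is and na_o must be positive")
        if self.vf <= 0 or self.c_m <= 0:
            raise ValueError("vf and c_m must be positive")

    def with_(self, **kwargs) -> "ReducedModelParams":
        return replace(self, **kwargs)

    def to_vector(self) -> np.ndarray:
        return np.array([
            self.g_nap_native, self.g_nap, self.g_naf, self.g_h, self.g_k2,
            self.g_leak_na, self.g_leak_k,
            self.a_nap_native, self.b_nap_native, self.a_nap, self.b_nap,
            self.a_m_naf, self.b_m_naf, self.a_h_naf, self.b_h_naf,
            self.h_a1, self.h_a2, self.h_half, self.a_k2, self.b_k2,
            self.e_h, self.e_k, self.e_leak_k,
            self.ipump_max, self.na_ih, self.na_is, self.na_o,
            self.c_m, self.vf,
        ])


@dataclass
class ReducedState:
    v_m: float = -0.055
    na_i: float = 0.011

    def __post_init__(self):
        if not 0.0 < self.na_i:
            raise ValueError("na_i must be positive")


CURRENT_NAMES_2D = (
    "i_nap_native", "i_nap", "i_naf", "i_h_na", "i_h_k", "i_k2",
    "i_leak_na", "i_leak_k", "i_pump",
)


def currents_2d(V, nai, params: ReducedModelParams) -> dict:
    """Per-current breakdown (nA each); accepts scalars or arrays.

    This numpy path is the reference evaluation; the compiled kernel used by
    the integrator is cross-checked against it in the test suite.
    """
    from .kinetics import boltzmann, h_activation, nernst_ena, pump_current

    p = params
    V = np.asarray(V, dtype=float)
    nai = np.asarray(nai, dtype=float)
    ena = nernst_ena(p.na_o, nai)
    ih = p.g_h * h_activation(V, p.h_a1, p.h_a2, p.h_half) ** 2 * (V - p.e_h)
    out = {
        "i_nap_native": p.g_nap_native
        * boltzmann(p.a_nap_native, p.b_nap_native, V) * (V - ena),
        "i_nap": p.g_nap * boltzmann(p.a_nap, p.b_nap, V) * (V - ena),
        "i_naf": p.g_naf * boltzmann(p.a_m_naf, p.b_m_naf, V) ** 3
        * boltzmann(p.a_h_naf, p.b_h_naf, V) * (V - ena),
        "i_h_na": ih * (3.0 / 7.0),
        "i_h_k": ih * (4.0 / 7.0),
        "i_k2": p.g_k2 * boltzmann(p.a_k2, p.b_k2, V) ** 2 * (V - p.e_k),
        "i_leak_na": p.g_leak_na * (V - ena),
        "i_leak_k": p.g_leak_k * (V - p.e_leak_k),
        "i_pump": pump_current(nai, p.ipump_max, p.na_ih, p.na_is),
    }
    return out


def total_current(V, nai, params: ReducedModelParams):
    """Sum of all nine membrane currents (nA); zero on the V-nullcline."""
    cur = currents_2d(V, nai, params)
    return sum(cur.values())


def na_flux(V, nai, params: ReducedModelParams):
    """d[Na+]_i/dt (M/s); zero on the [Na+]_i-nullcline."""
    cur = currents_2d(V, nai, params)
    return -(cur["i_nap_native"] + cur["i_nap"] + 3.0 * cur["i_pump"]
             + cur["i_naf"] + cur["i_h_na"] + cur["i_leak_na"]) / params.vf


def rhs_2d(state: ReducedState, params: ReducedModelParams) -> tuple[float, float]:
    """(dV/dt in V/s, d[Na+]_i/dt in M/s)."""
    dy = _kernels.reduced_rhs_kernel(
        0.0, np.array([state.v_m, state.na_i]), params.to_vector()
    )
    if not np.all(np.isfinite(dy)):
        raise FloatingPointError("non-finite derivative in reduced model")
    return float(dy[0]), float(dy[1])


def simulate_2d(
    params: ReducedModelParams,
    duration: float,
    init: ReducedState | None = None,
    sample_rate: float = 5000.0,
    rtol: float = 1e-8,
    atol=(1e-10, 1e-12),
    max_step: float = 0.5,
    method: str = "lsoda",
) -> Trace:
    """Integrate the reduced model (deterministic) to a uniform trace.

    ``method='lsoda'`` (default) uses the adaptive stiff-capable solver;
    ``method='rk4'`` uses a compiled fixed-step integrator with the step
    equal to the sampling interval -- the fast path used for the many
    evaluations inside the evolutionary fit.  The two agree on burst timing
    to a fraction of a percent.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if init is None:
        init = ReducedState()
    p = params.to_vector()
    t_eval = np.arange(0.0, duration, 1.0 / sample_rate)
    if method == "rk4":
        y = _kernels.reduced_rk4(np.array([init.v_m, init.na_i]), p,
                                 duration, 1.0 / sample_rate)
        t_eval = t_eval[: y.shape[1]]
        sol_t, (v, na) = t_eval, y
        if not np.all(np.isfinite(na)) or not np.all(np.isfinite(v)):
            raise RuntimeError("reduced-model integration diverged (rk4)")
    elif method == "lsoda":
        sol = solve_ivp(
            _kernels.reduced_rhs_kernel, (0.0, duration),
            np.array([init.v_m, init.na_i]), args=(p,),
            method="LSODA", rtol=rtol, atol=np.asarray(atol),
            max_step=max_step, t_eval=t_eval,
        )
        if not sol.success:
            raise RuntimeError(
                f"reduced-model integration failed: {sol.message}")
        sol_t, (v, na) = sol.t, sol.y
    else:
        raise ValueError(f"unknown method {method!r}")
    if np.any(na <= 0) or np.any(na >= params.na_o):
        raise RuntimeError("[Na+]_i left the physiological interval (0, na_o)")
    ena = _kernels.NERNST_RT_F * np.log(params.na_o / na)
    m_nap = 1.0 / (1.0 + np.exp(np.clip(params.a_nap * (v + params.b_nap),
                                        -500, 500)))
    i_nap = params.g_nap * m_nap * (v - ena)
    act = 1.0 / (1.0 + np.exp(np.clip((params.na_ih - na) / params.na_is,
                                      -500, 500)))
    i_pump = params.ipump_max * act
    return Trace(sol_t, v, i_nap, i_pump, na)


@dataclass
class CycleSummary:
    """Threshold-based cycle metrics of a slow oscillatory waveform."""

    bd: float           # mean time above threshold per cycle (s)
    ibi: float          # mean time below threshold per cycle (s)
    period: float       # mean cycle period (s)
    v_amplitude: float  # mean per-cycle V peak - trough (V)
    na_amplitude: float  # mean per-cycle [Na+]_i peak - trough (M)
    v_peak: float
    v_trough: float
    na_peak: float
    na_trough: float
    n_cycles: int


def _interp_crossings(t, x, thr, rising=True):
    """Crossing times of x through thr, linearly interpolated."""
    above = x > thr
    if rising:
        idx = np.where(~above[:-1] & above[1:])[0]
    else:
        idx = np.where(above[:-1] & ~above[1:])[0]
    if idx.size == 0:
        return np.empty(0)
    frac = (thr - x[idx]) / (x[idx + 1] - x[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def measure_2d_cycle(
    trace: Trace,
    v_threshold: float = -0.045,
    transient: float = 0.0,
) -> CycleSummary:
    """Burst timing and amplitudes of the reduced model's oscillation.

    The depolarized phase (voltage above ``v_threshold``) is the burst and
    the hyperpolarized phase the interburst interval.  Crossing times are
    located by linear interpolation; only complete phases between crossings
    are counted.  Amplitudes are per-cycle peak minus trough, averaged.
    """
    tr = trace.window(transient) if transient > 0 else trace
    t, v, na = tr.time, tr.v_m, tr.na_i
    ups = _interp_crossings(t, v, v_threshold, rising=True)
    downs = _interp_crossings(t, v, v_threshold, rising=False)
    if ups.size < 2:
        raise ValueError("no sustained oscillation: fewer than 2 up-crossings")
    bds, ibis = [], []
    for u in ups:
        later = downs[downs > u]
        nxt_up = ups[ups > u]
        if later.size and (not nxt_up.size or later[0] < nxt_up[0]):
            bds.append(later[0] - u)
    for d in downs:
        later = ups[ups > d]
        nxt_dn = downs[downs > d]
        if later.size and (not nxt_dn.size or later[0] < nxt_dn[0]):
            ibis.append(later[0] - d)
    v_pk, v_tr_, na_pk, na_tr = [], [], [], []
    for u0, u1 in zip(ups[:-1], ups[1:]):
        m = (t >= u0) & (t < u1)
        v_pk.append(v[m].max())
        v_tr_.append(v[m].min())
        na_pk.append(na[m].max())
        na_tr.append(na[m].min())
    return CycleSummary(
        bd=float(np.mean(bds)),
        ibi=float(np.mean(ibis)),
        period=float(np.mean(np.diff(ups))),
        v_amplitude=float(np.mean(v_pk) - np.mean(v_tr_)),
        na_amplitude=float(np.mean(na_pk) - np.mean(na_tr)),
        v_peak=float(np.mean(v_pk)),
        v_trough=float(np.mean(v_tr_)),
        na_peak=float(np.mean(na_pk)),
        na_trough=float(np.mean(na_tr)),
        n_cycles=len(ups) - 1,
    )
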