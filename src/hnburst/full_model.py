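"""Full conductance-based virtual hybrid HN neuron.

The model couples the canonical leech heartbeat (HN) interneuron -- fast and
persistent Na+ currents, three K+ currents, a hyperpolarization-activated
current, two Ca2+ currents, an ohmic leak and a native Na+/K+ pump -- with
the two dynamic-clamp *injected* currents of the hybrid experiments: a
persistent Na+ current of conductance ``g_nap`` and a pump current of maximal
value ``ipump_max``.  Intracellular Na+ is book-kept from the Na+-carrying
currents (fast Na+, both persistent Na+ components, and three elementary
charges per pump cycle for both pump terms); Na+ fluxes through the leak and
h-currents are deliberately not counted, matching the dynamic-clamp
estimator.

This simulator is the package's synthetic-data generator: every downstream
stage (burst quantification, regime classification) can run on its output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernels
from .trace import Trace

__all__ = [
    "FullModelParams",
    "FullState",
    "GATING_NAMES",
    "full_rhs",
    "simulate_full",
    "steady_state_reached",
    "default_initial_state",
]

GATING_NAMES = (
    "m_naf", "h_naf", "m_nap", "m_nap_native", "m_k1", "h_k1", "m_k2",
    "m_ka", "h_ka", "m_h", "m_caf", "h_caf", "m_cas", "h_cas",
)

#: Bias current held by the experimental protocol after electrode penetration
#: (nA).  Pure-model runs default to 0; protocol runs use this preset.
PROTOCOL_BIAS_NA = -0.1


@dataclass
class FullModelParams:
    """Parameters of the full hybrid model (defaults: published set).

    Conductances in nS, potentials in V, currents in nA, concentrations in M,
    capacitance in nF.  ``vf`` is the flux-scaling constant (nA*s/M) that
    converts net Na+-carrying current into concentration rate; the default is
    the reciprocal of the printed dimensionless factor 0.0024, corresponding
    to a cytosolic reservoir of roughly 4.3 pl.
    """

    g_naf: float = 150.0
    g_nap: float = 6.0            # dynamic-clamp injected
    g_nap_native: float = 5.0
    g_k1: float = 80.0
    g_k2: float = 80.0
    g_ka: float = 100.0
    g_h: float = 4.0
    g_caf: float = 5.0
    g_cas: float = 4.0
    g_leak: float = 7.0
    e_k: float = -0.07
    e_h: float = -0.021
    e_ca: float = 0.135
    e_leak: float = -0.045
    ipump_max: float = 0.3        # dynamic-clamp injected
    ipump_max_native: float = 0.1
    na_ih: float = 0.012
    na_is: float = 0.0016
    na_o: float = 0.115
    c_m: float = 0.25
    vf: float = 1.0 / 0.0024
    i_app: float = 0.0
    sigma_noise: float = 0.0      # amplitude of injected current noise (nA)

    def __post_init__(self):
        for f in fields(self):
            if f.name.startswith("g_") and getattr(self, f.name) < 0:
                raise ValueError(f"conductance {f.name} must be >= 0")
        if self.na_is <= 0 or self.na_o <= 0:
            raise ValueError("na_is and na_o must be positive")
        if self.vf <= 0 or self.c_m <= 0:
            raise ValueError("vf and c_m must be positive")
        if not 0.0 <= self.ipump_max <= 1.0:
            raise ValueError("ipump_max must lie in [0, 1] nA")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be >= 0")

    def with_(self, **kwargs) -> "FullModelParams":
        return replace(self, **kwargs)

    def to_vector(self) -> np.ndarray:
        return np.array([
            self.g_naf, self.g_nap, self.g_nap_native, self.g_k1, self.g_k2,
            self.g_ka, self.g_h, self.g_caf, self.g_cas, self.g_leak,
            self.e_k, self.e_h, self.e_ca, self.e_leak,
            self.ipump_max, self.ipump_max_native, self.na_ih, self.na_is,
            self.na_o, self.c_m, self.vf, self.i_app,
        ])


@dataclass
class FullState:
    """Instantaneous state: voltage, Na+ concentration, 14 gating variables."""

    v_m: float
    na_i: float
    gating: np.ndarray = field(default_factory=lambda: np.zeros(14))

    def __post_init__(self):
        self.gating = np.asarray(self.gating, dtype=float)
        if self.gating.shape != (14,):
            raise ValueError("gating must have 14 entries")
        if np.any(self.gating < 0) or np.any(self.gating > 1):
            raise ValueError("gating variables must lie in [0, 1]")
        if self.na_i <= 0:
            raise ValueError("na_i must be positive")

    def to_vector(self) -> np.ndarray:
        return np.concatenate(([self.v_m, self.na_i], self.gating))

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "FullState":
        return cls(float(y[0]), float(y[1]), np.array(y[2:16]))


def default_initial_state(v_m: float = -0.05, na_i: float = 0.010) -> FullState:
    """State with all gating variables at their steady-state values for v_m."""
    return FullState(v_m, na_i, _kernels.full_gating_inf(v_m))


_EMPTY = np.empty(0)


def full_rhs(state: FullState, params: FullModelParams, t: float = 0.0) -> np.ndarray:
    """Time derivative of the full state vector (V/s, M/s, 1/s x14)."""
    dy = _kernels.full_rhs_kernel(t, state.to_vector(), params.to_vector(),
                                  _EMPTY, 1.0)
    if not np.all(np.isfinite(dy)):
        raise FloatingPointError("non-finite derivative in full model")
    return dy


def full_currents(state: FullState, params: FullModelParams) -> dict:
    """Per-current breakdown (nA) at a state."""
    names = ("i_naf", "i_nap", "i_nap_native", "i_k1", "i_k2", "i_ka", "i_h",
             "i_caf", "i_cas", "i_pump", "i_pump_native", "i_leak")
    vals = _kernels.full_currents(state.to_vector(), params.to_vector())
    return dict(zip(names, vals))


def simulate_full(
    params: FullModelParams,
    duration: float,
    init: FullState | str = "default",
    seed: int | None = None,
    sample_rate: float = 5000.0,
    rtol: float = 1e-8,
    atol: float | np.ndarray | None = None,
    max_step: float = 0.01,
    record_currents: bool = False,
    method: str = "lsoda",
    rk4_dt: float = 2e-5,
) -> Trace:
    """Integrate the full model and return a uniformly sampled trace.

    ``method='lsoda'`` (default) uses the adaptive stiff-capable solver and
    resamples the solution to ``sample_rate`` (default 5 kHz, the
    acquisition rate of the hybrid experiments); ``method='rk4'`` uses a
    compiled fixed-step integrator (step ``rk4_dt``, a fifth of the fastest
    gating time constant) -- the fast path for long protocol sweeps, which
    matches the adaptive path's burst timing to well under a percent.

    If ``params.sigma_noise > 0`` a zero-mean current noise, held
    piecewise-constant over 1-ms bins and drawn from the seeded generator,
    is added to the voltage equation to emulate cycle-to-cycle variability.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if init == "default":
        init = default_initial_state()
    y0 = init.to_vector()
    p = params.to_vector()

    dt_noise = 1e-3
    if params.sigma_noise > 0:
        rng = np.random.default_rng(seed)
        n_bins = int(np.ceil(duration / dt_noise)) + 1
        noise = rng.normal(0.0, params.sigma_noise, n_bins)
        max_step = min(max_step, dt_noise)
    else:
        noise = _EMPTY

    if method == "rk4":
        sample_every = max(1, int(round(1.0 / (sample_rate * rk4_dt))))
        y = _kernels.full_rk4(y0, p, duration, rk4_dt, sample_every, noise,
                              dt_noise)
        t = np.arange(y.shape[1]) * (rk4_dt * sample_every)
        if not np.all(np.isfinite(y)):
            raise RuntimeError("full-model integration diverged (rk4)")
    elif method == "lsoda":
        if atol is None:
            atol = np.full(16, 1e-12)
            atol[0] = 1e-10
        t_eval = np.arange(0.0, duration, 1.0 / sample_rate)
        sol = solve_ivp(
            _kernels.full_rhs_kernel, (0.0, duration), y0,
            args=(p, noise, dt_noise), method="LSODA",
            rtol=rtol, atol=atol, max_step=max_step, t_eval=t_eval,
        )
        if not sol.success:
            raise RuntimeError(
                f"full-model integration failed: {sol.message}")
        t, y = sol.t, sol.y
    else:
        raise ValueError(f"unknown method {method!r}")
    na = y[1]
    if np.any(na <= 0) or np.any(na >= params.na_o):
        raise RuntimeError("[Na+]_i left the physiological interval (0, na_o)")

    v = y[0]
    ena = _kernels.NERNST_RT_F * np.log(params.na_o / na)
    i_nap = params.g_nap * y[4] * (v - ena)
    act = 1.0 / (1.0 + np.exp(np.clip((params.na_ih - na) / params.na_is,
                                      -500, 500)))
    i_pump = params.ipump_max * act
    extra = {}
    if record_currents:
        extra["i_naf_nA"] = params.g_naf * y[2] ** 3 * y[3] * (v - ena)
        extra["i_nap_native_nA"] = params.g_nap_native * y[5] * (v - ena)
        extra["i_pump_native_nA"] = params.ipump_max_native * act
    return Trace(t, v, i_nap, i_pump, na, extra)


def steady_state_reached(trace: Trace, n_cycles: int = 8, tol: float = 0.1) -> bool:
    """Whether the [Na+]_i oscillation amplitude has settled.

    Detects per-cycle peak-trough amplitudes of the Na+ signal and tests
    whether their relative spread (max-min over mean) across the last
    ``n_cycles`` cycles is within ``tol``.
    """
    from .burst import oscillation_stats

    amps, _, _ = oscillation_stats(trace.na_i, trace.time)
    if len(amps) < n_cycles:
        raise ValueError(
            f"only {len(amps)} cycles detected, need at least {n_cycles}"
        )
    last = np.asarray(amps[-n_cycles:])
    return bool((last.max() - last.min()) / last.mean() <= tol)
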