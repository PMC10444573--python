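"""Voltage- and Na+-dependent gating primitives shared by both neuron models.

All quantities use a consistent unit system: potentials in volts, time in
seconds, conductances in nS, currents in nA (nS x V = nA), capacitance in nF
and concentrations in molar.  Steepness parameters ``A`` therefore carry units
of 1/V and offsets ``B`` units of V.

The sign convention for the Boltzmann steady-state function is
``1 / (1 + exp(A * (V + B)))``: half-(in)activation sits at ``V = -B``, so a
negative ``A`` yields a depolarization-activated gate.  This is the convention
used by every explicitly printed steady-state formula of the reduced model and
by the canonical leech HN model lineage.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "boltzmann",
    "tau_sigmoid",
    "tau_h_naf",
    "h_activation",
    "pump_current",
    "nernst_ena",
]

# RT/F at the experimental temperature, in volts
NERNST_RT_F = 0.02526

#: Hard cap on exponent arguments so extreme voltages saturate instead of
#: overflowing in float64.
_EXP_CAP = 500.0


def _safe_exp(x):
    return np.exp(np.clip(x, -_EXP_CAP, _EXP_CAP))


def boltzmann(A, B, V):
    """Steady-state activation/inactivation ``1 / (1 + exp(A*(V + B)))``.

    Monotone in ``V`` (decreasing for ``A > 0``), saturating to 0/1 at extreme
    voltages without overflow.
    """
    return 1.0 / (1.0 + _safe_exp(A * (np.asarray(V, dtype=float) + B)))


def tau_sigmoid(A, B, C, D, V):
    """Sigmoidal voltage-dependent time constant ``C + D/(1 + exp(A*(V+B)))``.

    ``C`` is the floor reached where the sigmoid vanishes and ``C + D`` the
    opposite plateau, both in seconds.  Raises ``ValueError`` if the result is
    not strictly positive anywhere on the physiological range [-80, +20] mV.
    """
    vs = np.linspace(-0.080, 0.020, 101)
    probe = C + D / (1.0 + _safe_exp(A * (vs + B)))
    if np.any(probe <= 0.0):
        raise ValueError(
            f"tau_sigmoid(A={A}, B={B}, C={C}, D={D}) is non-positive on the "
            "physiological voltage range"
        )
    return C + D / (1.0 + _safe_exp(A * (np.asarray(V, dtype=float) + B)))


def tau_h_naf(V):
    """Inactivation time constant of the fast Na+ current (s).

    ``0.004 + 0.02/cosh(300*(V + 0.0027)) + 0.006/(1 + exp(500*(V + 0.028)))``
    """
    V = np.asarray(V, dtype=float)
    return (
        0.004
        + 0.02 / np.cosh(np.clip(300.0 * (V + 0.0027), -_EXP_CAP, _EXP_CAP))
        + 0.006 / (1.0 + _safe_exp(500.0 * (V + 0.028)))
    )


def h_activation(V, a1=180.0, a2=500.0, half=0.047):
    """Steady-state activation of the hyperpolarization-activated current.

    A double-exponential Boltzmann variant
    ``1 / (1 + 2*exp(a1*(V+half)) + exp(a2*(V+half)))``.  The full model uses
    (180, 500, 0.047); the reduced model's fitted variant uses
    (184.14, 511.5, 0.057).
    """
    V = np.asarray(V, dtype=float)
    return 1.0 / (
        1.0 + 2.0 * _safe_exp(a1 * (V + half)) + _safe_exp(a2 * (V + half))
    )


def pump_current(nai, imax, naih=0.012, nais=0.0016):
    """Na+/K+ pump current (nA), sigmoidally activated by [Na+]_i.

    ``imax / (1 + exp((naih - nai) / nais))`` -- strictly increasing in
    ``nai`` with range (0, imax).  ``naih`` is the half-activation
    concentration and ``nais`` the sensitivity (both molar).
    """
    if nais <= 0:
        raise ValueError("pump sensitivity nais must be positive")
    return imax / (1.0 + _safe_exp((naih - np.asarray(nai, dtype=float)) / nais))


def nernst_ena(nao, nai):
    """Na+ reversal potential ``0.02526 * ln(nao / nai)`` in volts."""
    nao = np.asarray(nao, dtype=float)
    nai = np.asarray(nai, dtype=float)
    if np.any(nao <= 0) or np.any(nai <= 0):
        raise ValueError("concentrations must be positive")
    return NERNST_RT_F * np.log(nao / nai)
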