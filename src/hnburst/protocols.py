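"""The two hybrid-experiment protocols as condition sweeps.

Protocol 1 holds the pump maximum constant and varies the injected
persistent-Na+ conductance over 1-7 nS; protocol 2 holds the conductance at
6 nS and varies the pump maximum over 0.1-0.9 nA.  Each condition is
simulated (seeded), quantified with the burst pipeline, and labeled LA/HA by
the two-threshold rule, producing a tidy table suitable for a two-parameter
regime map or normalized trend plots.

Full-model protocol runs hold the experimental bias current of -0.1 nA, the
steady current kept on the impaled neuron throughout the experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .burst import accept_recording, analyze_trace
from .classify import two_threshold_label
from .full_model import PROTOCOL_BIAS_NA, FullModelParams, simulate_full
from .reduced_model import ReducedModelParams, measure_2d_cycle, simulate_2d

__all__ = ["ProtocolSpec", "protocol_1", "protocol_2", "run_protocol"]


@dataclass
class ProtocolSpec:
    """A list of (g_nap [nS], ipump_max [nA]) conditions to sweep."""

    conditions: list                  # [(g_nap, ipump_max), ...]
    duration: float = 200.0           # per-condition simulated time (s)
    transient: float = 80.0           # discarded before analysis (s)
    seed: int = 0
    protocol_id: int = 0

    def __post_init__(self):
        for g, imax in self.conditions:
            if not (0.0 <= g <= 10.0 and 0.0 <= imax <= 1.0):
                raise ValueError(f"condition ({g}, {imax}) out of range")


def protocol_1(ipump_max: float, g_nap_values=(1, 2, 3, 4, 5, 6, 7),
               **kwargs) -> ProtocolSpec:
    """Fixed pump maximum, varied injected persistent-Na+ conductance."""
    return ProtocolSpec([(float(g), float(ipump_max)) for g in g_nap_values],
                        protocol_id=1, **kwargs)


def protocol_2(g_nap: float = 6.0,
               ipump_values=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
               **kwargs) -> ProtocolSpec:
    """Fixed conductance (6 nS), varied pump maximum."""
    return ProtocolSpec([(float(g_nap), float(i)) for i in ipump_values],
                        protocol_id=2, **kwargs)


def run_protocol(spec: ProtocolSpec, model: str = "full",
                 full_params: FullModelParams | None = None,
                 reduced_params: ReducedModelParams | None = None,
                 ) -> pd.DataFrame:
    """Simulate, analyze and label every condition of a protocol.

    Per-condition failures are recorded (``error`` column) and the sweep
    continues.  Returns one row per condition with timing metrics,
    oscillation amplitudes/medians, acceptance and the LA(0)/HA(1) label.
    """
    rows = []
    for k, (g_nap, imax) in enumerate(spec.conditions):
        row = {"g_nap": g_nap, "ipump_max": imax}
        try:
            if model == "full":
                base = full_params or FullModelParams(i_app=PROTOCOL_BIAS_NA)
                params = base.with_(g_nap=g_nap, ipump_max=imax)
                trace = simulate_full(params, spec.duration,
                                      seed=spec.seed + k)
                _, seg, m = analyze_trace(trace, transient=spec.transient)
                row.update(
                    bd=float(np.mean(m.bd)), ibi=float(np.mean(m.ibi)),
                    period=float(np.mean(m.period)),
                    spike_freq=m.spike_freq,
                    v_amplitude=m.env_v_amplitude,
                    na_amplitude=m.na_amplitude, na_median=m.na_median,
                    ipump_amplitude=m.ipump_amplitude,
                    ipump_median=m.ipump_median,
                    cv_t=m.cv_t, n_bursts=m.n_bursts,
                    accepted=accept_recording(m),
                )
            elif model == "2d":
                base = reduced_params or ReducedModelParams()
                params = base.with_(g_nap=g_nap, ipump_max=imax)
                trace = simulate_2d(params, spec.duration)
                cyc = measure_2d_cycle(trace, transient=spec.transient)
                row.update(
                    bd=cyc.bd, ibi=cyc.ibi, period=cyc.period,
                    v_amplitude=cyc.v_amplitude,
                    na_amplitude=cyc.na_amplitude,
                    n_cycles=cyc.n_cycles, accepted=True,
                )
            else:
                raise ValueError(f"unknown model {model!r}")
            row["label"] = two_threshold_label(row["v_amplitude"],
                                               row["na_amplitude"])
        except Exception as exc:  # per-condition failure, sweep continues
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)
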