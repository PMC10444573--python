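"""Columnar timeseries container for simulated (or recorded) hybrid-neuron data.

A :class:`Trace` mirrors the four signals a dynamic-clamp rig records in real
time: membrane potential, injected persistent Na+ current, injected pump
current, and the virtual intracellular Na+ concentration.  Extra per-current
channels may ride along.  On disk a trace is a plain CSV with the header
``time_s,v_m_V,i_nap_nA,i_pump_nA,na_i_M`` (plus any extra columns), written
with 12 significant digits so a round trip is lossless for analysis purposes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CORE_COLUMNS = ("time_s", "v_m_V", "i_nap_nA", "i_pump_nA", "na_i_M")


@dataclass
class Trace:
    """Uniformly (or adaptively) sampled multichannel timeseries.

    Attributes
    ----------
    time : strictly increasing sample times (s)
    v_m : membrane potential (V)
    i_nap : injected persistent Na+ current (nA)
    i_pump : injected Na+/K+ pump current (nA)
    na_i : intracellular Na+ concentration (M)
    extra : optional named additional channels, same length as ``time``
    """

    time: np.ndarray
    v_m: np.ndarray
    i_nap: np.ndarray
    i_pump: np.ndarray
    na_i: np.ndarray
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        n = self.time.size
        for name in ("v_m", "i_nap", "i_pump", "na_i"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size != n:
                raise ValueError(f"channel {name!r} has length {arr.size}, expected {n}")
            setattr(self, name, arr)
        for k, v in list(self.extra.items()):
            v = np.asarray(v, dtype=float)
            if v.size != n:
                raise ValueError(f"extra channel {k!r} has length {v.size}, expected {n}")
            self.extra[k] = v
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self):
        return self.time.size

    @property
    def dt(self) -> float:
        """Median sampling interval (s)."""
        return float(np.median(np.diff(self.time)))

    @property
    def rate(self) -> float:
        """Nominal sampling rate (Hz)."""
        return 1.0 / self.dt

    def window(self, t_start: float, t_stop: float | None = None) -> "Trace":
        """Sub-trace restricted to ``t_start <= t <= t_stop``."""
        if t_stop is None:
            t_stop = float(self.time[-1])
        m = (self.time >= t_start) & (self.time <= t_stop)
        return Trace(
            self.time[m], self.v_m[m], self.i_nap[m], self.i_pump[m],
            self.na_i[m], {k: v[m] for k, v in self.extra.items()},
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time_s": self.time,
                "v_m_V": self.v_m,
                "i_nap_nA": self.i_nap,
                "i_pump_nA": self.i_pump,
                "na_i_M": self.na_i,
            }
        )
        for k, v in self.extra.items():
            df[k] = v
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Trace":
        missing = [c for c in CORE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trace is missing required columns: {missing}")
        extra = {c: df[c].to_numpy() for c in df.columns if c not in CORE_COLUMNS}
        return cls(
            df["time_s"].to_numpy(), df["v_m_V"].to_numpy(),
            df["i_nap_nA"].to_numpy(), df["i_pump_nA"].to_numpy(),
            df["na_i_M"].to_numpy(), extra,
        )


def write_trace(trace: Trace, path) -> None:
    """Write a trace as CSV with 12 significant digits."""
    trace.to_frame().to_csv(path, index=False, float_format="%.12g")


def read_trace(path) -> Trace:
    """Read a CSV trace, validating the header schema."""
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ValueError(f"malformed trace file {path}: {exc}") from exc
    return Trace.from_frame(df)
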