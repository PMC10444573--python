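"""Burst quantification for spiking membrane-potential traces.

Pipeline: spike detection (peak prominence), burst segmentation by the
800-ms interspike-interval rule with a five-spike minimum, temporal metrics
(burst duration, interburst interval, median-spike cycle period), the
spike-averaged voltage envelope, oscillation amplitude / backside-median
statistics, coefficient-of-variation acceptance, and within-preparation
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks

from .trace import Trace

__all__ = [
    "SpikeTrain", "Burst", "BurstSegmentation", "CycleMetrics",
    "detect_spikes", "segment_bursts", "cycle_metrics", "envelope",
    "oscillation_stats", "accept_recording", "normalize_metrics",
    "analyze_trace",
]


@dataclass
class SpikeTrain:
    """Detected spikes with their peak values and bounding local minima."""

    times: np.ndarray        # spike peak times (s), strictly increasing
    peaks: np.ndarray        # peak voltages (V)
    left_min_idx: np.ndarray   # sample index of the preceding local minimum
    right_min_idx: np.ndarray  # sample index of the following local minimum
    peak_idx: np.ndarray       # sample index of the peak

    def __len__(self):
        return self.times.size


@dataclass
class Burst:
    first: float          # time of first spike (s)
    last: float           # time of last spike (s)
    n_spikes: int
    median_time: float    # time of the median spike (lower median)
    spike_indices: np.ndarray  # indices into the SpikeTrain

    @property
    def duration(self) -> float:
        return self.last - self.first


@dataclass
class BurstSegmentation:
    bursts: list
    ibis: list            # (start, end) of each interburst interval (s)
    flagged: bool = False  # fewer than 2 surviving bursts

    def __len__(self):
        return len(self.bursts)


def detect_spikes(trace: Trace, min_height: float = 0.020,
                  mode: str = "prominence") -> SpikeTrain:
    """Find spikes as voltage peaks of height larger than ``min_height``.

    ``mode='prominence'`` (default) measures height as topographic
    prominence, which is robust to the slow-wave baseline riding under the
    spikes; ``mode='absolute'`` instead keeps peaks whose absolute voltage
    exceeds ``min_height``.  Each spike carries the sample indices of the two
    local minima bounding it (trace endpoints when a spike is first or last).
    """
    v = trace.v_m
    if v.size == 0:
        raise ValueError("empty trace")
    if mode == "prominence":
        pk, _ = find_peaks(v, prominence=min_height)
    elif mode == "absolute":
        pk, _ = find_peaks(v, height=min_height)
    else:
        raise ValueError(f"unknown spike-detection mode {mode!r}")
    minima, _ = find_peaks(-v)
    if minima.size == 0:
        lmin = np.zeros(pk.size)
        rmin = np.full(pk.size, v.size - 1)
    else:
        left = np.searchsorted(minima, pk) - 1
        lmin = np.where(left >= 0, minima[np.clip(left, 0, None)], 0)
        right = np.searchsorted(minima, pk)
        rmin = np.where(right < minima.size,
                        minima[np.clip(right, None, minima.size - 1)],
                        v.size - 1)
    return SpikeTrain(trace.time[pk], v[pk], lmin.astype(int),
                      rmin.astype(int), pk.astype(int))


def segment_bursts(spikes, ibi_threshold: float = 0.8,
                   min_spikes: int = 5) -> BurstSegmentation:
    """Group spikes into bursts by the interspike-interval rule.

    Interspike intervals larger than ``ibi_threshold`` delimit groups; groups
    with fewer than ``min_spikes`` spikes are discarded and their span is
    concatenated, together with the two flanking long intervals, into a
    single interburst interval.  Each interval is assigned to the preceding
    burst.
    """
    times = spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError("spike times must be strictly increasing")
    if times.size == 0:
        return BurstSegmentation([], [], flagged=True)
    isi = np.diff(times)
    breaks = np.where(isi > ibi_threshold)[0]
    groups = np.split(np.arange(times.size), breaks + 1)
    bursts = []
    for g in groups:
        if g.size < min_spikes:
            continue
        t = times[g]
        bursts.append(Burst(
            first=float(t[0]), last=float(t[-1]), n_spikes=int(g.size),
            median_time=float(t[(g.size - 1) // 2]), spike_indices=g,
        ))
    ibis = [(bursts[i].last, bursts[i + 1].first)
            for i in range(len(bursts) - 1)]
    return BurstSegmentation(bursts, ibis, flagged=len(bursts) < 2)


@dataclass
class CycleMetrics:
    """Per-cycle burst characteristics plus envelope/Na+/pump statistics.

    A cycle is a burst together with the following interburst interval; the
    cycle period T runs median-spike to median-spike and is assigned to the
    first of the two bursts.
    """

    bd: np.ndarray
    ibi: np.ndarray
    period: np.ndarray
    inst_freqs: np.ndarray        # within-burst instantaneous frequencies (Hz)
    spike_freq: float             # mean intraburst spike frequency (Hz)
    env_v_amplitude: float = np.nan   # mean envelope oscillation amplitude (V)
    na_amplitude: float = np.nan      # mean [Na+]_i oscillation amplitude (M)
    na_median: float = np.nan         # averaged backside median [Na+]_i (M)
    ipump_amplitude: float = np.nan
    ipump_median: float = np.nan
    n_bursts: int = 0

    @property
    def cv_t(self) -> float:
        return float(np.std(self.period) / np.mean(self.period))

    @property
    def cv_bd(self) -> float:
        return float(np.std(self.bd) / np.mean(self.bd))

    @property
    def cv_ibi(self) -> float:
        return float(np.std(self.ibi) / np.mean(self.ibi))


def cycle_metrics(trace: Trace, seg: BurstSegmentation,
                  spikes: SpikeTrain | None = None) -> CycleMetrics:
    """Temporal and amplitude metrics of a segmented recording.

    The envelope, [Na+]_i and pump-current oscillation statistics are filled
    in when ``trace`` carries those channels and ``spikes`` is given.
    """
    if len(seg) < 2:
        raise ValueError("need at least 2 bursts for cycle metrics")
    bursts = seg.bursts
    bd = np.array([b.duration for b in bursts[:-1]])
    ibi = np.array([e - s for s, e in seg.ibis])
    period = np.array([bursts[i + 1].median_time - bursts[i].median_time
                       for i in range(len(bursts) - 1)])
    if spikes is not None:
        times = spikes.times
    else:
        times = None
    freqs = []
    if times is not None:
        for b in bursts:
            t = times[b.spike_indices]
            if t.size > 1:
                freqs.extend(1.0 / np.diff(t))  # last spike's ISI is the IBI
    freqs = np.asarray(freqs)
    metrics = CycleMetrics(
        bd=bd, ibi=ibi, period=period, inst_freqs=freqs,
        spike_freq=float(freqs.mean()) if freqs.size else np.nan,
        n_bursts=len(bursts),
    )
    if spikes is not None:
        env = envelope(trace, seg, spikes)
        try:
            amps, _, _ = oscillation_stats(env.v_m, env.time)
            metrics.env_v_amplitude = float(np.mean(amps))
        except ValueError:
            pass
        try:
            amps, _, med = oscillation_stats(trace.na_i, trace.time)
            metrics.na_amplitude = float(np.mean(amps))
            metrics.na_median = med
        except ValueError:
            pass
        try:
            amps, _, med = oscillation_stats(trace.i_pump, trace.time)
            metrics.ipump_amplitude = float(np.mean(amps))
            metrics.ipump_median = med
        except ValueError:
            pass
    return metrics


def envelope(trace: Trace, seg: BurstSegmentation,
             spikes: SpikeTrain) -> Trace:
    """Spike-averaged envelope of the membrane potential.

    Within bursts, the potential over each interval between the consecutive
    minima bounding a spike is replaced by its mean; between bursts the
    potential is kept as is.  Returned as a trace sharing the source's time
    support (other channels passed through).
    """
    v = trace.v_m.copy()
    for b in seg.bursts:
        for si in b.spike_indices:
            i0 = spikes.left_min_idx[si]
            i1 = spikes.right_min_idx[si]
            if i1 > i0:
                v[i0:i1 + 1] = trace.v_m[i0:i1 + 1].mean()
    return Trace(trace.time, v, trace.i_nap, trace.i_pump, trace.na_i)


def oscillation_stats(signal, time, rel_prominence: float = 0.25):
    """Peak-trough amplitudes and backside medians of a slow oscillation.

    Peaks and troughs are detected with prominence at least
    ``rel_prominence`` of the signal range and paired: each peak with the
    following trough.  Returns ``(amplitudes, mean_amplitude, median)`` where
    amplitudes are per-cycle peak minus trough and the median is the median
    of the samples on each falling flank (peak to next trough), averaged
    across cycles.
    """
    x = np.asarray(signal, dtype=float)
    rng = x.max() - x.min() if x.size else 0.0
    if x.size == 0 or rng == 0.0:
        raise ValueError("signal has no oscillation")
    prom = rel_prominence * rng
    pks, _ = find_peaks(x, prominence=prom)
    trs, _ = find_peaks(-x, prominence=prom)
    amps, medians = [], []
    for p in pks:
        later = trs[trs > p]
        if later.size:
            tr = later[0]
            amps.append(x[p] - x[tr])
            medians.append(np.median(x[p:tr + 1]))
    if not amps:
        raise ValueError("no peak/trough pair found")
    return amps, float(np.mean(amps)), float(np.mean(medians))


def accept_recording(metrics: CycleMetrics, cv_cutoff: float = 0.25,
                     min_bursts: int = 8) -> bool:
    """Acceptance rule: at least ``min_bursts`` bursts and CV(T) < cutoff."""
    return metrics.n_bursts >= min_bursts and metrics.cv_t < cv_cutoff


_NORMALIZED_FIELDS = ("env_v_amplitude", "na_amplitude", "na_median",
                      "ipump_amplitude", "ipump_median")


def normalize_metrics(metrics: CycleMetrics,
                      reference: CycleMetrics) -> CycleMetrics:
    """Divide timing and amplitude metrics by a within-preparation reference.

    The reference is the recording at the standard condition (pump maximum
    0.3 nA, injected persistent-Na+ conductance 6 nS).
    """
    updates = {}
    for name in ("bd", "ibi", "period"):
        ref = float(np.mean(getattr(reference, name)))
        if ref == 0:
            raise ZeroDivisionError(f"reference {name} is zero")
        updates[name] = getattr(metrics, name) / ref
    for name in _NORMALIZED_FIELDS:
        ref = getattr(reference, name)
        if np.isfinite(ref):
            if ref == 0:
                raise ZeroDivisionError(f"reference {name} is zero")
            updates[name] = getattr(metrics, name) / ref
    return replace(metrics, **updates)


def analyze_trace(trace: Trace, min_height: float = 0.020,
                  ibi_threshold: float = 0.8, min_spikes: int = 5,
                  transient: float = 0.0):
    """Run the full pipeline on a trace.

    Returns ``(spikes, segmentation, metrics)``; ``transient`` seconds are
    discarded from the head of the trace first.
    """
    tr = trace.window(transient) if transient > 0 else trace
    spikes = detect_spikes(tr, min_height=min_height)
    seg = segment_bursts(spikes, ibi_threshold=ibi_threshold,
                         min_spikes=min_spikes)
    metrics = cycle_metrics(tr, seg, spikes)
    return spikes, seg, metrics
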