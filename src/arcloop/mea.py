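"""Multi-electrode-array spike detection and rate summaries.

Multi-unit spikes are detected on each extracellular channel as the first
sample whose absolute voltage reaches a fixed threshold (both polarities,
inclusive comparison), followed by a refractory dead time so a single
biphasic waveform is not counted twice. No spike sorting is attempted.
The headline summary is the mean spike rate per electrode: each channel's
count/duration in Hz, averaged over all channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DEFAULT_THRESHOLD_MV",
    "ElectrodeRecording",
    "SpikeTrainSet",
    "estimate_noise_sd",
    "detect_spikes",
    "mean_rate_per_electrode",
    "rate_timecourse_normalized",
    "burst_fraction",
]

#: Fixed detection threshold in mV (about 2x the baseline noise envelope).
DEFAULT_THRESHOLD_MV = 0.009


@dataclass(frozen=True)
class ElectrodeRecording:
    """Multi-channel extracellular voltage traces in mV."""

    fs: float
    traces: np.ndarray  # shape (n_channels, n_samples)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if np.asarray(self.traces).ndim != 2:
            raise ValueError("traces must be a 2-D (channels x samples) array")

    @property
    def n_channels(self) -> int:
        return self.traces.shape[0]

    @property
    def duration_s(self) -> float:
        return self.traces.shape[1] / self.fs


@dataclass(frozen=True)
class SpikeTrainSet:
    """Per-channel sorted spike times (s) with the detection settings used."""

    trains: tuple[np.ndarray, ...]
    threshold_mv: float
    refractory_s: float


def estimate_noise_sd(trace: Sequence[float]) -> float:
    """Robust noise scale (mV): median absolute deviation / 0.6745.

    The MAD is insensitive to sparse large-amplitude spikes riding on the
    baseline, unlike the plain standard deviation.
    """
    x = np.asarray(trace, dtype=float)
    if x.size < 1000:
        raise ValueError(f"need >= 1000 samples for a noise estimate, got {x.size}")
    return float(np.median(np.abs(x - np.median(x))) / 0.6745)


def _detect_channel(
    trace: np.ndarray, fs: float, threshold: float, dead_samples: int
) -> np.ndarray:
    candidates = np.flatnonzero(np.abs(trace) >= threshold)
    if candidates.size == 0:
        return np.empty(0)
    kept = []
    last = -dead_samples - 1
    for i in candidates:
        if i - last >= dead_samples:
            kept.append(i)
            last = i
    return np.asarray(kept, dtype=float) / fs


def detect_spikes(
    recording: ElectrodeRecording,
    threshold_mv: float = DEFAULT_THRESHOLD_MV,
    refractory_s: float = 0.002,
    adaptive: bool = False,
    adaptive_multiple: float = 6.0,
) -> SpikeTrainSet:
    """Threshold-crossing spike detection on every channel.

    A spike is registered at the first sample with ``|v| >= threshold``
    (inclusive; both polarities), after which ``refractory_s`` of trace is
    ignored. With ``adaptive=True`` the threshold is set per channel to
    ``adaptive_multiple`` times the MAD noise estimate instead of the fixed
    value.
    """
    if threshold_mv <= 0:
        raise ValueError("threshold must be positive")
    dead = max(int(round(refractory_s * recording.fs)), 1)
    trains = []
    for trace in recording.traces:
        thr = (
            adaptive_multiple * estimate_noise_sd(trace) if adaptive else threshold_mv
        )
        trains.append(_detect_channel(trace, recording.fs, thr, dead))
    return SpikeTrainSet(tuple(trains), threshold_mv, refractory_s)


def mean_rate_per_electrode(spikes: SpikeTrainSet, duration_s: float) -> float:
    """Mean over channels of per-channel spike rate (Hz)."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return float(np.mean([len(t) / duration_s for t in spikes.trains]))


def rate_timecourse_normalized(
    rates_by_session: Sequence[tuple[float, float]],
) -> list[tuple[float, float]]:
    """Normalize session rates (time_h, Hz) to the t = 0 session, in %."""
    baseline = [r for t, r in rates_by_session if t == 0]
    if not baseline:
        raise ValueError("no baseline (t = 0) session present")
    if baseline[0] <= 0:
        raise ValueError("baseline rate must be positive for normalization")
    return [(t, 100.0 * r / baseline[0]) for t, r in rates_by_session]


def burst_fraction(
    train: Sequence[float], isi_threshold_s: float = 0.1, min_spikes: int = 3
) -> float:
    """Fraction of spikes inside bursts.

    A burst is a maximal run of >= ``min_spikes`` consecutive spikes whose
    inter-spike intervals are all <= ``isi_threshold_s``.
    """
    t = np.sort(np.asarray(train, dtype=float))
    if t.size == 0:
        return 0.0
    close = np.diff(t) <= isi_threshold_s  # close[i]: gap i..i+1 is short
    in_burst = np.zeros(t.size, dtype=bool)
    run_start = 0
    for i in range(close.size + 1):
        if i == close.size or not close[i]:
            run_len = i - run_start + 1  # spikes in this run
            if run_len >= min_spikes:
                in_burst[run_start : i + 1] = True
            run_start = i + 1
    return float(in_burst.mean())
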