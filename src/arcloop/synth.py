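"""Synthetic data generators for every input the pipeline consumes.

All generators are pure functions of an explicit integer seed: noisy
replicate time-course tables (qPCR/western-style, multiplicative noise on
deterministic turnover or feedback trajectories), delta-Ct qPCR tables with
planted fold changes, and multi-channel extracellular recordings with
Gaussian baseline noise plus planted biphasic spikes at Poisson or
burst-structured times (ground truth returned alongside).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import feedback as fb
from .kinetics import Condition, PerturbationSchedule, RateConstants, simulate
from .mea import ElectrodeRecording

__all__ = [
    "NoiseSpec",
    "DEFAULT_KINETIC_TIMES_H",
    "DEFAULT_PROTOCOL_TIMES_H",
    "DEFAULT_NOISE_SD_MV",
    "synth_timecourse_table",
    "synth_feedback_table",
    "synth_qpcr_table",
    "synth_recording",
    "poisson_spike_times",
    "burst_spike_times",
    "spike_template",
]

#: Sampling grids mirroring typical inhibitor-chase and activity-protocol designs.
DEFAULT_KINETIC_TIMES_H = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0)
DEFAULT_PROTOCOL_TIMES_H = (0.0, 0.5, 1.0, 2.0, 6.0, 12.0, 24.0, 48.0)

#: Baseline noise sd in mV. The detection threshold of 0.009 mV is read as
#: 2x the noise *envelope* (~3 sd), i.e. 6 sd, so that threshold crossings
#: by noise alone are vanishingly rare (see docs/methods.md).
DEFAULT_NOISE_SD_MV = 0.0015


@dataclass(frozen=True)
class NoiseSpec:
    """Replicate noise model: CV, distribution family, count and seed."""

    cv: float = 0.10
    distribution: str = "lognormal"
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.distribution not in ("lognormal", "truncated_gaussian"):
            raise ValueError(f"unknown distribution {self.distribution!r}")


def _noise_factors(noise: NoiseSpec, size: tuple[int, ...], rng) -> np.ndarray:
    """Unit-mean multiplicative noise factors with the requested CV."""
    if noise.cv == 0:
        return np.ones(size)
    if noise.distribution == "lognormal":
        sigma = math.sqrt(math.log(1.0 + noise.cv**2))
        return np.exp(rng.normal(-0.5 * sigma**2, sigma, size))
    a = (0.0 - 1.0) / noise.cv  # truncate at zero
    return stats.truncnorm.rvs(a, np.inf, loc=1.0, scale=noise.cv, size=size,
                               random_state=rng)


def synth_timecourse_table(
    params: RateConstants,
    condition: Condition | PerturbationSchedule,
    times: Sequence[float] = DEFAULT_KINETIC_TIMES_H,
    noise: NoiseSpec = NoiseSpec(),
    label: str | None = None,
    analytes: Sequence[str] = ("mrna", "protein"),
) -> pd.DataFrame:
    """Noisy replicate measurement table from a turnover-model trajectory.

    Truth comes from the piecewise-analytic simulator; each (time,
    replicate, analyte) observation is truth times an i.i.d. unit-mean
    noise factor. Deterministic given ``noise.seed``.
    """
    traj = simulate(params, condition, times)
    if label is None:
        label = condition.label if isinstance(condition, Condition) else "schedule"
    rng = np.random.default_rng(noise.seed)
    truth = {"mrna": traj.mrna, "protein": traj.protein}
    rows = []
    for analyte in analytes:
        values = truth[analyte]
        factors = _noise_factors(noise, (noise.n_replicates, len(values)), rng)
        for rep in range(noise.n_replicates):
            rows.append(
                pd.DataFrame(
                    {
                        "condition": label,
                        "analyte": analyte,
                        "time_h": np.asarray(times, dtype=float),
                        "replicate": rep + 1,
                        "value_pct": values * factors[rep],
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def synth_feedback_table(
    params: fb.FeedbackParams,
    protocol_name: str,
    times: Sequence[float] = DEFAULT_PROTOCOL_TIMES_H,
    noise: NoiseSpec = NoiseSpec(),
    t_end: float | None = None,
) -> pd.DataFrame:
    """Noisy replicate table of feedback-loop analytes under a protocol."""
    t_end = float(max(times)) if t_end is None else t_end
    prot = fb.protocol(protocol_name, t_end=t_end)
    dt = min(np.diff(np.unique(times)).min() / 2, 0.05) if len(times) > 1 else 0.05
    traj = fb.simulate_protocol(params, prot, dt_out=dt)
    idx = np.searchsorted(traj.times, np.asarray(times, dtype=float))
    idx = np.clip(idx, 0, traj.times.size - 1)
    rng = np.random.default_rng(noise.seed)
    series = {
        "mrna": traj.mrna_pct[idx],
        "protein": traj.protein_pct[idx],
        "p_erk": traj.erk_pct[idx],
        "spike_rate": traj.spike_rate_pct[idx],
    }
    rows = []
    for analyte, values in series.items():
        factors = _noise_factors(noise, (noise.n_replicates, len(values)), rng)
        for rep in range(noise.n_replicates):
            rows.append(
                pd.DataFrame(
                    {
                        "condition": protocol_name.lower(),
                        "analyte": analyte,
                        "time_h": np.asarray(times, dtype=float),
                        "replicate": rep + 1,
                        "value_pct": values * factors[rep],
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def synth_qpcr_table(
    quantities: Mapping[str, float],
    ct_reference_mean: float = 20.0,
    efficiency: float = 2.0,
    ct_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    control: str = "control",
) -> pd.DataFrame:
    """Ct table with planted relative quantities (delta-delta-Ct invertible).

    ``quantities`` maps sample label -> relative quantity; the control
    sample (added with quantity 1 if absent) anchors the normalization.
    Columns: sample, replicate, ct_target, ct_reference.
    """
    if efficiency <= 1:
        raise ValueError("efficiency must exceed 1")
    if any(q <= 0 for q in quantities.values()):
        raise ValueError("planted quantities must be positive")
    quantities = dict(quantities)
    quantities.setdefault(control, 1.0)
    base_delta = 5.0  # control-group target-minus-reference Ct offset
    rng = np.random.default_rng(seed)
    rows = []
    log_e = math.log(efficiency)
    for sample, q in quantities.items():
        for rep in range(1, n_replicates + 1):
            ct_ref = ct_reference_mean + rng.normal(0, ct_sd) if ct_sd else ct_reference_mean
            delta = base_delta - math.log(q) / log_e
            ct_tgt = ct_ref + delta + (rng.normal(0, ct_sd) if ct_sd else 0.0)
            rows.append((sample, rep, ct_tgt, ct_ref))
    return pd.DataFrame(
        rows, columns=["sample", "replicate", "ct_target", "ct_reference"]
    )


def spike_template(fs: float, duration_s: float = 0.0015) -> np.ndarray:
    """Biphasic waveform: one cycle of a damped sine, unit peak amplitude."""
    t = np.arange(0.0, duration_s, 1.0 / fs)
    w = -np.sin(2 * np.pi * t / duration_s) * np.exp(-2.0 * t / duration_s)
    peak = np.max(np.abs(w))
    return w / peak if peak > 0 else w


def poisson_spike_times(rate_hz: float, duration_s: float, rng) -> np.ndarray:
    """Homogeneous Poisson spike times on [0, duration)."""
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, n))


def burst_spike_times(
    duration_s: float,
    rng,
    burst_rate_hz: float = 0.5,
    spikes_per_burst: int = 5,
    intra_isi_s: float = 0.01,
    isolated_rate_hz: float = 1.0,
) -> np.ndarray:
    """Burst-modulated train: Poisson burst onsets plus isolated spikes."""
    onsets = poisson_spike_times(burst_rate_hz, duration_s, rng)
    bursts = [
        onset + intra_isi_s * np.arange(spikes_per_burst) for onset in onsets
    ]
    isolated = poisson_spike_times(isolated_rate_hz, duration_s, rng)
    times = np.sort(np.concatenate(bursts + [isolated])) if bursts or isolated.size else isolated
    return times[times < duration_s]


def synth_recording(
    fs: float = 20_000.0,
    duration_s: float = 10.0,
    n_channels: int = 8,
    noise_sd_mv: float = DEFAULT_NOISE_SD_MV,
    rate_hz: float | None = None,
    spike_times: Sequence[Sequence[float]] | None = None,
    amplitude_mv: float = 0.03,
    seed: int = 0,
    burst: bool = False,
) -> tuple[ElectrodeRecording, list[np.ndarray]]:
    """Gaussian-noise traces with planted biphasic spikes; truth returned.

    Spike times per channel come from ``spike_times`` if given, otherwise
    from a homogeneous Poisson process at ``rate_hz`` (or a bursting
    process when ``burst=True``). Spikes closer together than the template
    width trigger a warning; the ground truth keeps both.
    """
    if fs <= 0 or duration_s <= 0:
        raise ValueError("fs and duration must be positive")
    rng = np.random.default_rng(seed)
    n_samples = int(round(fs * duration_s))
    template = amplitude_mv * spike_template(fs)
    width = template.size

    traces = rng.normal(0.0, noise_sd_mv, (n_channels, n_samples))
    truth: list[np.ndarray] = []
    for ch in range(n_channels):
        if spike_times is not None:
            times = np.sort(np.asarray(spike_times[ch], dtype=float))
        elif rate_hz is not None:
            times = (
                burst_spike_times(duration_s, rng)
                if burst
                else poisson_spike_times(rate_hz, duration_s, rng)
            )
        else:
            times = np.empty(0)
        if times.size > 1 and (np.diff(times) < width / fs).any():
            warnings.warn("planted spikes overlap within the template width")
        for t0 in times:
            i0 = int(round(t0 * fs))
            i1 = min(i0 + width, n_samples)
            if i0 < n_samples:
                traces[ch, i0:i1] += template[: i1 - i0]
        truth.append(times)
    return ElectrodeRecording(fs=fs, traces=traces), truth
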