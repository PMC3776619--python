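"""Closed-loop homeostatic control of network activity by an IEG actuator.

The loop couples five stages, mirroring the sensor→controller→actuator→plant
architecture of homeostatic synaptic scaling in cultured hippocampal
networks:

* network spike rate (algebraic, instantaneous):
  ``a = a0 * drive * w * s_na`` — excitatory drive times synaptic weight,
  gated by sodium channels (TTX sets ``s_na = 0``);
* calcium sensor: ``c = s_ca * a / a0`` (NMDAR + L-VGCC lumped into one
  factor ``s_ca``; CPP+nimodipine sets it to 0);
* ERK controller: first-order relaxation ``de/dt = (u_erk * c - e)/tau_e``
  (MEK inhibition by U0126 sets ``u_erk = 0``);
* Arc transcription actuator: Hill-type activation with an
  activity-independent floor,
  ``r_eff = r * (beta + (1 - beta) * e**n_hill)``, feeding the
  two-compartment mRNA/protein turnover model;
* plant: multiplicative synaptic-weight adjustment
  ``dw/dt = -k_w * eta * (p - 1) * w`` within hard bounds — protein above
  baseline scales synapses down, below baseline scales them up.

The interior fixed point has exact adaptation: for any sustained drive D
(within weight bounds) the unique equilibrium is a = a0, e = m = p = 1,
w = 1/D, so the spike rate returns precisely to its set point while the
synaptic weight absorbs the perturbation.

State vector order used throughout: (e, m, p, w).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetics import RateConstants

__all__ = [
    "FeedbackParams",
    "FeedbackState",
    "Protocol",
    "FeedbackTrajectory",
    "protocol",
    "PROTOCOL_NAMES",
    "feedback_derivatives",
    "simulate_protocol",
    "peak_time",
    "recovery_time",
    "D_PTX",
    "D_TSC",
]

#: Disinhibition factor applied by picrotoxin (GABA-A block).
D_PTX = 3.0
#: Tonic drive of Tsc1-KO networks; exceeds 1/w_min so that synaptic
#: down-scaling cannot fully compensate and the loop stays engaged.
D_TSC = 20.0


@dataclass(frozen=True)
class FeedbackParams:
    """Parameters of the closed homeostatic loop.

    ``a0`` baseline network spike rate (Hz); ``drive`` disinhibition factor
    (1 = baseline); ``tau_e`` ERK relaxation time (h); ``n_hill``
    transcription-activation exponent; ``beta`` activity-independent
    transcription floor (fraction of basal, ties the loop to the open-loop
    activity-blockade observation that mRNA settles at 62.5% of baseline
    production); ``k_w`` weight-adjustment gain (1/h); ``w_bounds`` hard
    bounds on the synaptic weight; ``s_na``/``s_ca``/``u_erk``/``eta``
    pharmacological and genetic gates on sodium channels, the calcium
    sensor, the ERK controller and the Arc actuator.
    """

    a0: float = 7.52
    drive: float = 1.0
    tau_e: float = 0.5
    n_hill: float = 2.0
    beta: float = 0.625
    k_w: float = 0.15
    w_bounds: tuple[float, float] = (0.1, 3.0)
    s_na: float = 1.0
    s_ca: float = 1.0
    u_erk: float = 1.0
    eta: float = 1.0
    kinetics: RateConstants = field(default_factory=RateConstants)

    def __post_init__(self) -> None:
        if self.a0 <= 0 or self.drive <= 0 or self.tau_e <= 0:
            raise ValueError("a0, drive and tau_e must be positive")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        lo, hi = self.w_bounds
        if not (0 < lo < 1 < hi):
            raise ValueError("w_bounds must be valid and contain 1")
        for name in ("s_na", "s_ca", "u_erk", "eta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class FeedbackState:
    """Loop state: spike rate (Hz) plus baseline-normalized e, m, p, w."""

    a: float
    e: float
    m: float
    p: float
    w: float

    def __post_init__(self) -> None:
        if min(self.a, self.e, self.m, self.p, self.w) < 0:
            raise ValueError("all state variables must be non-negative")


@dataclass(frozen=True)
class Protocol:
    """Named perturbation protocol: timed parameter overrides."""

    name: str
    t_end: float
    events: tuple[tuple[float, Mapping[str, float]], ...] = ()

    def __post_init__(self) -> None:
        for t, _ in self.events:
            if not 0.0 <= t <= self.t_end:
                raise ValueError("event times must lie within [0, t_end]")


def _presets(d_ptx: float, d_tsc: float) -> dict[str, tuple]:
    ptx = ((0.0, {"drive": d_ptx}),)
    return {
        "BASELINE": (),
        "PTX": ptx,
        "TTX": ((0.0, {"s_na": 0.0}),),
        # drugs the paper tested on the picrotoxin background: the PTX drive
        # step is part of the preset
        "U0126": ((0.0, {"drive": d_ptx, "u_erk": 0.0}),),
        "CPP_NIM": ((0.0, {"drive": d_ptx, "s_ca": 0.0}),),
        "MPEP": ptx,
        "AIDA": ptx,
        "NASPM": ptx,
        "RAPAMYCIN": ptx,
        "ARC_NULL": ((0.0, {"drive": d_ptx, "eta": 0.0}),),
        # standalone (basal-background) sensor blocks
        "CPP_NIM_BASAL": ((0.0, {"s_ca": 0.0}),),
        "U0126_BASAL": ((0.0, {"u_erk": 0.0}),),
        # Tsc1 KO: tonic drive from t=0; rescue drugs added at 24 h
        "TSC1_KO": ((0.0, {"drive": d_tsc}),),
        "TSC1_KO_TTX": ((0.0, {"drive": d_tsc}), (24.0, {"s_na": 0.0})),
        "TSC1_KO_CPP_NIM": ((0.0, {"drive": d_tsc}), (24.0, {"s_ca": 0.0})),
    }


PROTOCOL_NAMES = tuple(_presets(D_PTX, D_TSC))


def protocol(
    name: str, t_end: float = 48.0, d_ptx: float = D_PTX, d_tsc: float = D_TSC
) -> Protocol:
    """Build a preset protocol by name (see :data:`PROTOCOL_NAMES`)."""
    presets = _presets(d_ptx, d_tsc)
    key = name.upper()
    if key not in presets:
        raise ValueError(f"unknown protocol {name!r}; choose from {PROTOCOL_NAMES}")
    return Protocol(key, t_end, presets[key])


def activity(w: float, params: FeedbackParams) -> float:
    """Instantaneous network spike rate in Hz."""
    return params.a0 * params.drive * w * params.s_na


def feedback_derivatives(
    state: Sequence[float], params: FeedbackParams
) -> np.ndarray:
    """Time derivatives (de/dt, dm/dt, dp/dt, dw/dt) of the closed loop."""
    e, m, p, w = state
    kin = params.kinetics
    a = activity(w, params)
    c = params.s_ca * a / params.a0
    de = (params.u_erk * c - e) / params.tau_e
    r_eff = kin.r * (params.beta + (1.0 - params.beta) * e**params.n_hill)
    dm = r_eff - kin.k_mrna_deg * m
    dp = kin.k_tl * m - kin.k_p * p
    dw = -params.k_w * params.eta * (p - 1.0) * w
    lo, hi = params.w_bounds
    if (w <= lo and dw < 0) or (w >= hi and dw > 0):
        dw = 0.0  # soft clip: the weight cannot leave its bounds
    return np.array([de, dm, dp, dw])


VARIABLES = ("spike_rate", "erk", "mrna", "protein", "weight")


@dataclass(frozen=True)
class FeedbackTrajectory:
    """Sampled loop trajectory; all columns % of baseline except Hz."""

    times: np.ndarray
    spike_rate_hz: np.ndarray
    spike_rate_pct: np.ndarray
    erk_pct: np.ndarray
    mrna_pct: np.ndarray
    protein_pct: np.ndarray
    weight_pct: np.ndarray

    def variable(self, name: str) -> np.ndarray:
        """Percent-of-baseline series for one of ``VARIABLES``."""
        try:
            return {
                "spike_rate": self.spike_rate_pct,
                "erk": self.erk_pct,
                "mrna": self.mrna_pct,
                "protein": self.protein_pct,
                "weight": self.weight_pct,
            }[name]
        except KeyError:
            raise ValueError(
                f"unknown variable {name!r}; choose from {VARIABLES}"
            ) from None

    def to_frame(self, condition: str = "") -> pd.DataFrame:
        """Long-format export matching the turnover-trajectory CSV dialect."""
        frames = []
        columns = {
            "spike_rate_hz": self.spike_rate_hz,
            "spike_rate_pct": self.spike_rate_pct,
            "p_erk_pct": self.erk_pct,
            "mrna_pct": self.mrna_pct,
            "protein_pct": self.protein_pct,
            "weight_pct": self.weight_pct,
        }
        for analyte, values in columns.items():
            frames.append(
                pd.DataFrame(
                    {
                        "condition": condition,
                        "analyte": analyte,
                        "time_h": self.times,
                        "value_pct": values,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def simulate_protocol(
    params: FeedbackParams,
    prot: Protocol,
    dt_out: float = 0.05,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> FeedbackTrajectory:
    """Integrate the closed loop under a protocol; deterministic.

    Overrides are applied exactly at their event times; between events the
    smooth system is integrated adaptively (LSODA) and sampled on the
    ``dt_out`` grid. The initial state is the unperturbed fixed point
    (e = m = p = w = 1).
    """
    if dt_out <= 0:
        raise ValueError("dt_out must be positive")
    times = np.round(np.arange(0.0, prot.t_end + dt_out / 2, dt_out), 12)
    breakpoints = sorted({0.0, prot.t_end, *(t for t, _ in prot.events)})
    events = dict(prot.events)  # later events at equal times win; fine here

    state = np.array([1.0, 1.0, 1.0, 1.0])
    current = params
    out = np.empty((4, times.size))
    a_out = np.empty(times.size)

    for t0, t1 in zip(breakpoints, breakpoints[1:] + [None]):
        if t0 in events:
            current = dataclasses.replace(current, **dict(events[t0]))
        if t1 is None:
            break
        mask = (times >= t0 - 1e-12) & (times <= t1 + 1e-12)
        t_eval = np.clip(times[mask], t0, t1)
        sol = solve_ivp(
            lambda t, y: feedback_derivatives(y, current),
            (t0, t1),
            state,
            method="LSODA",
            t_eval=t_eval if t_eval.size else None,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed on [{t0}, {t1}]: {sol.message}")
        if t_eval.size:
            lo, hi = current.w_bounds
            y = sol.y.copy()
            y[3] = np.clip(y[3], lo, hi)
            out[:, mask] = y
            a_out[mask] = np.array([activity(w, current) for w in y[3]])
        state = sol.y[:, -1]

    return FeedbackTrajectory(
        times=times,
        spike_rate_hz=a_out,
        spike_rate_pct=100.0 * a_out / params.a0,
        erk_pct=100.0 * out[0],
        mrna_pct=100.0 * out[1],
        protein_pct=100.0 * out[2],
        weight_pct=100.0 * out[3],
    )


def peak_time(traj: FeedbackTrajectory, variable: str) -> float:
    """Time of the global maximum of a variable; earliest time wins ties."""
    values = traj.variable(variable)
    if values.size == 0:
        raise ValueError("empty trajectory")
    return float(traj.times[int(np.argmax(values))])


def recovery_time(
    traj: FeedbackTrajectory, variable: str, tolerance_fraction: float
) -> float | None:
    """Earliest post-peak time with |x - baseline|/baseline within tolerance.

    The variable must stay within the band through the end of the
    trajectory; returns ``None`` if it never does (not recovered).
    Baseline is 100% (the unperturbed fixed point).
    """
    if not 0.0 < tolerance_fraction < 1.0:
        raise ValueError("tolerance_fraction must lie in (0, 1)")
    values = traj.variable(variable)
    if values.size == 0:
        raise ValueError("empty trajectory")
    i_peak = int(np.argmax(values))
    ok = np.abs(values - 100.0) <= 100.0 * tolerance_fraction
    if not ok[-1]:
        return None
    bad = np.flatnonzero(~ok)
    i_rec = 0 if bad.size == 0 else int(bad[-1]) + 1
    return float(traj.times[max(i_rec, i_peak)])
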