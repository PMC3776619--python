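"""Two-compartment turnover model of an immediate-early gene (Arc).

The model tracks mRNA (``M``) and protein (``P``) in baseline-normalized
units (basal steady state = 1) with zero-order transcription and first-order
decay, translation and degradation:

.. math::

    dM/dt &= r \\cdot u_{tx} - (k_{nt} + k_{tdd} \\cdot u_{tl})\\, M \\\\
    dP/dt &= k_{tl} \\cdot u_{tl}\\, M - k_p\\, P

The distinguishing kinetic feature is *translation-dependent decay* (TDD):
a component ``k_tdd`` of mRNA turnover that is active only while the
message is being translated, so blocking translation (cycloheximide,
``u_tl = 0``) both halts protein synthesis and stabilizes the mRNA.
Pharmacological conditions enter only through the two scale factors
``u_tx`` (transcription) and ``u_tl`` (translation), which makes the system
piecewise linear and exactly solvable on each segment of a drug schedule.

Units: time in hours, rate constants in 1/h, abundances baseline-normalized
(trajectories are reported as % of baseline, i.e. ×100).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_K_P",
    "RateConstants",
    "Condition",
    "PerturbationSchedule",
    "Trajectory",
    "BASAL",
    "ACTD",
    "CHX",
    "ACTD_CHX",
    "TTX",
    "RAPAMYCIN",
    "CONDITIONS",
    "effective_rates",
    "derivatives",
    "steady_state",
    "simulate",
]

#: Default protein degradation constant (1/h): sqrt(1.6^2 - 0.8^2), the
#: residual-translation-corrected value; the rounded 1.36 1/h agrees to 2%.
DEFAULT_K_P = math.sqrt(1.6**2 - 0.8**2)


@dataclass(frozen=True)
class RateConstants:
    """Kinetic parameters of the two-compartment turnover model.

    Parameters
    ----------
    r : float
        Zero-order transcription rate (baseline-normalized abundance / h).
    k_nt : float
        Translation-independent mRNA decay constant (1/h).
    k_tdd : float
        Translation-dependent mRNA decay constant (1/h); active only while
        translation is ongoing.
    k_tl : float
        First-order translation rate (1/h).
    k_p : float
        First-order protein degradation constant (1/h).

    The defaults make both basal steady states exactly 1 in normalized
    units: r / (k_nt + k_tdd) = 1.6 / 1.6 = 1 and k_tl = k_p.
    """

    r: float = 1.6
    k_nt: float = 0.98
    k_tdd: float = 0.62
    k_tl: float = DEFAULT_K_P
    k_p: float = DEFAULT_K_P

    def __post_init__(self) -> None:
        for name in ("r", "k_nt", "k_tdd", "k_tl", "k_p"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.k_nt + self.k_tdd <= 0:
            raise ValueError("basal mRNA decay k_nt + k_tdd must be positive")

    @property
    def k_mrna_deg(self) -> float:
        """Total basal mRNA decay constant k_nt + k_tdd (1/h)."""
        return self.k_nt + self.k_tdd


@dataclass(frozen=True)
class Condition:
    """A pharmacological condition as transcription/translation scaling.

    ``u_tx`` scales transcription, ``u_tl`` scales translation (and with it
    the TDD component of mRNA decay). Both must lie in [0, 1].
    """

    u_tx: float
    u_tl: float
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.u_tx <= 1.0:
            raise ValueError(f"u_tx must be in [0, 1], got {self.u_tx}")
        if not 0.0 <= self.u_tl <= 1.0:
            raise ValueError(f"u_tl must be in [0, 1], got {self.u_tl}")


BASAL = Condition(1.0, 1.0, "basal")
#: Actinomycin D: transcription blocked.
ACTD = Condition(0.0, 1.0, "actd")
#: Cycloheximide: translation blocked (stabilizes a TDD substrate).
CHX = Condition(1.0, 0.0, "chx")
ACTD_CHX = Condition(0.0, 0.0, "actd_chx")
#: Action-potential blockade: residual activity-independent transcription
#: chosen so that mRNA is 64% of baseline 2 h after onset.
TTX = Condition(0.625, 1.0, "ttx")
#: mTORC1 inhibition leaves global Arc translation and turnover unchanged.
RAPAMYCIN = Condition(1.0, 1.0, "rapamycin")

CONDITIONS: dict[str, Condition] = {
    c.label: c for c in (BASAL, ACTD, CHX, ACTD_CHX, TTX, RAPAMYCIN)
}


@dataclass(frozen=True)
class PerturbationSchedule:
    """Piecewise-constant drug regime: ordered (t_start, condition) segments."""

    segments: tuple[tuple[float, Condition], ...]
    t_end: float

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule needs at least one segment")
        starts = [t for t, _ in self.segments]
        if starts[0] != 0.0:
            raise ValueError("first segment must start at t = 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("segment start times must be strictly increasing")
        if self.t_end <= starts[-1]:
            raise ValueError("t_end must exceed the last segment start")

    @classmethod
    def constant(cls, condition: Condition, t_end: float) -> "PerturbationSchedule":
        return cls(((0.0, condition),), t_end)


@dataclass(frozen=True)
class Trajectory:
    """Simulated time courses, % of baseline vs hours."""

    times: np.ndarray
    mrna: np.ndarray
    protein: np.ndarray

    def to_frame(self, condition: str = "") -> pd.DataFrame:
        """Long-format table with columns condition, analyte, time_h, value_pct."""
        frames = []
        for analyte, values in (("mrna", self.mrna), ("protein", self.protein)):
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


def effective_rates(
    params: RateConstants, condition: Condition
) -> tuple[float, float, float, float]:
    """Per-condition rates: (transcription, mRNA decay, translation, protein decay).

    Transcription scales with ``u_tx``; the TDD component of mRNA decay and
    the translation rate scale with ``u_tl``; protein degradation is
    condition-independent.
    """
    return (
        params.r * condition.u_tx,
        params.k_nt + params.k_tdd * condition.u_tl,
        params.k_tl * condition.u_tl,
        params.k_p,
    )


def derivatives(
    state: Sequence[float], params: RateConstants, condition: Condition
) -> tuple[float, float]:
    """Right-hand side (dM/dt, dP/dt) in baseline-normalized units per hour."""
    m, p = state
    if m < 0 or p < 0:
        raise ValueError(f"state must be non-negative, got M={m}, P={p}")
    r_eff, k_m, k_tl_eff, k_p = effective_rates(params, condition)
    return (r_eff - k_m * m, k_tl_eff * m - k_p * p)


def steady_state(
    params: RateConstants, condition: Condition
) -> tuple[float, float]:
    """Fixed point (M*, P*) under a constant condition, normalized units."""
    r_eff, k_m, k_tl_eff, k_p = effective_rates(params, condition)
    if k_m <= 0:
        raise ValueError("no steady state: mRNA decay is zero under this condition")
    if k_p <= 0:
        raise ValueError("no steady state: protein decay is zero")
    m_star = r_eff / k_m
    return m_star, k_tl_eff * m_star / k_p


def _advance(
    t: np.ndarray,
    m0: float,
    p0: float,
    r_eff: float,
    k_m: float,
    k_tl: float,
    k_p: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form (M(t), P(t)) for constant rates from state (m0, p0) at t=0.

    mRNA relaxes exponentially toward its segment steady state; protein is
    the convolution of that exponential with its own first-order decay
    (a double exponential). Degenerate rate combinations (k_m = 0, k_p = 0,
    k_p = k_m) take their analytic limits.
    """
    t = np.asarray(t, dtype=float)
    # --- mRNA ---
    if k_m > 0:
        m_inf = r_eff / k_m
        em = np.exp(-k_m * t)
        m = m_inf + (m0 - m_inf) * em
    else:
        m = m0 + r_eff * t

    # --- protein: dP/dt = k_tl * M(t) - k_p * P ---
    if k_p > 0 and k_m > 0:
        p_inf = k_tl * m_inf / k_p
        ep = np.exp(-k_p * t)
        if abs(k_p - k_m) > 1e-9 * max(k_p, k_m):
            c = k_tl * (m0 - m_inf) / (k_p - k_m)
            p = p_inf + (p0 - p_inf - c) * ep + c * em
        else:  # k_p == k_m: the cross term degenerates to t * exp(-k t)
            p = p_inf + (p0 - p_inf) * ep + k_tl * (m0 - m_inf) * t * ep
    elif k_p > 0:  # k_m == 0, M linear in t
        # particular solution for a linear source k_tl*(m0 + r_eff t)
        part = (k_tl / k_p) * (m0 + r_eff * t) - k_tl * r_eff / k_p**2
        part0 = k_tl * m0 / k_p - k_tl * r_eff / k_p**2
        p = part + (p0 - part0) * np.exp(-k_p * t)
    else:  # k_p == 0: P accumulates the integral of k_tl * M
        if k_m > 0:
            integral = m_inf * t + (m0 - m_inf) * (1.0 - np.exp(-k_m * t)) / k_m
        else:
            integral = m0 * t + 0.5 * r_eff * t**2
        p = p0 + k_tl * integral
    return m, p


def simulate(
    params: RateConstants,
    schedule: PerturbationSchedule | Condition,
    times: Sequence[float],
    initial_state: tuple[float, float] | None = None,
) -> Trajectory:
    """Piecewise-analytic trajectory of the turnover model, % of baseline.

    Parameters
    ----------
    params
        Kinetic rate constants.
    schedule
        A :class:`PerturbationSchedule`, or a bare :class:`Condition`
        (treated as constant from t = 0 through ``max(times)``).
    times
        Sample times in hours, within [0, t_end].
    initial_state
        (M, P) in baseline-normalized units at t = 0; defaults to the basal
        steady state.

    The baseline used for the % scaling is the basal (unperturbed) steady
    state of ``params``, so a basal simulation sits at exactly 100.
    """
    if isinstance(schedule, Condition):
        t_end = float(np.max(times)) if len(times) else 0.0
        schedule = PerturbationSchedule.constant(schedule, max(t_end, 1e-12))
    times = np.asarray(times, dtype=float)
    if times.size and (times.min() < 0 or times.max() > schedule.t_end + 1e-12):
        raise ValueError("sample times must lie within [0, t_end] of the schedule")

    m_base, p_base = steady_state(params, BASAL)
    state = (m_base, p_base) if initial_state is None else tuple(initial_state)

    starts = [t for t, _ in schedule.segments]
    bounds = starts[1:] + [schedule.t_end]
    mrna = np.empty_like(times)
    protein = np.empty_like(times)
    for (t0, cond), t1 in zip(schedule.segments, bounds):
        r_eff, k_m, k_tl_eff, k_p = effective_rates(params, cond)
        if t1 == schedule.t_end:  # last segment: closed on the right
            mask = (times >= t0) & (times <= t1 + 1e-12)
        else:
            mask = (times >= t0) & (times < t1)
        if mask.any():
            m, p = _advance(times[mask] - t0, *state, r_eff, k_m, k_tl_eff, k_p)
            mrna[mask] = m
            protein[mask] = p
        # advance the state to the segment boundary
        m_b, p_b = _advance(np.array([t1 - t0]), *state, r_eff, k_m, k_tl_eff, k_p)
        state = (float(m_b[0]), float(p_b[0]))

    p_scale = 100.0 / p_base if p_base > 0 else np.nan
    return Trajectory(times, 100.0 * mrna / m_base, protein * p_scale)
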