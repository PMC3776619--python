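"""Configuration schema and file I/O for the pipeline.

Run configurations are single-document YAML or JSON with units embedded in
key names (``r_per_h``, ``tau_e_h`` ...). Unknown keys are rejected.
Tables travel as long-format CSV (one observation per row); recordings as
a float CSV matrix next to a small JSON header.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .feedback import FeedbackParams
from .kinetics import CONDITIONS, Condition, PerturbationSchedule, RateConstants
from .mea import ElectrodeRecording
from .synth import NoiseSpec

__all__ = [
    "KineticsConfig",
    "FeedbackConfig",
    "NoiseConfig",
    "ScheduleSegment",
    "RunConfig",
    "load_config",
    "read_measurement_table",
    "write_measurement_table",
    "save_recording",
    "load_recording",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class KineticsConfig(_Strict):
    r_per_h: float = 1.6
    k_nt_per_h: float = 0.98
    k_tdd_per_h: float = 0.62
    k_tl_per_h: Optional[float] = None  # defaults to k_p
    k_p_per_h: float = RateConstants().k_p

    def to_params(self) -> RateConstants:
        k_tl = self.k_p_per_h if self.k_tl_per_h is None else self.k_tl_per_h
        return RateConstants(
            r=self.r_per_h,
            k_nt=self.k_nt_per_h,
            k_tdd=self.k_tdd_per_h,
            k_tl=k_tl,
            k_p=self.k_p_per_h,
        )


class FeedbackConfig(_Strict):
    a0_hz: float = FeedbackParams().a0
    drive: float = 1.0
    tau_e_h: float = FeedbackParams().tau_e
    n_hill: float = FeedbackParams().n_hill
    beta: float = FeedbackParams().beta
    k_w_per_h: float = FeedbackParams().k_w
    w_min: float = FeedbackParams().w_bounds[0]
    w_max: float = FeedbackParams().w_bounds[1]
    s_na: float = 1.0
    s_ca: float = 1.0
    u_erk: float = 1.0
    eta: float = 1.0

    def to_params(self, kinetics: RateConstants | None = None) -> FeedbackParams:
        return FeedbackParams(
            a0=self.a0_hz,
            drive=self.drive,
            tau_e=self.tau_e_h,
            n_hill=self.n_hill,
            beta=self.beta,
            k_w=self.k_w_per_h,
            w_bounds=(self.w_min, self.w_max),
            s_na=self.s_na,
            s_ca=self.s_ca,
            u_erk=self.u_erk,
            eta=self.eta,
            kinetics=kinetics or RateConstants(),
        )


class NoiseConfig(_Strict):
    cv: float = 0.10
    distribution: Literal["lognormal", "truncated_gaussian"] = "lognormal"
    n_replicates: int = 3

    def to_spec(self, seed: int) -> NoiseSpec:
        return NoiseSpec(
            cv=self.cv,
            distribution=self.distribution,
            n_replicates=self.n_replicates,
            seed=seed,
        )


class ScheduleSegment(_Strict):
    t_start_h: float
    condition: str


class RunConfig(_Strict):
    """Top-level run configuration; seeds are always explicit."""

    seed: int
    kinetics: KineticsConfig = Field(default_factory=KineticsConfig)
    feedback: FeedbackConfig = Field(default_factory=FeedbackConfig)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    condition: Optional[str] = None
    schedule: Optional[list[ScheduleSegment]] = None
    t_end_h: float = 6.0
    times_h: Optional[list[float]] = None
    protocol: Optional[str] = None
    dt_out_h: float = 0.05

    def to_schedule(self) -> PerturbationSchedule:
        if self.schedule:
            segments = tuple(
                (seg.t_start_h, _lookup_condition(seg.condition))
                for seg in self.schedule
            )
            return PerturbationSchedule(segments, self.t_end_h)
        name = self.condition or "basal"
        return PerturbationSchedule.constant(_lookup_condition(name), self.t_end_h)


def _lookup_condition(name: str) -> Condition:
    try:
        return CONDITIONS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown condition {name!r}; choose from {sorted(CONDITIONS)}"
        ) from None


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ValueError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        raise ValueError(f"invalid config {path}: {exc}") from exc


def read_measurement_table(path: str | Path) -> pd.DataFrame:
    from .estimate import validate_measurement_table

    table = pd.read_csv(path)
    if table.empty:
        raise ValueError(f"measurement table {path} is empty")
    return validate_measurement_table(table)


def write_measurement_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format="%.12g")


def save_recording(rec: ElectrodeRecording, prefix: str | Path) -> None:
    """Write <prefix>.json (header) and <prefix>.csv (channels x samples, mV)."""
    prefix = Path(prefix)
    header = {
        "fs_hz": rec.fs,
        "n_channels": rec.n_channels,
        "duration_s": rec.duration_s,
        "units": "mV",
    }
    prefix.with_suffix(".json").write_text(json.dumps(header, indent=2))
    np.savetxt(prefix.with_suffix(".csv"), rec.traces, delimiter=",", fmt="%.9g")


def load_recording(prefix: str | Path) -> ElectrodeRecording:
    prefix = Path(prefix)
    if prefix.suffix:  # accept either the prefix or one of the two files
        prefix = prefix.with_suffix("")
    header = json.loads(prefix.with_suffix(".json").read_text())
    traces = np.loadtxt(prefix.with_suffix(".csv"), delimiter=",", ndmin=2)
    rec = ElectrodeRecording(fs=float(header["fs_hz"]), traces=traces)
    if rec.n_channels != int(header["n_channels"]):
        raise ValueError("recording header/matrix channel-count mismatch")
    return rec
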