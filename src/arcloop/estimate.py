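"""Rate-constant estimation from pharmacological perturbation time courses.

Implements the full basal-kinetics pipeline for a translation-dependent-decay
(TDD) substrate:

* single-exponential fits to %-of-baseline chase curves (log-linear OLS or
  a nonlinear plateau model for curves that settle above zero),
* the steady-state production balance r = k_deg * M*,
* the TDD decomposition k_tdd = k_deg - k_deg,CHX,
* correction of the apparent protein decay rate for ongoing translation from
  residual decaying mRNA, k_p = sqrt(k_deg^2 - k_app^2),
* production estimated from the initial accumulation under translational
  blockade, r = slope0 + k_nt * M0,
* raw-measurement normalization for western densitometry and qPCR
  (delta-delta-Ct).

Measurement tables are long-format :class:`pandas.DataFrame` objects with
columns ``condition, analyte, time_h, replicate, value_pct``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .kinetics import ACTD, RateConstants, simulate

__all__ = [
    "FitResult",
    "fit_exponential",
    "half_life",
    "production_from_balance",
    "decompose_tdd",
    "correct_protein_rate",
    "production_from_accumulation",
    "estimate_basal_rates",
    "normalize_to_control",
    "qpcr_relative_quantity",
    "validate_measurement_table",
]

MEASUREMENT_COLUMNS = ("condition", "analyte", "time_h", "replicate", "value_pct")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a single-exponential fit.

    ``k`` is the decay (positive) or growth (negative) constant in 1/h;
    ``amplitude`` the fitted t=0 level in %; ``plateau`` the fitted
    asymptote (nonlinear method only); ``stderr_k`` the standard error of
    ``k``; ``window`` the (t_min, t_max) actually used.
    """

    k: float
    amplitude: float
    stderr_k: float
    n_points: int
    method: str
    window: tuple[float, float]
    plateau: float | None = None


def validate_measurement_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format measurement-table contract; returns the table."""
    missing = [c for c in MEASUREMENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    if (table["value_pct"] < 0).any():
        raise ValueError("value_pct must be non-negative")
    if (table["replicate"] < 1).any():
        raise ValueError("replicate IDs must be >= 1")
    return table


def fit_exponential(
    times: Sequence[float],
    values: Sequence[float],
    method: str = "log_linear",
    window: tuple[float, float] | None = None,
) -> FitResult:
    """Fit a single exponential to a %-of-baseline time course.

    ``log_linear``: ordinary least squares of ln(value) on time; k is the
    negated slope. ``nonlinear_plateau``: least squares of
    ``plateau + (100 - plateau) * exp(-k t)`` for curves approaching a
    nonzero steady state.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape:
        raise ValueError("times and values must have the same length")
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, v = t[mask], v[mask]
    win = (float(t.min()), float(t.max())) if t.size else (np.nan, np.nan)
    if t.size < 3:
        raise ValueError(f"need >= 3 points in window, got {t.size}")

    if method == "log_linear":
        if (v <= 0).any():
            raise ValueError("log_linear requires strictly positive values")
        if np.ptp(t) == 0:
            raise ValueError("singular design: all time points identical")
        res = stats.linregress(t, np.log(v))
        return FitResult(
            k=-res.slope,
            amplitude=float(np.exp(res.intercept)),
            stderr_k=float(res.stderr),
            n_points=int(t.size),
            method=method,
            window=win,
        )
    if method == "nonlinear_plateau":

        def model(tt, plateau, k):
            return plateau + (100.0 - plateau) * np.exp(-k * tt)

        p0 = (float(v.min()), 1.0)
        popt, pcov = optimize.curve_fit(model, t, v, p0=p0, maxfev=10000)
        plateau, k = popt
        stderr = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.nan
        return FitResult(
            k=float(k),
            amplitude=100.0 - float(plateau),
            stderr_k=stderr,
            n_points=int(t.size),
            method=method,
            window=win,
            plateau=float(plateau),
        )
    raise ValueError(f"unknown fit method: {method!r}")


def half_life(k: float) -> float:
    """ln(2)/k in hours; requires k > 0."""
    if k <= 0:
        raise ValueError(f"half-life undefined for k <= 0, got {k}")
    return math.log(2.0) / k


def production_from_balance(k_deg: float, m_star: float) -> float:
    """Zero-order production from steady-state balance: r = k_deg * M*."""
    if k_deg < 0 or m_star < 0:
        raise ValueError("k_deg and m_star must be >= 0")
    return k_deg * m_star


def decompose_tdd(k_deg: float, k_deg_chx: float) -> tuple[float, float]:
    """Split total mRNA decay into a translation-dependent part and its share.

    Returns (k_tdd, tdd_fraction) where k_tdd = k_deg - k_deg_chx and
    tdd_fraction = k_tdd / k_deg.
    """
    if k_deg_chx < 0:
        raise ValueError("decay constants must be >= 0")
    if k_deg_chx > k_deg:
        raise ValueError(
            "k_deg_chx exceeds k_deg: negative translation-dependent decay"
        )
    k_tdd = k_deg - k_deg_chx
    return k_tdd, (k_tdd / k_deg if k_deg > 0 else 0.0)


def correct_protein_rate(k_mrna_deg: float, k_app: float) -> float:
    """True protein degradation from the apparent rate under transcription block.

    The apparent protein decay under ActD under-estimates degradation because
    residual (decaying) mRNA keeps producing protein; the corrected constant
    is sqrt(k_mrna_deg^2 - k_app^2).
    """
    if k_app < 0:
        raise ValueError("k_app must be >= 0")
    if k_app >= k_mrna_deg:
        raise ValueError("correction undefined: k_app must be < k_mrna_deg")
    return math.sqrt(k_mrna_deg**2 - k_app**2)


def production_from_accumulation(
    initial_slope: float, k_nt: float, m0: float
) -> float:
    """Production rate from initial mRNA accumulation under translation block.

    With the TDD pathway silenced by the translation block, the balance at
    t = 0 is slope0 = r - k_nt * M0, hence r = slope0 + k_nt * M0.
    """
    if k_nt < 0 or m0 < 0:
        raise ValueError("k_nt and m0 must be >= 0")
    return initial_slope + k_nt * m0


def normalize_to_control(
    raw_target: Sequence[float] | float,
    raw_reference: Sequence[float] | float,
    control_ratios: Sequence[float] | float,
) -> np.ndarray:
    """Densitometry normalization: target/reference as % of the control mean.

    ``control_ratios`` are the target/reference ratios of the control group
    (phospho/total for phospho-proteins, protein/loading-control otherwise).
    """
    target = np.atleast_1d(np.asarray(raw_target, dtype=float))
    reference = np.atleast_1d(np.asarray(raw_reference, dtype=float))
    control = np.atleast_1d(np.asarray(control_ratios, dtype=float))
    if (reference <= 0).any():
        raise ValueError("reference values must be positive")
    if (control <= 0).any():
        raise ValueError("control ratios must be positive")
    return 100.0 * (target / reference) / control.mean()


def qpcr_relative_quantity(
    ct_target: float,
    ct_reference: float,
    ct_target_control: float,
    ct_reference_control: float,
    efficiency: float = 2.0,
) -> float:
    """Delta-delta-Ct relative quantity at a given amplification efficiency."""
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1 fold/cycle")
    ddct = (ct_target - ct_reference) - (ct_target_control - ct_reference_control)
    return float(efficiency**-ddct)


def _series_means(table: pd.DataFrame, condition: str, analyte: str) -> pd.Series:
    sub = table[(table["condition"] == condition) & (table["analyte"] == analyte)]
    return sub.groupby("time_h")["value_pct"].mean().sort_index()


def _fit_series(
    table: pd.DataFrame,
    condition: str,
    analyte: str,
    window: tuple[float, float] | None = None,
) -> FitResult:
    means = _series_means(table, condition, analyte)
    return fit_exponential(means.index.to_numpy(), means.to_numpy(), window=window)


def _deconvolve_protein_rate(
    times: np.ndarray, values_pct: np.ndarray, k_mrna_deg: float
) -> float:
    """Least-squares fit of the two-compartment ActD protein solution.

    P(t)/P0 = (k_p e^{-k_m t} - k_m e^{-k_p t}) / (k_p - k_m) with k_m fixed
    at the fitted mRNA decay constant; returns k_p.
    """

    def model(t, k_p):
        km = k_mrna_deg
        if abs(k_p - km) < 1e-9:
            return 100.0 * np.exp(-km * t) * (1.0 + km * t)
        return 100.0 * (k_p * np.exp(-km * t) - km * np.exp(-k_p * t)) / (k_p - km)

    popt, _ = optimize.curve_fit(
        model, times, values_pct, p0=(0.9 * k_mrna_deg,), maxfev=10000
    )
    return float(popt[0])


def estimate_basal_rates(
    table: pd.DataFrame,
    protein_window: tuple[float, float] = (0.0, 2.0),
    method: str = "sqrt",
) -> tuple[RateConstants, dict]:
    """Run the full basal-kinetics estimation pipeline on a measurement table.

    Requires series (actd, mrna), (actd_chx, mrna), (actd, protein) and
    (chx, mrna). Fits the total and translation-independent mRNA decay
    constants and the apparent protein decay over ``protein_window``, then
    decomposes TDD, corrects the protein rate (``method="sqrt"`` applies the
    quadrature formula; ``"deconvolve"`` fits the full two-compartment
    protein solution), and forms both production estimates.

    Returns the assembled :class:`RateConstants` (with k_tl = k_p, closing
    the model so the basal protein steady state is 1) and a report dict
    carrying every intermediate fit.
    """
    validate_measurement_table(table)
    required = [
        ("actd", "mrna"),
        ("actd_chx", "mrna"),
        ("actd", "protein"),
        ("chx", "mrna"),
    ]
    missing = [
        pair
        for pair in required
        if table[
            (table["condition"] == pair[0]) & (table["analyte"] == pair[1])
        ].empty
    ]
    if missing:
        raise ValueError(f"missing required series (condition, analyte): {missing}")

    actd_mrna = _series_means(table, "actd", "mrna")
    fit_kdeg = fit_exponential(
        actd_mrna.index.to_numpy(), actd_mrna.to_numpy(), window=(1e-12, np.inf)
    )
    fit_knt = _fit_series(table, "actd_chx", "mrna", window=(1e-12, np.inf))
    fit_kapp = _fit_series(table, "actd", "protein", window=protein_window)

    k_deg, k_nt_hat, k_app = fit_kdeg.k, fit_knt.k, fit_kapp.k
    k_tdd, tdd_fraction = decompose_tdd(k_deg, k_nt_hat)

    if method == "sqrt":
        k_p = correct_protein_rate(k_deg, k_app)
    elif method == "deconvolve":
        prot = _series_means(table, "actd", "protein")
        k_p = _deconvolve_protein_rate(
            prot.index.to_numpy(), prot.to_numpy(), k_deg
        )
    else:
        raise ValueError(f"unknown protein-rate method: {method!r}")

    # steady-state production balance; baseline abundance from the t=0 group
    t0 = actd_mrna.index[actd_mrna.index <= 1e-12]
    m_star = float(actd_mrna.loc[t0].mean()) / 100.0 if len(t0) else 1.0
    r_balance = production_from_balance(k_deg, m_star)

    # production from initial accumulation under translational blockade;
    # the two-point secant is corrected for exponential sampling bias with
    # the fitted k_nt (factor k*dt / (1 - exp(-k*dt)), exact at zero noise)
    chx = _series_means(table, "chx", "mrna") / 100.0
    t0_c, t1_c = chx.index[0], chx.index[1]
    secant = (chx.iloc[1] - chx.iloc[0]) / (t1_c - t0_c)
    dt = t1_c - t0_c
    bias = k_nt_hat * dt / -math.expm1(-k_nt_hat * dt) if k_nt_hat > 0 else 1.0
    slope0 = secant * bias
    r_accum = production_from_accumulation(slope0, k_nt_hat, float(chx.iloc[0]))

    params = RateConstants(r=r_balance, k_nt=k_nt_hat, k_tdd=k_tdd, k_tl=k_p, k_p=k_p)
    report = {
        "k_mrna_deg_per_h": k_deg,
        "k_mrna_deg_chx_per_h": k_nt_hat,
        "k_tdd_per_h": k_tdd,
        "tdd_fraction": tdd_fraction,
        "k_protein_app_per_h": k_app,
        "k_protein_deg_per_h": k_p,
        "protein_rate_method": method,
        "r_mrna_balance_per_h": r_balance,
        "r_mrna_accumulation_per_h": r_accum,
        "mrna_half_life_h": half_life(k_deg),
        "protein_half_life_h": half_life(k_p),
        "fits": {
            "actd_mrna": fit_kdeg,
            "actd_chx_mrna": fit_knt,
            "actd_protein": fit_kapp,
        },
    }
    return params, report
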