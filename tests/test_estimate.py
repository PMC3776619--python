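"""Rate-estimation unit, round-trip and calibration tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from arcloop.estimate import (
    correct_protein_rate,
    decompose_tdd,
    estimate_basal_rates,
    fit_exponential,
    half_life,
    normalize_to_control,
    production_from_accumulation,
    production_from_balance,
    qpcr_relative_quantity,
    validate_measurement_table,
)
from arcloop.kinetics import ACTD, ACTD_CHX, CHX, TTX, RateConstants, simulate
from arcloop.synth import NoiseSpec, synth_timecourse_table

DEFAULTS = RateConstants()
SAMPLES_H = [0.5, 1.0, 2.0, 4.0, 6.0]


def noiseless_table(conditions=(ACTD, CHX, ACTD_CHX), times=(0, 0.5, 1, 2, 4, 6)):
    tables = [
        synth_timecourse_table(DEFAULTS, c, times, NoiseSpec(cv=0.0, seed=0))
        for c in conditions
    ]
    return pd.concat(tables, ignore_index=True)


class TestFitExponential:
    def test_recovers_total_mrna_decay(self):
        traj = simulate(DEFAULTS, ACTD, SAMPLES_H)
        fit = fit_exponential(SAMPLES_H, traj.mrna)
        assert fit.k == pytest.approx(1.6, rel=1e-9)
        assert fit.amplitude == pytest.approx(100.0, rel=1e-9)
        assert fit.stderr_k == pytest.approx(0.0, abs=1e-9)

    def test_recovers_translation_independent_decay(self):
        traj = simulate(DEFAULTS, ACTD_CHX, SAMPLES_H)
        fit = fit_exponential(SAMPLES_H, traj.mrna)
        assert fit.k == pytest.approx(0.98, rel=1e-9)

    def test_constant_series_zero_rate(self):
        fit = fit_exponential([0, 1, 2], [100.0, 100.0, 100.0])
        assert fit.k == 0.0

    def test_window_selects_points(self):
        traj = simulate(DEFAULTS, ACTD, [0, 0.5, 1, 2, 4, 6])
        fit = fit_exponential([0, 0.5, 1, 2, 4, 6], traj.mrna, window=(0.5, 6))
        assert fit.n_points == 5
        assert fit.window == (0.5, 6.0)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential([0, 1, 2], [100.0, 0.0, 10.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential([0, 1], [100.0, 50.0])

    def test_singular_design_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential([1, 1, 1], [100.0, 90.0, 80.0])

    def test_plateau_model_recovers_ttx_curve(self):
        times = np.array([0, 0.5, 1, 2, 4, 6, 12.0])
        traj = simulate(DEFAULTS, TTX, times)
        fit = fit_exponential(times, traj.mrna, method="nonlinear_plateau")
        assert fit.method == "nonlinear_plateau"
        assert fit.plateau == pytest.approx(62.5, rel=1e-5)
        assert fit.k == pytest.approx(1.6, rel=1e-5)


class TestPointwiseOperations:
    @pytest.mark.parametrize(
        "k,expected", [(1.6, 0.4332), (RateConstants().k_p, 0.5002), (math.log(2), 1.0)]
    )
    def test_half_life(self, k, expected):
        assert half_life(k) == pytest.approx(expected, abs=1e-4)

    def test_half_life_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            half_life(0.0)

    @pytest.mark.parametrize(
        "k_deg,m_star,expected", [(1.6, 1.0, 1.6), (0.0, 1.0, 0.0), (0.98, 1.6 / 0.98, 1.6)]
    )
    def test_production_from_balance(self, k_deg, m_star, expected):
        assert production_from_balance(k_deg, m_star) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "k_deg,k_chx,expected",
        [
            (1.6, 0.98, (0.62, 0.3875)),
            (1.6, 1.6, (0.0, 0.0)),
            (2.0, 1.0, (1.0, 0.5)),
        ],
    )
    def test_decompose_tdd(self, k_deg, k_chx, expected):
        assert decompose_tdd(k_deg, k_chx) == pytest.approx(expected)

    def test_decompose_tdd_rejects_negative_tdd(self):
        with pytest.raises(ValueError):
            decompose_tdd(1.0, 1.5)

    @given(k_deg=st.floats(0.1, 5.0), k_chx_frac=st.floats(0.0, 1.0))
    def test_decompose_tdd_additivity(self, k_deg, k_chx_frac):
        k_chx = k_deg * k_chx_frac
        k_tdd, _ = decompose_tdd(k_deg, k_chx)
        assert k_tdd + k_chx == pytest.approx(k_deg, rel=1e-12)

    def test_correct_protein_rate(self):
        assert correct_protein_rate(1.6, 0.8) == pytest.approx(
            math.sqrt(1.6**2 - 0.8**2)
        )
        assert correct_protein_rate(1.6, 0.0) == pytest.approx(1.6)
        with pytest.raises(ValueError):
            correct_protein_rate(1.6, 1.7)

    @pytest.mark.parametrize(
        "slope,k_nt,m0,expected",
        [(0.9, 0.98, 1.0, 1.88), (0.0, 0.98, 1.0, 0.98), (0.62, 0.98, 1.0, 1.6)],
    )
    def test_production_from_accumulation(self, slope, k_nt, m0, expected):
        assert production_from_accumulation(slope, k_nt, m0) == pytest.approx(expected)


class TestApparentProteinRate:
    def test_round_trip_reproduces_apparent_0_8(self):
        """Protein decay under transcription block, fit over {0,1,2} h."""
        traj = simulate(DEFAULTS, ACTD, [0.0, 1.0, 2.0])
        fit = fit_exponential([0.0, 1.0, 2.0], traj.protein)
        assert fit.k == pytest.approx(0.795, abs=1e-3)
        assert correct_protein_rate(1.6, fit.k) == pytest.approx(DEFAULTS.k_p, rel=0.01)

    @pytest.mark.parametrize("k_m", [1.0, 1.6, 2.2, 3.0])
    def test_quadrature_correction_near_operating_regime(self, k_m):
        # the quadrature formula is a local approximation: accurate where
        # the apparent rate sits near k_m / 2 (the measured regime), with
        # the fit window scaled to the mRNA lifetime
        k_p = math.sqrt(3) / 2 * k_m
        params = RateConstants(r=k_m, k_nt=k_m, k_tdd=0.0, k_tl=k_p, k_p=k_p)
        window = [0.0, 1.6 / k_m, 3.2 / k_m]
        traj = simulate(params, ACTD, window)
        k_app = fit_exponential(window, traj.protein).k
        assert k_app < k_m
        assert correct_protein_rate(k_m, k_app) == pytest.approx(k_p, rel=0.05)

    @pytest.mark.parametrize("k_m", [1.0, 2.2])
    @pytest.mark.parametrize("k_p_frac", [0.3, 0.6, 0.9])
    def test_deconvolution_recovers_protein_rate_everywhere(self, k_m, k_p_frac):
        # the full two-compartment fit has no such regime restriction
        from arcloop.estimate import _deconvolve_protein_rate

        k_p = k_p_frac * k_m
        params = RateConstants(r=k_m, k_nt=k_m, k_tdd=0.0, k_tl=k_p, k_p=k_p)
        times = np.array([0.0, 0.5, 1.0, 2.0, 4.0])
        traj = simulate(params, ACTD, times)
        assert _deconvolve_protein_rate(times, traj.protein, k_m) == pytest.approx(
            k_p, rel=1e-6
        )


class TestEstimateBasalRates:
    def test_noiseless_round_trip_deconvolve(self):
        params, report = estimate_basal_rates(noiseless_table(), method="deconvolve")
        assert params.r == pytest.approx(DEFAULTS.r, rel=1e-3)
        assert params.k_nt == pytest.approx(DEFAULTS.k_nt, rel=1e-3)
        assert params.k_tdd == pytest.approx(DEFAULTS.k_tdd, rel=1e-3)
        assert params.k_p == pytest.approx(DEFAULTS.k_p, rel=1e-3)

    def test_noiseless_round_trip_sqrt_formula(self):
        # the default grid adds a 0.5 h sample inside the fit window, so the
        # apparent rate lands near (not exactly at) the 3-point 0.795 value
        params, report = estimate_basal_rates(noiseless_table(), method="sqrt")
        assert report["k_protein_app_per_h"] == pytest.approx(0.8, abs=0.025)
        assert params.k_p == pytest.approx(DEFAULTS.k_p, rel=0.01)

    def test_internal_agreement_of_production_estimates(self):
        _, report = estimate_basal_rates(noiseless_table())
        r_bal = report["r_mrna_balance_per_h"]
        r_acc = report["r_mrna_accumulation_per_h"]
        assert r_acc == pytest.approx(r_bal, rel=1e-3)

    def test_missing_series_named_in_error(self):
        table = noiseless_table(conditions=(ACTD, CHX))
        with pytest.raises(ValueError, match="actd_chx"):
            estimate_basal_rates(table)

    def test_monte_carlo_mean_near_truth(self):
        ks = []
        for seed in range(50):
            table = synth_timecourse_table(
                DEFAULTS, ACTD, SAMPLES_H, NoiseSpec(cv=0.10, n_replicates=3, seed=seed)
            )
            means = table[table["analyte"] == "mrna"].groupby("time_h")["value_pct"].mean()
            ks.append(fit_exponential(means.index, means.values).k)
        assert np.mean(ks) == pytest.approx(1.6, abs=0.1)


class TestNormalization:
    def test_blot_normalization_examples(self):
        assert normalize_to_control(2.0, 1.0, [2.0])[0] == pytest.approx(100.0)
        assert normalize_to_control(4.0, 1.0, [2.0])[0] == pytest.approx(200.0)

    def test_blot_normalization_recovers_planted_fold_change(self, rng):
        control_true, fold = 2.0, 1.73
        reference = rng.lognormal(0, 0.05, 12)
        noise = rng.lognormal(0, 0.05, 12)
        target = np.r_[np.full(6, control_true), np.full(6, control_true * fold)]
        raw_t, raw_r = target * reference * noise, reference
        control_ratios = raw_t[:6] / raw_r[:6]
        out = normalize_to_control(raw_t, raw_r, control_ratios)
        assert out[6:].mean() / out[:6].mean() == pytest.approx(fold, rel=0.05)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_control(1.0, 0.0, [1.0])

    def test_qpcr_identity_and_doubling(self):
        assert qpcr_relative_quantity(20, 20, 20, 20) == pytest.approx(1.0)
        assert qpcr_relative_quantity(19, 20, 20, 20) == pytest.approx(2.0)

    def test_qpcr_requires_efficiency_above_one(self):
        with pytest.raises(ValueError):
            qpcr_relative_quantity(20, 20, 20, 20, efficiency=1.0)

    def test_table_contract(self):
        bad = pd.DataFrame({"condition": ["a"], "analyte": ["mrna"]})
        with pytest.raises(ValueError, match="missing columns"):
            validate_measurement_table(bad)
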