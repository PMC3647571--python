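"""System GMM estimator: differencing, instruments, recovery, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from ndrpath import (
    CohortParams,
    ModelSpec,
    ar_test,
    build_instruments,
    default_model_spec,
    estimate,
    first_difference,
    generate_cohort,
    hansen_test,
    pooled_ols,
)
from ndrpath.errors import DiagnosticUnavailableError, EstimationError
from conftest import noise_free_params


class TestFirstDifference:
    def test_consecutive_series(self, toy_panel):
        out = first_difference(toy_panel, "hba1c")
        p1 = out.frame[out.frame["patient_id"] == 1]
        assert list(p1["duration"]) == [2, 3]
        assert list(p1["d_hba1c"]) == [-0.5, 0.0]

    def test_gap_breaks_differencing(self, toy_panel):
        out = first_difference(toy_panel, "hba1c")
        assert (out.frame["patient_id"] == 2).sum() == 0

    def test_single_observation_patient_drops_out(self, toy_panel):
        out = first_difference(toy_panel, "hba1c")
        assert (out.frame["patient_id"] == 3).sum() == 0


def _balanced_toy_panel(tmax, n=30, seed=5):
    """Balanced panel with irregular values so no instrument column is zero."""
    rng = np.random.default_rng(seed)
    rows = []
    for pid in range(1, n + 1):
        y = rng.normal(7, 1)
        w = rng.normal(30, 3)
        for t in range(tmax + 1):
            y = 0.5 * y + rng.normal(3.5, 0.5)
            w = 0.7 * w + rng.normal(9, 1)
            rows.append({
                "patient_id": pid, "duration": t, "hba1c": y, "bmi": w,
                "smoking": float(rng.random() < 0.3),
                "age_at_diagnosis": 50 + pid % 7, "female": pid % 2,
                "sbp": 140.0, "tchdl": 4.0, "ldl": 3.0,
                "year_of_diagnosis": 2001, "calendar_year": 2001 + t,
                "treatment_class": "diet",
            })
    return pd.DataFrame(rows)


class TestInstruments:
    def test_uncollapsed_count_matches_enumeration_oracle(self):
        """Brute-force enumeration of admissible (t, lag) pairs."""
        tmax = 3
        panel = _balanced_toy_panel(tmax)
        spec = ModelSpec("hba1c", predetermined=("bmi",), constant=True)
        # oracle: differenced equation at t needs lagged levels; the levels
        # equation needs lagged differences plus the constant
        count = 0
        for t in range(2, tmax + 1):                   # differenced rows
            count += len(range(2, t + 1))              # y lags >= 2
            count += len(range(1, t + 1))              # predetermined lags >= 1
        for t in range(1, tmax + 1):                   # levels rows
            if t - 2 >= 0:
                count += 1                             # delta y_{t-1}
            count += 1                                 # delta bmi_t
        count += 1                                     # constant
        assert build_instruments(panel, spec).count == count

    def test_collapsing_strictly_reduces_columns(self):
        panel = _balanced_toy_panel(tmax=4)
        spec = ModelSpec("hba1c", predetermined=("bmi",), constant=True)
        full = build_instruments(panel, spec).count
        collapsed = build_instruments(panel, ModelSpec(
            "hba1c", predetermined=("bmi",), constant=True, collapse=True)).count
        assert collapsed < full

    def test_endogenous_regressor_instruments_start_at_lag_two(self):
        panel = _balanced_toy_panel(tmax=4)
        spec = ModelSpec("hba1c", endogenous=("smoking",), constant=True)
        labels = build_instruments(panel, spec).labels
        smoking_diff = [l for l in labels if l.startswith("D.smoking")]
        assert smoking_diff, "expected lagged-level instruments for smoking"
        assert all(",L1" not in l for l in smoking_diff)
        # predetermined variables do get lag-1 instruments
        labels_pre = build_instruments(
            panel, ModelSpec("hba1c", predetermined=("smoking",), constant=True)
        ).labels
        assert any(",L1" in l for l in labels_pre if l.startswith("D.smoking"))

    def test_max_lag_caps_depth(self):
        panel = _balanced_toy_panel(tmax=5)
        spec = ModelSpec("hba1c", constant=True, max_lag=2)
        labels = build_instruments(panel, spec).labels
        assert all("L3" not in l and "L4" not in l for l in labels)


class TestEstimate:
    def test_alpha_recovery_on_synthetic_cohort(self, small_cohort, coeffs):
        for rf in ("bmi", "hba1c"):
            fit = estimate(small_cohort, default_model_spec(rf, collapse=True))
            assert fit.alpha == pytest.approx(coeffs[rf].lag.value, abs=0.08)

    def test_invariance_to_patient_ordering_and_relabeling(self, small_cohort):
        spec = default_model_spec("tchdl", collapse=True)
        base = estimate(small_cohort, spec)
        df = small_cohort.frame.sample(frac=1.0, random_state=3).copy()
        df["patient_id"] = df["patient_id"] * 7 + 3
        scrambled = estimate(df, spec)
        assert np.allclose(base.params.values, scrambled.params.values, atol=1e-8)
        assert base.hansen_stat == pytest.approx(scrambled.hansen_stat, abs=1e-6)

    def test_no_heterogeneity_limit_agrees_with_pooled_ols(self, coeffs):
        params = noise_free_params(
            n=600, diagnosis_years=(2001, 2001),
            sigma_nu={rf: sd for rf, sd in
                      {"hba1c": 0.8, "sbp": 1.1, "tchdl": 0.8, "ldl": 0.65, "bmi": 2.0}.items()},
        )
        panel = generate_cohort(params, seed=21)
        spec = default_model_spec("hba1c", collapse=True)
        fit = estimate(panel, spec)
        ols = pooled_ols(panel, spec)
        true_alpha = coeffs["hba1c"].lag.value
        assert fit.alpha == pytest.approx(true_alpha, abs=0.06)
        assert ols.iloc[0] == pytest.approx(true_alpha, abs=0.06)
        assert abs(fit.alpha - ols.iloc[0]) < 0.06

    def test_pooled_ols_overstates_alpha_with_random_effects(self, small_cohort, coeffs):
        spec = default_model_spec("hba1c", collapse=True)
        fit = estimate(small_cohort, spec)
        ols_alpha = pooled_ols(small_cohort, spec).iloc[0]
        true_alpha = coeffs["hba1c"].lag.value
        assert ols_alpha - true_alpha > 0.10
        assert abs(fit.alpha - true_alpha) < ols_alpha - true_alpha

    def test_panel_too_short_raises(self, small_cohort):
        df = small_cohort.frame[small_cohort.frame["duration"] <= 1]
        with pytest.raises(EstimationError, match="waves"):
            estimate(df, default_model_spec("bmi", collapse=True))

    def test_under_identification_raises(self, small_cohort):
        df = small_cohort.frame.copy()
        df["extra"] = 0.0  # a regressor contributing no usable instrument
        spec = ModelSpec("hba1c", exogenous=("age_at_diagnosis", "female", "extra"),
                         constant=True, collapse=True, max_lag=1)
        with pytest.raises(EstimationError, match="under-identified"):
            estimate(df, spec)

    def test_unbalanced_panel_with_gaps_still_estimates(self, coeffs):
        params = CohortParams(n=600, diagnosis_years=(2001, 2004),
                              annual_dropout=0.08, visit_missingness=0.15,
                              baseline_missingness=0.0)
        panel = generate_cohort(params, seed=31)
        fit = estimate(panel, default_model_spec("bmi", collapse=True))
        assert fit.alpha == pytest.approx(coeffs["bmi"].lag.value, abs=0.10)
        assert fit.n_patients < 600 or fit.person_years < len(panel.frame)


class TestDiagnostics:
    def test_hansen_undefined_when_just_identified(self, small_cohort):
        spec = ModelSpec("hba1c", exogenous=("age_at_diagnosis", "female"),
                         constant=True, collapse=True, max_lag=1)
        fit = estimate(small_cohort, spec)
        assert fit.hansen_df == 0
        with pytest.raises(DiagnosticUnavailableError):
            hansen_test(fit)

    def test_ar_unavailable_for_degenerate_residuals(self, noise_free_panel):
        spec = default_model_spec("bmi", collapse=True, two_step=False)
        fit = estimate(noise_free_panel, spec)
        with pytest.raises(DiagnosticUnavailableError, match="zero variance"):
            ar_test(fit, 1)

    def test_ar2_needs_enough_periods(self, small_cohort):
        df = small_cohort.frame[small_cohort.frame["duration"] <= 3]
        fit = estimate(df, default_model_spec("bmi", collapse=True))
        with pytest.raises(DiagnosticUnavailableError):
            ar_test(fit, 2)

    def test_iid_shocks_reject_ar1_not_ar2(self, small_cohort):
        fit = estimate(small_cohort, default_model_spec("tchdl", collapse=True))
        z1, p1 = ar_test(fit, 1)
        assert z1 < -5 and p1 < 1e-6   # differencing induces MA(1) by construction
        _, p2 = ar_test(fit, 2)
        assert p2 > 0.01

    def test_serially_correlated_shocks_trip_ar2_and_hansen(self):
        """AR(1) shocks invalidate the lag-2 moment conditions."""
        spec = default_model_spec("tchdl", collapse=True)
        h_ok, h_bad, ar2_bad = [], [], []
        for r in range(15):
            kwargs = dict(n=400, diagnosis_years=(2001, 2001), annual_dropout=0.0,
                          visit_missingness=0.0, baseline_missingness=0.0)
            ok = generate_cohort(CohortParams(**kwargs), seed=900 + r)
            bad = generate_cohort(CohortParams(**kwargs, nu_ar1=0.5), seed=900 + r)
            h_ok.append(estimate(ok, spec).hansen_p)
            fit_bad = estimate(bad, spec)
            h_bad.append(fit_bad.hansen_p)
            ar2_bad.append(ar_test(fit_bad, 2)[1])
        assert np.median(h_bad) < 0.05 < np.median(h_ok)
        assert np.mean(np.array(ar2_bad) < 0.05) >= 0.5


def test_fit_summary_mentions_key_quantities(small_cohort):
    fit = estimate(small_cohort, default_model_spec("bmi", collapse=True))
    text = fit.summary()
    assert "Hansen" in text and "AR(2)" in text and "lag_bmi" in text
    assert str(fit.n_patients) in text
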