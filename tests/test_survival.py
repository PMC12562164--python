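"""Patient variables, Cox fitting, stepwise selection and KM/log-rank."""

import numpy as np
import pandas as pd
import pytest

from psdelta.errors import ValidationError
from psdelta.io_formats import ClinicalRecord
from psdelta.survival import (
    SurvivalConfig,
    fit_cox,
    median_split_km,
    patient_variables,
    stepwise_select,
    vars_frame,
)
from psdelta.synthetic_data import generate_cohort

from conftest import make_effect


def _clinical(sample_id, time=100.0, event=1, **kw):
    defaults = dict(age=60.0, sex=1, tmb=10.0, stage=2, cancer_type="UCEC")
    defaults.update(kw)
    return ClinicalRecord(sample_id=sample_id, time=time, event=event, **defaults)


class TestPatientVariables:
    def test_worked_example(self):
        # deltas [0.1, -0.2, 0.01]: two pass the 0.05 cutoff (sum -0.1);
        # two of three are strictly positive
        effects = [make_effect(d, sample="S1", position=i + 1) for i, d in enumerate([0.1, -0.2, 0.01])]
        (v,) = patient_variables(effects, [_clinical("S1")])
        assert v.mut_num == 2
        assert v.score_all == pytest.approx(-0.1)
        assert v.percent_mut == pytest.approx(2 / 3)
        assert v.n_scored == 3

    def test_all_zero_deltas(self):
        effects = [make_effect(0.0, sample="S1", position=i + 1) for i in range(3)]
        (v,) = patient_variables(effects, [_clinical("S1")])
        assert (v.mut_num, v.score_all, v.percent_mut) == (0, 0.0, 0.0)

    def test_sample_without_effects_excluded_and_logged(self, caplog):
        effects = [make_effect(0.1, sample="S1")]
        with caplog.at_level("INFO"):
            vars_ = patient_variables(effects, [_clinical("S1"), _clinical("S2")])
        assert [v.sample_id for v in vars_] == ["S1"]
        assert "excluded 1" in caplog.text

    def test_duplicate_clinical_rows_error(self):
        effects = [make_effect(0.1, sample="S1")]
        with pytest.raises(ValidationError, match="duplicate clinical"):
            patient_variables(effects, [_clinical("S1"), _clinical("S1")])

    def test_partition_of_effects_across_patients(self):
        effects = [
            make_effect(0.01 * i, sample=f"S{i % 7}", position=i + 1) for i in range(100)
        ]
        clinical = [_clinical(f"S{i}") for i in range(7)]
        vars_ = patient_variables(effects, clinical)
        assert sum(v.n_scored for v in vars_) == len(effects)


def _sim_frame(seed, n=300, beta=0.0, censor_rate=0.3):
    clinical, truth = generate_cohort(
        n, beta=beta, censor_rate=censor_rate, seed=seed
    )
    df = pd.DataFrame(
        {
            "time": [c.time for c in clinical],
            "event": [c.event for c in clinical],
            "age": [c.age for c in clinical],
            "sex": [c.sex for c in clinical],
            "tmb": [c.tmb for c in clinical],
            "stage": [c.stage for c in clinical],
            "percent_mut": [truth.percent_mut_true[c.sample_id] for c in clinical],
        }
    )
    return df


class TestFitCox:
    def test_recovers_planted_coefficient_roughly(self):
        df = _sim_frame(seed=42, n=800, beta=1.0)
        fit = fit_cox(df, ps_variable="percent_mut")
        assert fit.coefficients["percent_mut"] == pytest.approx(1.0, abs=0.45)
        assert fit.n_events <= fit.n_subjects == len(df)

    def test_zero_variance_covariate_named(self):
        df = _sim_frame(seed=1)
        df["sex"] = 1
        with pytest.raises(ValidationError, match="sex"):
            fit_cox(df, ps_variable="percent_mut")

    def test_too_few_events(self):
        df = _sim_frame(seed=1).head(40)
        df["event"] = 0
        with pytest.raises(ValidationError, match="events"):
            fit_cox(df, ps_variable="percent_mut")

    def test_missing_stage_rows_dropped_listwise(self, caplog):
        clinical, truth = generate_cohort(
            200, beta=0.0, censor_rate=0.2, seed=3, stage_missing_rate=0.2
        )
        df = _sim_frame(seed=3)  # same covariate layout
        df = pd.DataFrame(
            {
                "time": [c.time for c in clinical],
                "event": [c.event for c in clinical],
                "age": [c.age for c in clinical],
                "sex": [c.sex for c in clinical],
                "tmb": [c.tmb for c in clinical],
                "stage": [np.nan if c.stage is None else c.stage for c in clinical],
                "percent_mut": [truth.percent_mut_true[c.sample_id] for c in clinical],
            }
        )
        n_missing = int(df["stage"].isna().sum())
        assert n_missing > 0
        with caplog.at_level("INFO"):
            fit = fit_cox(df, ps_variable="percent_mut")
        assert fit.n_subjects == len(df) - n_missing
        assert "listwise" in caplog.text

    def test_significance_predicate(self):
        df = _sim_frame(seed=7, n=600, beta=2.0)
        fit = fit_cox(df, ps_variable="percent_mut")
        assert fit.significant("percent_mut")


class TestStepwiseSelect:
    def test_noise_covariate_eliminated(self):
        # a pure-noise covariate survives only when spuriously significant
        # (5% by Wald calibration); the elimination rate sits near 95%
        rng = np.random.default_rng(0)
        eliminated = 0
        n_reps = 100
        for rep in range(n_reps):
            df = _sim_frame(seed=100 + rep, n=500, beta=1.0)
            df["noise"] = rng.normal(size=len(df))
            retained, fit = stepwise_select(df, ["percent_mut", "noise"])
            if "noise" not in retained:
                eliminated += 1
        assert eliminated / n_reps >= 0.90

    def test_all_significant_all_retained(self):
        df = _sim_frame(seed=5, n=800, beta=2.0)
        df["age2"] = df["age"]  # keep candidates independent & informative
        retained, fit = stepwise_select(df, ["percent_mut", "age"])
        # age has a planted effect in the generator; both should survive
        assert "percent_mut" in retained

    def test_single_candidate_behaves_as_plain_fit(self):
        df = _sim_frame(seed=6, n=300, beta=1.0)
        retained, fit = stepwise_select(df, ["percent_mut"])
        plain = fit_cox(df, covariates=["percent_mut"], ps_variable=None)
        assert retained == ["percent_mut"]
        assert fit.coefficients["percent_mut"] == plain.coefficients["percent_mut"]


class TestMedianSplitKM:
    def test_identical_groups_logrank_p_one(self):
        # two groups with byte-identical outcomes: no separation
        times = [10, 20, 30, 40, 50] * 2
        events = [1, 1, 0, 1, 0] * 2
        df = pd.DataFrame(
            {
                "time": times,
                "event": events,
                "x": [0.0] * 5 + [1.0] * 5,
            }
        )
        res = median_split_km(df, "x")
        assert res.p_value == pytest.approx(1.0, abs=1e-9)
        pd.testing.assert_frame_equal(res.curves["high"], res.curves["low"])

    def test_km_without_censoring_equals_empirical_survival(self):
        times = [1.0, 2.0, 3.0, 4.0]
        df = pd.DataFrame(
            {
                "time": times * 2,
                "event": [1] * 8,
                "x": [0.0] * 4 + [1.0] * 4,
            }
        )
        res = median_split_km(df, "x")
        curve = res.curves["high"].set_index("time")["survival"]
        # S(t) = fraction of subjects with time > t
        for t, expected in [(1.0, 0.75), (2.0, 0.5), (3.0, 0.25), (4.0, 0.0)]:
            assert curve.loc[t] == pytest.approx(expected)

    def test_km_plateau_beyond_last_event(self):
        df = pd.DataFrame(
            {"time": [1, 2, 3, 9, 1, 2, 3, 9], "event": [1, 1, 0, 0] * 2, "x": [0.0] * 4 + [1.0] * 4}
        )
        res = median_split_km(df, "x")
        curve = res.curves["high"]
        assert curve["survival"].iloc[-1] == curve.loc[curve["time"] >= 2, "survival"].iloc[0]

    def test_degenerate_split_errors(self):
        df = pd.DataFrame({"time": [1, 2, 3], "event": [1, 1, 1], "x": [1.0, 1.0, 1.0]})
        with pytest.raises(ValidationError, match="degenerate"):
            median_split_km(df, "x")

    def test_median_valued_subjects_go_low(self):
        df = pd.DataFrame(
            {
                "time": range(1, 7),
                "event": [1] * 6,
                "x": [1.0, 1.0, 2.0, 2.0, 3.0, 3.0],
            }
        )
        res = median_split_km(df, "x")
        assert (res.labels == "high").sum() == 2  # only the two x=3 subjects
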