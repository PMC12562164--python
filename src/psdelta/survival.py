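"""Per-patient phase-separation variables and their prognostic association.

Three per-patient variables summarise a patient's delta-PS profile:

``mut_num``
    number of PS-affecting mutations (|delta| > affect cutoff, 0.05);
``score_all``
    sum of delta over those affecting mutations;
``percent_mut``
    fraction of the patient's scored mutations with delta strictly > 0
    (configurable cutoff, default 0).

Association with overall survival is tested by multivariable Cox
proportional-hazards regression (Efron tie handling, via lifelines) with
age, sex, tumour mutation burden (TMB) and ordinal tumour stage as
background covariates, by backward stepwise selection on Wald p-values,
and by median-split Kaplan–Meier curves with a two-group log-rank test
(median-valued subjects go to the low group).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

from .errors import NumericalError, ValidationError
from .io_formats import ClinicalRecord
from .mutation_effect import DEFAULT_AFFECT_CUTOFF, MutationEffect

logger = logging.getLogger(__name__)

#: Background clinical covariates used in the multivariable models.
DEFAULT_COVARIATES = ("age", "sex", "tmb", "stage")


@dataclass(frozen=True)
class SurvivalConfig:
    affect_cutoff: float = DEFAULT_AFFECT_CUTOFF
    #: Strict lower cutoff on delta for a mutation to count as "positive"
    #: in percent_mut (default 0; sensitivity analyses may move it).
    percent_mut_cutoff: float = 0.0
    #: Wald-p threshold for covariate retention in stepwise selection.
    p_threshold: float = 0.05


@dataclass(frozen=True)
class PatientSurvivalVars:
    sample_id: str
    cancer_type: str
    mut_num: int
    score_all: float
    percent_mut: float
    n_scored: int
    clinical: ClinicalRecord


@dataclass(frozen=True)
class CoxFit:
    """A fitted proportional-hazards model (coefficients are log hazard ratios)."""

    variables: tuple[str, ...]
    coefficients: Mapping[str, float]
    standard_errors: Mapping[str, float]
    p_values: Mapping[str, float]
    n_subjects: int
    n_events: int

    def significant(self, variable: str, threshold: float = 0.05) -> bool:
        """The selection predicate: retained iff Wald p < threshold."""
        return self.p_values[variable] < threshold


@dataclass(frozen=True)
class KMResult:
    labels: pd.Series  # sample_id -> "high"/"low"
    curves: Mapping[str, pd.DataFrame]  # group -> (time, survival) coordinates
    statistic: float
    p_value: float
    median_cutoff: float


# ---------------------------------------------------------------------------
# Patient variables
# ---------------------------------------------------------------------------

def patient_variables(
    effects: Sequence[MutationEffect],
    clinical: Sequence[ClinicalRecord],
    config: SurvivalConfig | None = None,
) -> list[PatientSurvivalVars]:
    """One record per clinical sample carrying >= 1 scored mutation.

    Samples present in the clinical table but absent from the effects are
    excluded and logged; duplicate clinical rows for one sample are an
    error (ambiguous join).
    """
    config = config or SurvivalConfig()
    by_sample: dict[str, list[MutationEffect]] = {}
    for e in effects:
        by_sample.setdefault(e.mutation.sample_id, []).append(e)

    seen: set[str] = set()
    out: list[PatientSurvivalVars] = []
    n_excluded = 0
    for rec in clinical:
        if rec.sample_id in seen:
            raise ValidationError(
                f"duplicate clinical row for sample {rec.sample_id!r}"
            )
        seen.add(rec.sample_id)
        es = by_sample.get(rec.sample_id)
        if not es:
            n_excluded += 1
            continue
        deltas = [e.delta for e in es]
        affecting = [d for d in deltas if abs(d) > config.affect_cutoff]
        out.append(
            PatientSurvivalVars(
                sample_id=rec.sample_id,
                cancer_type=rec.cancer_type or (es[0].mutation.cancer_type),
                mut_num=len(affecting),
                score_all=float(sum(affecting)),
                percent_mut=sum(d > config.percent_mut_cutoff for d in deltas) / len(deltas),
                n_scored=len(deltas),
                clinical=rec,
            )
        )
    if n_excluded:
        logger.info(
            "patient_variables: excluded %d clinical sample(s) with no scored mutation",
            n_excluded,
        )
    return out


def vars_frame(vars: Sequence[PatientSurvivalVars]) -> pd.DataFrame:
    """Patient variables + clinical covariates as a modelling DataFrame."""
    return pd.DataFrame(
        [
            {
                "sample_id": v.sample_id,
                "cancer_type": v.cancer_type,
                "mut_num": v.mut_num,
                "score_all": v.score_all,
                "percent_mut": v.percent_mut,
                "n_scored": v.n_scored,
                "time": v.clinical.time,
                "event": v.clinical.event,
                "age": v.clinical.age,
                "sex": v.clinical.sex,
                "tmb": v.clinical.tmb,
                "stage": np.nan if v.clinical.stage is None else v.clinical.stage,
            }
            for v in vars
        ]
    )


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------

def _as_frame(vars) -> pd.DataFrame:
    if isinstance(vars, pd.DataFrame):
        return vars.copy()
    return vars_frame(vars)


def fit_cox(
    vars,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    ps_variable: str | None = "percent_mut",
    *,
    duration_col: str = "time",
    event_col: str = "event",
) -> CoxFit:
    """Multivariable Cox proportional-hazards fit (Efron ties).

    ``vars`` is a list of :class:`PatientSurvivalVars` or an equivalent
    DataFrame. Rows with missing covariate values (e.g. unstaged tumours)
    are dropped listwise and logged. Zero-variance covariates and
    non-convergence raise.
    """
    df = _as_frame(vars)
    model_vars = list(covariates) + ([ps_variable] if ps_variable else [])
    missing = [v for v in model_vars if v not in df.columns]
    if missing:
        raise ValidationError(f"missing model column(s): {missing}")

    sub = df[[duration_col, event_col, *model_vars]]
    n_before = len(sub)
    sub = sub.dropna()
    if len(sub) < n_before:
        logger.info(
            "fit_cox: dropped %d row(s) with missing covariates (listwise)",
            n_before - len(sub),
        )
    if int(sub[event_col].sum()) < 2:
        raise ValidationError("need >= 2 observed events to fit a Cox model")
    for v in model_vars:
        if sub[v].nunique() <= 1:
            raise ValidationError(f"zero-variance covariate: {v!r}")

    cph = CoxPHFitter()
    try:
        cph.fit(sub, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as exc:
        raise NumericalError(f"Cox model failed to converge: {exc}") from exc
    summary = cph.summary
    return CoxFit(
        variables=tuple(model_vars),
        coefficients={v: float(summary.loc[v, "coef"]) for v in model_vars},
        standard_errors={v: float(summary.loc[v, "se(coef)"]) for v in model_vars},
        p_values={v: float(summary.loc[v, "p"]) for v in model_vars},
        n_subjects=len(sub),
        n_events=int(sub[event_col].sum()),
    )


def stepwise_select(
    vars,
    candidates: Sequence[str],
    *,
    duration_col: str = "time",
    event_col: str = "event",
    p_threshold: float = 0.05,
) -> tuple[list[str], CoxFit]:
    """Backward elimination: refit dropping the worst Wald p until every
    retained candidate has p < threshold. Deterministic given input order;
    at least one candidate is always retained (the final fit is reported
    even if its p is above threshold)."""
    if len(candidates) < 1:
        raise ValidationError("need >= 1 candidate covariate")
    retained = list(candidates)
    while True:
        fit = fit_cox(
            vars, covariates=retained, ps_variable=None,
            duration_col=duration_col, event_col=event_col,
        )
        worst = max(retained, key=lambda v: fit.p_values[v])
        if fit.p_values[worst] < p_threshold or len(retained) == 1:
            return retained, fit
        retained.remove(worst)


# ---------------------------------------------------------------------------
# Kaplan–Meier / log-rank
# ---------------------------------------------------------------------------

def median_split_km(
    vars,
    variable_name: str,
    *,
    duration_col: str = "time",
    event_col: str = "event",
) -> KMResult:
    """Median split (high: value > median; low: value <= median) with
    Kaplan–Meier curves per group and a two-group log-rank test."""
    df = _as_frame(vars)
    if variable_name not in df.columns:
        raise ValidationError(f"unknown variable {variable_name!r}")
    values = df[variable_name]
    median = float(values.median())
    high = values > median
    if high.sum() < 2 or (~high).sum() < 2:
        raise ValidationError(
            f"degenerate median split on {variable_name!r}: "
            f"{int(high.sum())} high vs {int((~high).sum())} low subjects"
        )
    labels = pd.Series(np.where(high, "high", "low"), index=df.get("sample_id", df.index))

    curves: dict[str, pd.DataFrame] = {}
    for name, mask in (("high", high), ("low", ~high)):
        kmf = KaplanMeierFitter()
        kmf.fit(df.loc[mask, duration_col], df.loc[mask, event_col])
        sf = kmf.survival_function_
        curves[name] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
        )

    lr = logrank_test(
        df.loc[high, duration_col], df.loc[~high, duration_col],
        event_observed_A=df.loc[high, event_col],
        event_observed_B=df.loc[~high, event_col],
    )
    return KMResult(
        labels=labels,
        curves=curves,
        statistic=float(lr.test_statistic),
        p_value=float(lr.p_value),
        median_cutoff=median,
    )
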