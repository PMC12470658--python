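"""Cohort-level longitudinal analysis of outer-retinal metrics.

The central object is :class:`ProgressionAnalysis`, a statsmodels-style
model built from a cohort of per-eye records; ``fit()`` applies the
progression rule (>= 4 percentage-point increase in partial EZ
attenuation by default) and returns a :class:`ProgressionResults` carrying

* the paired longitudinal summary of every metric (mean +- SD at OCT1,
  OCT2, of the differences, and the paired-t p-value),
* flagged-vs-unflagged group comparisons of clinical covariates (Welch t
  for continuous covariates; chi-square or Fisher's exact for categorical
  ones) and of the metric deltas,
* screening-concordance accounting against clinician and masked-expert
  toxicity labels,
* inter-label agreement (Cohen's kappa), and a ``summary()`` text report.

The same computations are exposed as module-level functions for use
without the model object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dataclass_fields

import numpy as np
import pandas as pd

from .cohort import (
    CATEGORICAL_COVARIATES,
    CONTINUOUS_COVARIATES,
    CohortRecord,
    PROGRESSION_METRIC,
    PROGRESSION_THRESHOLD_PP,
    classify_progressor,
)
from .exceptions import ValidationError
from .mapping import OuterRetinalMetrics
from .stats import TestResult, categorical_test, cohen_kappa, paired_ttest, welch_ttest


def _metric_matrix(records: list[CohortRecord], which: str) -> pd.DataFrame:
    rows = [getattr(r, which).as_dict() for r in records]
    return pd.DataFrame(rows, index=[r.eye_id for r in records])


def cohort_paired_summary(records: list[CohortRecord]) -> pd.DataFrame:
    """Longitudinal per-metric summary across the cohort.

    One row per outer-retinal metric: mean and SD at OCT1 and OCT2, mean
    and SD of the per-eye differences (OCT2 - OCT1; attenuation deltas are
    absolute percentage-point changes), and the two-sided paired-t p-value.
    """
    if len(records) < 2:
        raise ValidationError("paired summary requires at least 2 eyes")
    m1 = _metric_matrix(records, "metrics_oct1")
    m2 = _metric_matrix(records, "metrics_oct2")
    rows = []
    for name in OuterRetinalMetrics.field_names():
        a, b = m1[name].to_numpy(), m2[name].to_numpy()
        d = b - a
        res = paired_ttest(a, b)
        rows.append({
            "metric": name,
            "oct1_mean": a.mean(), "oct1_sd": a.std(ddof=1),
            "oct2_mean": b.mean(), "oct2_sd": b.std(ddof=1),
            "diff_mean": d.mean(), "diff_sd": d.std(ddof=1),
            "p_value": res.p_value,
        })
    return pd.DataFrame(rows).set_index("metric")


def compute_flags(
    records: list[CohortRecord],
    threshold_pp: float = PROGRESSION_THRESHOLD_PP,
    metric: str = PROGRESSION_METRIC,
    inclusive: bool = True,
) -> np.ndarray:
    """Boolean progression flag per record, in cohort order."""
    return np.array([
        classify_progressor(r.delta(), threshold_pp, metric, inclusive)
        for r in records
    ])


def progressor_group_comparison(
    records: list[CohortRecord],
    flags: np.ndarray,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flagged-vs-unflagged comparisons of covariates and metric deltas.

    Returns ``(covariates, deltas)`` DataFrames.  Continuous covariates and
    metric deltas get group means +- SD with a two-sided Welch t-test;
    categorical covariates get group counts with a chi-square test, or
    Fisher's exact test when any expected cell count is below 5.
    """
    flags = np.asarray(flags, dtype=bool)
    if len(flags) != len(records):
        raise ValidationError("flags length does not match cohort size")
    cov_rows = []
    for name in CONTINUOUS_COVARIATES:
        v = np.array([getattr(r, name) for r in records], dtype=float)
        cov_rows.append(_continuous_row(name, v, flags))
    for name in CATEGORICAL_COVARIATES:
        v = np.array([str(getattr(r, name)) for r in records])
        cats = sorted(set(v))
        table = np.array([[(v[flags] == c).sum() for c in cats],
                          [(v[~flags] == c).sum() for c in cats]])
        res = categorical_test(table)
        cov_rows.append({
            "variable": name, "kind": "categorical",
            "flagged_mean": np.nan, "flagged_sd": np.nan,
            "unflagged_mean": np.nan, "unflagged_sd": np.nan,
            "levels": "/".join(cats),
            "flagged_counts": "/".join(str(int(c)) for c in table[0]),
            "unflagged_counts": "/".join(str(int(c)) for c in table[1]),
            "p_value": res.p_value, "method": res.method,
        })
    deltas = pd.DataFrame([r.delta().as_dict() for r in records])
    delta_rows = [
        _continuous_row(name, deltas[name].to_numpy(), flags)
        for name in OuterRetinalMetrics.field_names()
    ]
    return (pd.DataFrame(cov_rows).set_index("variable"),
            pd.DataFrame(delta_rows).set_index("variable"))


def _continuous_row(name: str, values: np.ndarray, flags: np.ndarray) -> dict:
    x, y = values[flags], values[~flags]
    if len(x) >= 2 and len(y) >= 2:
        res = welch_ttest(x, y)
    else:
        res = TestResult(float("nan"), float("nan"), "Welch t (group too small)")
    return {
        "variable": name, "kind": "continuous",
        "flagged_mean": x.mean() if len(x) else np.nan,
        "flagged_sd": x.std(ddof=1) if len(x) > 1 else np.nan,
        "unflagged_mean": y.mean() if len(y) else np.nan,
        "unflagged_sd": y.std(ddof=1) if len(y) > 1 else np.nan,
        "levels": "", "flagged_counts": "", "unflagged_counts": "",
        "p_value": res.p_value, "method": res.method,
    }


def _pct(num: int, den: int) -> float:
    """Percentage with 1-dp rounding and an explicit zero-denominator guard."""
    return 0.0 if den == 0 else round(100.0 * num / den, 1)


@dataclass(frozen=True)
class ConcordanceReport:
    """Screening-concordance counts and percentages (1-dp)."""

    n_eyes: int
    n_flagged: int
    n_expert_progression: int
    n_clinical_ever: int
    pct_flagged: float
    pct_flagged_clinician_oct2: float
    pct_flagged_expert_toxicity: float
    pct_expert_progression: float
    pct_expert_progression_flagged: float
    pct_expert_progression_clinician_oct2: float
    pct_clinical_ever: float

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self)}


def screening_concordance(
    records: list[CohortRecord], flags: np.ndarray
) -> ConcordanceReport:
    """Cross-tabulate the progression flag against toxicity labels.

    Reports, each rounded to 1 dp: % of the cohort flagged; % of flagged
    eyes with a clinician diagnosis at OCT2; % of flagged eyes with expert
    toxicity; % of the cohort with expert-noted progression; % of
    expert-progression eyes flagged; % of expert-progression eyes
    clinically recognized at OCT2; % of the cohort clinically diagnosed
    ever.
    """
    flags = np.asarray(flags, dtype=bool)
    clin2 = np.array([r.clinician_toxicity_at_oct2 for r in records])
    clin_ever = np.array([r.clinician_toxicity_ever for r in records])
    expert_tox = np.array([r.expert_toxicity_oct2 for r in records])
    expert_prog = np.array([r.expert_progression for r in records])
    n = len(records)
    n_flag = int(flags.sum())
    n_exp = int(expert_prog.sum())
    return ConcordanceReport(
        n_eyes=n,
        n_flagged=n_flag,
        n_expert_progression=n_exp,
        n_clinical_ever=int(clin_ever.sum()),
        pct_flagged=_pct(n_flag, n),
        pct_flagged_clinician_oct2=_pct(int((flags & clin2).sum()), n_flag),
        pct_flagged_expert_toxicity=_pct(int((flags & expert_tox).sum()), n_flag),
        pct_expert_progression=_pct(n_exp, n),
        pct_expert_progression_flagged=_pct(int((expert_prog & flags).sum()), n_exp),
        pct_expert_progression_clinician_oct2=_pct(
            int((expert_prog & clin2).sum()), n_exp),
        pct_clinical_ever=_pct(int(clin_ever.sum()), n),
    )


class ProgressionAnalysis:
    """Longitudinal progression model for a cohort of eyes on HCQ.

    Parameters
    ----------
    records
        Per-eye :class:`~ezmap.cohort.CohortRecord` list with metrics at
        both timepoints.
    validate
        Run per-record invariant checks on construction (default True).
    """

    def __init__(self, records: list[CohortRecord], validate: bool = True):
        if len(records) < 2:
            raise ValidationError("cohort analysis requires at least 2 eyes")
        if validate:
            for r in records:
                r.validate()
        self.records = list(records)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "ProgressionAnalysis":
        """Build from a flat cohort table (see :mod:`ezmap.io` for the schema)."""
        from .io import records_from_frame

        return cls(records_from_frame(frame), **kwargs)

    def fit(
        self,
        threshold_pp: float = PROGRESSION_THRESHOLD_PP,
        metric: str = PROGRESSION_METRIC,
        inclusive: bool = True,
        alpha: float = 0.05,
    ) -> "ProgressionResults":
        """Classify progressors and compute all cohort summaries."""
        flags = compute_flags(self.records, threshold_pp, metric, inclusive)
        paired = cohort_paired_summary(self.records)
        covariates, deltas = progressor_group_comparison(self.records, flags)
        concordance = screening_concordance(self.records, flags)
        expert = [r.expert_toxicity_oct2 for r in self.records]
        clin = [r.clinician_toxicity_ever for r in self.records]
        kappa = cohen_kappa(expert, clin)
        return ProgressionResults(
            model=self, flags=flags, threshold_pp=threshold_pp, metric=metric,
            alpha=alpha, paired_summary=paired, covariate_comparison=covariates,
            delta_comparison=deltas, concordance=concordance,
            label_agreement_kappa=kappa,
        )


@dataclass
class ProgressionResults:
    """Fitted cohort results: flags, summaries, comparisons, concordance."""

    model: ProgressionAnalysis
    flags: np.ndarray
    threshold_pp: float
    metric: str
    alpha: float
    paired_summary: pd.DataFrame
    covariate_comparison: pd.DataFrame
    delta_comparison: pd.DataFrame
    concordance: ConcordanceReport
    label_agreement_kappa: float

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())

    def significant_metrics(self) -> list[str]:
        p = self.paired_summary["p_value"]
        return list(p.index[p < self.alpha])

    def summary(self) -> str:
        c = self.concordance
        lines = [
            "Longitudinal EZ attenuation analysis",
            "=" * 36,
            f"Eyes: {c.n_eyes}   threshold: >= {self.threshold_pp:g} pp "
            f"increase in {self.metric}",
            f"Flagged progressors: {c.n_flagged} ({c.pct_flagged}%)",
            f"Expert-noted progression: {c.n_expert_progression} "
            f"({c.pct_expert_progression}%)",
            f"Clinician-diagnosed toxicity ever: {c.n_clinical_ever} "
            f"({c.pct_clinical_ever}%)",
            f"Expert toxicity among flagged: {c.pct_flagged_expert_toxicity}%",
            f"Flagged among expert progression: {c.pct_expert_progression_flagged}%",
            f"Label agreement (expert vs clinician ever), kappa: "
            f"{self.label_agreement_kappa:.2f}",
            "",
            "Paired longitudinal summary (OCT1 -> OCT2)",
            "-" * 42,
            self.paired_summary.round(3).to_string(),
            "",
            "Flagged vs unflagged covariates",
            "-" * 31,
            self.covariate_comparison[
                ["flagged_mean", "unflagged_mean", "p_value", "method"]
            ].round(3).to_string(),
        ]
        return "\n".join(lines)
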