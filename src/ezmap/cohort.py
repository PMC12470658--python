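"""Per-eye longitudinal records, metric deltas, and the progression rule.

One record holds a single study eye (one eye per subject, right eye when
both are eligible): clinical covariates, the outer-retinal metric vector at
two OCT timepoints at least one year apart, and toxicity labels from the
managing clinician and from masked expert readers.

An eye is classified a *progressor* when its en-face partial EZ attenuation
increases by at least 4 percentage points between the two OCTs.  The
threshold is applied to the partial-attenuation delta and is inclusive;
both choices are configurable (`metric=`, `inclusive=`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dataclass_fields

from .exceptions import ValidationError
from .mapping import OuterRetinalMetrics

#: Default progression threshold, in absolute percentage points of
#: partial EZ attenuation between the two OCTs.
PROGRESSION_THRESHOLD_PP = 4.0
#: Metric delta the progression rule is applied to.
PROGRESSION_METRIC = "partial_attenuation_pct"

CONTINUOUS_COVARIATES = (
    "age_hcq_initiated_yr",
    "age_oct1_yr",
    "age_oct2_yr",
    "daily_dose_mg",
    "abw_dose_mg_kg",
    "ibw_dose_mg_kg",
    "cumulative_dose_kg",
    "duration_yr",
    "interval_yr",
    "logmar_oct1",
    "logmar_oct2",
)
CATEGORICAL_COVARIATES = (
    "gender",
    "ethnicity",
    "indication",
    "tamoxifen",
    "kidney_disease",
)
LABEL_FIELDS = (
    "clinician_toxicity_at_oct2",
    "clinician_toxicity_ever",
    "expert_toxicity_oct2",
    "expert_progression",
)


@dataclass
class MetricsDelta:
    """Elementwise OCT2 - OCT1 difference of the metric vector.

    Attenuation deltas are absolute percentage-point changes (not relative).
    """

    partial_attenuation_pct: float
    total_attenuation_pct: float
    csf_thickness_um: float
    csf_volume_mm3: float
    csf_point_nasal_um: float
    csf_point_temporal_um: float
    parafoveal_thickness_um: float
    parafoveal_volume_mm3: float
    parafoveal_point_nasal_um: float
    parafoveal_point_temporal_um: float
    cube_volume_mm3: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in dataclass_fields(self)}


@dataclass
class CohortRecord:
    """One study eye: covariates, metrics at both OCTs, and labels."""

    eye_id: str
    laterality: str = "OD"
    # clinical covariates
    age_hcq_initiated_yr: float = float("nan")
    age_oct1_yr: float = float("nan")
    age_oct2_yr: float = float("nan")
    daily_dose_mg: float = float("nan")
    abw_dose_mg_kg: float = float("nan")
    ibw_dose_mg_kg: float = float("nan")
    cumulative_dose_kg: float = float("nan")
    duration_yr: float = float("nan")
    interval_yr: float = float("nan")
    logmar_oct1: float = float("nan")
    logmar_oct2: float = float("nan")
    gender: str = "F"
    ethnicity: str = "White"
    indication: str = "RA"
    tamoxifen: bool = False
    kidney_disease: bool = False
    # outer-retinal metrics
    metrics_oct1: OuterRetinalMetrics | None = None
    metrics_oct2: OuterRetinalMetrics | None = None
    # toxicity labels
    clinician_toxicity_at_oct2: bool = False
    clinician_toxicity_ever: bool = False
    expert_toxicity_oct2: bool = False
    expert_progression: bool = False

    def validate(self) -> None:
        if self.interval_yr == self.interval_yr and self.interval_yr < 1.0:
            raise ValidationError(
                f"{self.eye_id}: OCT interval must be at least 1 year"
            )
        if (self.age_oct1_yr == self.age_oct1_yr
                and self.age_oct2_yr == self.age_oct2_yr
                and self.age_oct2_yr < self.age_oct1_yr):
            raise ValidationError(f"{self.eye_id}: ages must increase OCT1 -> OCT2")
        for name in ("logmar_oct1", "logmar_oct2"):
            v = getattr(self, name)
            if v == v and not (-0.3 <= v <= 3.0):
                raise ValidationError(f"{self.eye_id}: {name}={v} outside [-0.3, 3]")

    def delta(self) -> MetricsDelta:
        if self.metrics_oct1 is None or self.metrics_oct2 is None:
            raise ValidationError(f"{self.eye_id}: metrics missing at a timepoint")
        return longitudinal_change(self.metrics_oct1, self.metrics_oct2)


def longitudinal_change(
    m1: OuterRetinalMetrics, m2: OuterRetinalMetrics
) -> MetricsDelta:
    """Elementwise metric difference, OCT2 - OCT1."""
    d1, d2 = m1.as_dict(), m2.as_dict()
    return MetricsDelta(**{k: d2[k] - d1[k] for k in d1})


def classify_progressor(
    delta: MetricsDelta,
    threshold_pp: float = PROGRESSION_THRESHOLD_PP,
    metric: str = PROGRESSION_METRIC,
    inclusive: bool = True,
) -> bool:
    """Flag an eye whose attenuation increased by >= threshold_pp points."""
    change = getattr(delta, metric)
    return change >= threshold_pp if inclusive else change > threshold_pp
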