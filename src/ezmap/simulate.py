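"""Synthetic macular cubes, boundary surfaces, eye pairs and cohorts.

No patient data ship with this package; every downstream stage is exercised
on synthetic inputs whose statistical structure mirrors the screening
cohort the analysis is designed for:

* The *thickness phenotype* is a radial EZ-RPE field: a smooth base profile
  interpolating the central-subfield mean (40.4 um) to the parafoveal mean
  (36.8 um) with a gentle peripheral slope, minus an annular Gaussian dip
  centered ~1.2 mm from the fovea.  The dip stylizes the parafoveal
  thinning of early hydroxychloroquine (HCQ) toxicity; in "progressor" eyes
  it deepens between the two timepoints, in stable eyes it is absent and
  the two timepoints differ only by measurement noise.
* The *intensity renderer* paints Gaussian-profile bright bands at the four
  boundary depths (ILM, outer OPL, EZ, RPE) over a dark background with
  multiplicative speckle, emulating B-scan appearance well enough to test
  segmentation end to end.
* The *cohort generator* samples clinical covariates per group (age at HCQ
  initiation ~ N(61.6, 13.0) for progressors vs N(50.5, 12.1) for stable
  eyes, baseline logMAR ~ N(0.20, 0.24) vs N(0.08, 0.16) floored at -0.12,
  OCT interval ~ N(3.1, 0.9) truncated at 1 year) and assigns clinician /
  expert toxicity labels to match configurable concordance counts.
* ``fixture_cohort_from_counts`` builds a fully deterministic cohort whose
  flag/label contingency structure equals a set of integer screening counts
  exactly, for arithmetic checks.

Everything is deterministic under a fixed seed (numpy Generator streams).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .boundaries import BoundarySet
from .cohort import CohortRecord
from .exceptions import ValidationError
from .geometry import CubeGeometry
from .mapping import (
    EZRPEMap,
    OuterRetinalMetrics,
    PARTIAL_ATTENUATION_THRESHOLD_UM,
    compute_metrics,
)

# -- anatomy constants for the intensity phantom (um from frame top) --------

RPE_DEPTH_UM = 350.0          # flat RPE reference surface
RETINA_THICKNESS_UM = 330.0   # ILM-to-RPE away from the fovea
FOVEAL_PIT_DEPTH_UM = 110.0   # pit excavation of the ILM at the fovea
FOVEAL_PIT_SIGMA_MM = 0.30
ONL_THICKNESS_UM = 80.0       # OPL-to-EZ away from the fovea
ONL_FOVEAL_BULGE_UM = 30.0
ONL_BULGE_SIGMA_MM = 0.35

#: Peak reflectivity of each boundary band in the phantom (arbitrary units).
BAND_AMPLITUDE = {"ilm": 0.9, "opl": 0.55, "ez": 0.85, "rpe": 1.0}
BAND_SIGMA_UM = 5.0
BACKGROUND_LEVEL = 0.05
DEFAULT_SPECKLE_SIGMA = 0.35
DEFAULT_N_AXIAL = 1024


@dataclass(frozen=True)
class PhenotypeParams:
    """Parameters of the radial EZ-RPE thickness phenotype.

    ``ring_depth_um_t1`` / ``ring_depth_um_t2`` are the annular dip depths
    at the two OCT timepoints; progressors deepen between them, stable eyes
    keep both at zero.
    """

    base_csf_um: float = 40.4
    base_parafoveal_um: float = 36.8
    peripheral_slope_um_per_mm: float = -1.0
    ring_center_mm: float = 1.2
    ring_sigma_mm: float = 0.4
    ring_depth_um_t1: float = 0.0
    ring_depth_um_t2: float = 0.0
    noise_sd_um: float = 1.5
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("base_csf_um", "base_parafoveal_um", "ring_sigma_mm",
                     "ring_depth_um_t1", "ring_depth_um_t2", "noise_sd_um"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.ring_center_mm < 0:
            raise ValidationError("ring_center_mm must be >= 0")
        # a zero t2 with a configured t1 denotes single-timepoint use
        if 0 < self.ring_depth_um_t2 < self.ring_depth_um_t1:
            raise ValidationError(
                "progressor phenotype requires ring_depth_um_t2 >= ring_depth_um_t1"
            )

    @classmethod
    def stable(cls, **overrides) -> "PhenotypeParams":
        return cls(**overrides)

    @classmethod
    def progressor(cls, **overrides) -> "PhenotypeParams":
        defaults = dict(ring_depth_um_t1=10.0, ring_depth_um_t2=35.0)
        defaults.update(overrides)
        return cls(**defaults)


def base_profile_um(r_mm: np.ndarray, params: PhenotypeParams) -> np.ndarray:
    """Noise-free base thickness at en-face radius r (no annular dip)."""
    r = np.asarray(r_mm, dtype=float)
    inner = (params.base_csf_um
             + (params.base_parafoveal_um - params.base_csf_um) * r)
    outer = (params.base_parafoveal_um
             + params.peripheral_slope_um_per_mm * (r - 1.0))
    return np.clip(np.where(r <= 1.0, inner, outer), 0.0, None)


def truth_profile_um(r_mm: np.ndarray, params: PhenotypeParams,
                     ring_depth_um: float) -> np.ndarray:
    """Noise-free thickness profile including the annular dip, clamped >= 0."""
    r = np.asarray(r_mm, dtype=float)
    dip = ring_depth_um * np.exp(
        -((r - params.ring_center_mm) ** 2) / (2.0 * params.ring_sigma_mm ** 2)
    )
    return np.clip(base_profile_um(r, params) - dip, 0.0, None)


def _ring_depth(params: PhenotypeParams, timepoint: int) -> float:
    if timepoint not in (1, 2):
        raise ValidationError("timepoint must be 1 or 2")
    return params.ring_depth_um_t1 if timepoint == 1 else params.ring_depth_um_t2


def simulate_thickness_field(
    params: PhenotypeParams,
    geometry: CubeGeometry | None = None,
    timepoint: int = 1,
    seed: int | np.random.Generator | None = None,
) -> EZRPEMap:
    """Ground-truth EZ-RPE thickness map for one eye at one timepoint.

    T(r) = base(r) - depth * exp(-(r - ring_center)^2 / (2 sigma^2)) + noise,
    clamped at 0; deterministic under a fixed seed.
    """
    geometry = geometry or CubeGeometry()
    if params.ring_center_mm >= min(geometry.extent_fast_mm,
                                    geometry.extent_slow_mm) / 2:
        raise ValidationError("ring_center_mm must lie inside the cube half-extent")
    r = geometry.fovea_distance_mm()
    t = truth_profile_um(r, params, _ring_depth(params, timepoint))
    if params.noise_sd_um > 0:
        rng = _as_rng(seed if seed is not None else params.seed)
        t = t + rng.normal(0.0, params.noise_sd_um, size=t.shape)
    return EZRPEMap(np.clip(t, 0.0, None), np.ones(t.shape, dtype=bool), geometry)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def attenuated_fraction_continuum(
    ring_depth_um: float,
    params: PhenotypeParams,
    geometry: CubeGeometry | None = None,
    threshold_um: float = PARTIAL_ATTENUATION_THRESHOLD_UM,
    n_radial: int = 4000,
) -> float:
    """Continuum (grid-free) attenuated area fraction of the noise-free field.

    Integrates the annular region where the radial profile drops to or below
    the threshold; requires the region to stay inside the inscribed circle
    of the scan rectangle (it does for realistic ring parameters).
    """
    geometry = geometry or CubeGeometry()
    r_max = min(geometry.extent_fast_mm, geometry.extent_slow_mm) / 2
    r = np.linspace(0.0, r_max, n_radial)
    below = truth_profile_um(r, params, ring_depth_um) <= threshold_um
    if below[-1]:
        raise ValidationError(
            "attenuated region reaches the cube edge; target fraction too large"
        )
    dr = r[1] - r[0]
    area = float((2.0 * np.pi * r[below]).sum() * dr)
    return area / geometry.scan_area_mm2


def ring_depth_for_attenuation(
    target_pct: float,
    params: PhenotypeParams | None = None,
    geometry: CubeGeometry | None = None,
    threshold_um: float = PARTIAL_ATTENUATION_THRESHOLD_UM,
) -> float:
    """Annular dip depth (um) producing a target partial-attenuation %.

    Solves the continuum area fraction for the depth by bracketing +
    root-finding; target 0 returns depth 0.
    """
    params = params or PhenotypeParams()
    geometry = geometry or CubeGeometry()
    if not 0 <= target_pct < 100:
        raise ValidationError("target percentage must be in [0, 100)")
    if target_pct == 0:
        return 0.0
    target = target_pct / 100.0

    def f(d: float) -> float:
        return attenuated_fraction_continuum(d, params, geometry, threshold_um) - target

    hi = 30.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1000.0:
            raise ValidationError("target attenuation unreachable for this phenotype")
    return float(brentq(f, 0.0, hi, xtol=1e-6))


# -- intensity-cube rendering ------------------------------------------------


def boundary_surfaces_from_field(field: EZRPEMap) -> BoundarySet:
    """Ground-truth boundary surfaces consistent with a thickness field.

    The RPE is flat at ``RPE_DEPTH_UM``; the EZ sits ``thickness`` above it;
    the OPL and ILM follow a stylized foveal anatomy (ONL bulge, foveal pit).
    """
    geom = field.geometry
    r = geom.fovea_distance_mm()
    rpe = np.full(geom.shape, RPE_DEPTH_UM)
    ez = rpe - field.thickness_um
    onl = (ONL_THICKNESS_UM
           + ONL_FOVEAL_BULGE_UM * np.exp(-r ** 2 / (2 * ONL_BULGE_SIGMA_MM ** 2)))
    opl = ez - onl
    retina = (RETINA_THICKNESS_UM
              - FOVEAL_PIT_DEPTH_UM * np.exp(-r ** 2 / (2 * FOVEAL_PIT_SIGMA_MM ** 2)))
    ilm = rpe - retina
    bs = BoundarySet(ilm, opl, ez, rpe, field.valid.copy())
    bs.validate()
    return bs


def render_intensity_cube(
    boundaries: BoundarySet,
    geometry: CubeGeometry | None = None,
    n_axial: int = DEFAULT_N_AXIAL,
    speckle_sigma: float = DEFAULT_SPECKLE_SIGMA,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Render a synthetic intensity cube from boundary surfaces.

    Returns a float32 array of shape (n_slow, n_axial, n_fast): one frame
    per B-scan.  Each A-scan holds Gaussian-profile bright bands at the four
    boundary depths over a dark background; ``speckle_sigma`` controls
    multiplicative log-normal speckle (0 disables noise).
    """
    geometry = geometry or CubeGeometry()
    if boundaries.shape != geometry.shape:
        raise ValidationError("boundary grid does not match geometry")
    rng = _as_rng(seed)
    z = (np.arange(n_axial) + 0.5) * geometry.axial_um_per_px  # um, frame top = 0
    cube = np.empty((geometry.n_slow, n_axial, geometry.n_fast), dtype=np.float32)
    two_s2 = 2.0 * BAND_SIGMA_UM ** 2
    for s in range(geometry.n_slow):
        frame = np.full((n_axial, geometry.n_fast), BACKGROUND_LEVEL)
        for name, amp in BAND_AMPLITUDE.items():
            depth = boundaries.depth(name)[s]  # (n_fast,)
            frame += amp * np.exp(-((z[:, None] - depth[None, :]) ** 2) / two_s2)
        if speckle_sigma > 0:
            frame = frame * rng.lognormal(
                mean=-0.5 * speckle_sigma ** 2, sigma=speckle_sigma, size=frame.shape
            )
            frame = frame + rng.normal(0.0, 0.01, size=frame.shape)
        cube[s] = np.clip(frame, 0.0, None)
    return cube


@dataclass
class EyePair:
    """One simulated eye at both timepoints, with ground truth."""

    truth_t1: EZRPEMap
    truth_t2: EZRPEMap
    boundaries_t1: BoundarySet
    boundaries_t2: BoundarySet
    cube_t1: np.ndarray | None = None
    cube_t2: np.ndarray | None = None


def simulate_eye_pair(
    params: PhenotypeParams,
    geometry: CubeGeometry | None = None,
    seed: int | np.random.Generator | None = None,
    render_cubes: bool = False,
    n_axial: int = DEFAULT_N_AXIAL,
    speckle_sigma: float = DEFAULT_SPECKLE_SIGMA,
) -> EyePair:
    """Simulate one eye at OCT1 and OCT2.

    OCT2 uses ``ring_depth_um_t2``; a stable phenotype differs between the
    timepoints only by measurement noise.
    """
    geometry = geometry or CubeGeometry()
    rng = _as_rng(seed if seed is not None else params.seed)
    t1 = simulate_thickness_field(params, geometry, timepoint=1, seed=rng)
    t2 = simulate_thickness_field(params, geometry, timepoint=2, seed=rng)
    # boundary ground truth is built from the noise-free profile plus the
    # same measurement noise realization baked into the truth fields
    b1 = boundary_surfaces_from_field(t1)
    b2 = boundary_surfaces_from_field(t2)
    c1 = c2 = None
    if render_cubes:
        c1 = render_intensity_cube(b1, geometry, n_axial, speckle_sigma, rng)
        c2 = render_intensity_cube(b2, geometry, n_axial, speckle_sigma, rng)
    return EyePair(t1, t2, b1, b2, c1, c2)


# -- cohort-level generation -------------------------------------------------


@dataclass(frozen=True)
class ConcordanceCounts:
    """Integer screening-concordance counts for one cohort.

    Defaults are the reported cohort: 373 eyes, 34 flagged by the >= 4
    percentage-point rule, 27 with expert-noted progression (26 of them
    flagged), 3 clinician diagnoses at OCT2 and 6 ever (one of the three
    later diagnoses falling in the flagged group).
    """

    n_eyes: int = 373
    n_flagged: int = 34
    n_expert_progression: int = 27
    n_expert_and_flagged: int = 26
    n_clinical_at_oct2: int = 3
    n_clinical_total: int = 6
    n_clinical_later_flagged: int = 1

    def __post_init__(self) -> None:
        c = self
        checks = [
            0 <= c.n_flagged <= c.n_eyes,
            0 <= c.n_expert_progression <= c.n_eyes,
            0 <= c.n_expert_and_flagged <= min(c.n_flagged, c.n_expert_progression),
            0 <= c.n_clinical_at_oct2 <= c.n_clinical_total <= c.n_eyes,
            c.n_clinical_later_flagged >= 0,
            (c.n_clinical_at_oct2 + c.n_clinical_later_flagged
             <= max(c.n_expert_and_flagged, 0)
             or (c.n_clinical_at_oct2 + c.n_clinical_later_flagged == 0)),
            (c.n_clinical_at_oct2 + c.n_clinical_later_flagged
             <= c.n_clinical_total),
            # unflagged non-expert eyes must accommodate the remaining
            # later clinician diagnoses
            (c.n_clinical_total - c.n_clinical_at_oct2 - c.n_clinical_later_flagged
             <= c.n_eyes - c.n_flagged
             - (c.n_expert_progression - c.n_expert_and_flagged)),
        ]
        if not all(checks):
            raise ValidationError("inconsistent nested concordance counts")


@dataclass(frozen=True)
class CohortParams:
    """Cohort size, group covariate distributions and label counts.

    The (mean, SD) pairs follow the reported group summaries; covariates
    are sampled independently within group.
    """

    n_eyes: int = 373
    n_progressors: int = 34
    age_init_progressor: tuple[float, float] = (61.6, 13.0)
    age_init_stable: tuple[float, float] = (50.5, 12.1)
    age_init_min_yr: float = 18.0
    logmar_progressor: tuple[float, float] = (0.20, 0.24)
    logmar_stable: tuple[float, float] = (0.08, 0.16)
    logmar_floor: float = -0.12
    interval_yr: tuple[float, float] = (3.1, 0.9)
    interval_min_yr: float = 1.0
    duration_yr: tuple[float, float] = (5.6, 3.7)
    duration_min_yr: float = 0.5
    daily_dose_mg: tuple[float, float] = (379.38, 59.40)
    abw_dose_mg_kg: tuple[float, float] = (4.8, 1.5)
    ibw_dose_mg_kg: tuple[float, float] = (6.5, 1.5)
    female_fraction: float = 0.86
    tamoxifen_fraction: float = 0.02
    kidney_fraction: float = 0.06
    phenotype_progressor: PhenotypeParams = field(
        default_factory=PhenotypeParams.progressor)
    phenotype_stable: PhenotypeParams = field(default_factory=PhenotypeParams.stable)
    concordance: ConcordanceCounts = field(default_factory=ConcordanceCounts)

    def __post_init__(self) -> None:
        if not 0 <= self.n_progressors <= self.n_eyes:
            raise ValidationError("need 0 <= n_progressors <= n_eyes")
        for name in ("age_init_progressor", "age_init_stable", "logmar_progressor",
                     "logmar_stable", "interval_yr", "duration_yr", "daily_dose_mg",
                     "abw_dose_mg_kg", "ibw_dose_mg_kg"):
            if getattr(self, name)[1] <= 0:
                raise ValidationError(f"{name} SD must be positive")


_ETHNICITIES = ("White", "Black", "Hispanic", "Asian", "Other")
_ETHNICITY_P = (0.70, 0.24, 0.01, 0.02, 0.03)
_INDICATIONS = ("RA", "Lupus", "Other")
_INDICATION_P = (0.43, 0.35, 0.22)


def _truncated_normal(rng, mean, sd, low, size):
    out = rng.normal(mean, sd, size=size)
    while True:
        bad = out < low
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))


def _scaled_label_counts(cc: ConcordanceCounts, n_eyes: int,
                         n_progressors: int) -> dict[str, int]:
    """Scale the default concordance counts to a different cohort size."""
    if cc.n_flagged == 0 or n_progressors == 0:
        return dict(expert_flagged=0, expert_stable=0, clin_oct2=0,
                    clin_later_flagged=0, clin_later_stable=0)
    f = n_progressors / cc.n_flagged
    expert_flagged = min(round(cc.n_expert_and_flagged * f), n_progressors)
    clin_oct2 = min(round(cc.n_clinical_at_oct2 * f), expert_flagged)
    clin_later_flagged = min(round(cc.n_clinical_later_flagged * f),
                             expert_flagged - clin_oct2)
    g = n_eyes / cc.n_eyes
    expert_stable = min(
        round((cc.n_expert_progression - cc.n_expert_and_flagged) * g),
        n_eyes - n_progressors)
    clin_later_stable = min(
        round((cc.n_clinical_total - cc.n_clinical_at_oct2
               - cc.n_clinical_later_flagged) * g),
        n_eyes - n_progressors - expert_stable)
    return dict(expert_flagged=expert_flagged, expert_stable=expert_stable,
                clin_oct2=clin_oct2, clin_later_flagged=clin_later_flagged,
                clin_later_stable=clin_later_stable)


def simulate_cohort(
    cp: CohortParams | None = None,
    geometry: CubeGeometry | None = None,
    seed: int | np.random.Generator | None = None,
) -> list[CohortRecord]:
    """Simulate a full longitudinal cohort of one-eye records.

    Exactly ``n_progressors`` eyes carry the progressor phenotype and
    progressor covariate distributions; the remainder are stable.  Metric
    vectors are computed from simulated thickness fields at both
    timepoints; labels are assigned to match the configured concordance
    counts (scaled to the cohort size).
    """
    cp = cp or CohortParams()
    geometry = geometry or CubeGeometry()
    rng = _as_rng(seed)
    n, n_prog = cp.n_eyes, cp.n_progressors
    is_prog = np.zeros(n, dtype=bool)
    is_prog[rng.choice(n, size=n_prog, replace=False)] = True

    def group_normal(pair_prog, pair_stable, low):
        out = np.empty(n)
        out[is_prog] = _truncated_normal(rng, *pair_prog, low, int(n_prog))
        out[~is_prog] = _truncated_normal(rng, *pair_stable, low, int(n - n_prog))
        return out

    age_init = group_normal(cp.age_init_progressor, cp.age_init_stable,
                            cp.age_init_min_yr)
    logmar1 = group_normal(cp.logmar_progressor, cp.logmar_stable, cp.logmar_floor)
    logmar2 = np.clip(logmar1 + rng.normal(0.013, 0.05, size=n), cp.logmar_floor, 3.0)
    duration = _truncated_normal(rng, *cp.duration_yr, cp.duration_min_yr, n)
    interval = _truncated_normal(rng, *cp.interval_yr, cp.interval_min_yr, n)
    daily = _truncated_normal(rng, *cp.daily_dose_mg, 50.0, n)
    abw = _truncated_normal(rng, *cp.abw_dose_mg_kg, 0.5, n)
    ibw = _truncated_normal(rng, *cp.ibw_dose_mg_kg, 0.5, n)
    cumulative_kg = daily * 365.25 * duration / 1e6
    female = rng.random(n) < cp.female_fraction
    ethnicity = rng.choice(_ETHNICITIES, size=n, p=_ETHNICITY_P)
    indication = rng.choice(_INDICATIONS, size=n, p=_INDICATION_P)
    tamoxifen = rng.random(n) < cp.tamoxifen_fraction
    kidney = rng.random(n) < cp.kidney_fraction

    counts = _scaled_label_counts(cp.concordance, n, n_prog)
    prog_idx = np.flatnonzero(is_prog)
    stable_idx = np.flatnonzero(~is_prog)
    expert = np.zeros(n, dtype=bool)
    clin_oct2 = np.zeros(n, dtype=bool)
    clin_ever = np.zeros(n, dtype=bool)
    expert[prog_idx[:counts["expert_flagged"]]] = True
    clin_oct2[prog_idx[:counts["clin_oct2"]]] = True
    clin_ever[prog_idx[:counts["clin_oct2"] + counts["clin_later_flagged"]]] = True
    expert[stable_idx[:counts["expert_stable"]]] = True
    clin_ever[stable_idx[counts["expert_stable"]:
                         counts["expert_stable"] + counts["clin_later_stable"]]] = True

    records: list[CohortRecord] = []
    for i in range(n):
        params = cp.phenotype_progressor if is_prog[i] else cp.phenotype_stable
        m1 = compute_metrics(
            simulate_thickness_field(params, geometry, timepoint=1, seed=rng))
        m2 = compute_metrics(
            simulate_thickness_field(params, geometry, timepoint=2, seed=rng))
        rec = CohortRecord(
            eye_id=f"EYE-{i + 1:04d}",
            laterality="OD",
            age_hcq_initiated_yr=float(age_init[i]),
            age_oct1_yr=float(age_init[i] + duration[i]),
            age_oct2_yr=float(age_init[i] + duration[i] + interval[i]),
            daily_dose_mg=float(daily[i]),
            abw_dose_mg_kg=float(abw[i]),
            ibw_dose_mg_kg=float(ibw[i]),
            cumulative_dose_kg=float(cumulative_kg[i]),
            duration_yr=float(duration[i]),
            interval_yr=float(interval[i]),
            logmar_oct1=float(logmar1[i]),
            logmar_oct2=float(logmar2[i]),
            gender="F" if female[i] else "M",
            ethnicity=str(ethnicity[i]),
            indication=str(indication[i]),
            tamoxifen=bool(tamoxifen[i]),
            kidney_disease=bool(kidney[i]),
            metrics_oct1=m1,
            metrics_oct2=m2,
            clinician_toxicity_at_oct2=bool(clin_oct2[i]),
            clinician_toxicity_ever=bool(clin_ever[i]),
            expert_toxicity_oct2=bool(expert[i]),
            expert_progression=bool(expert[i]),
        )
        rec.validate()
        records.append(rec)
    return records


def _fixture_metrics(partial_pct: float) -> OuterRetinalMetrics:
    """Plausible, internally consistent metric vector for fixture eyes."""
    return OuterRetinalMetrics(
        partial_attenuation_pct=partial_pct,
        total_attenuation_pct=partial_pct / 2.0,
        csf_thickness_um=40.4,
        csf_volume_mm3=0.032,
        csf_point_nasal_um=39.1,
        csf_point_temporal_um=37.9,
        parafoveal_thickness_um=36.8,
        parafoveal_volume_mm3=0.116,
        parafoveal_point_nasal_um=35.6,
        parafoveal_point_temporal_um=35.1,
        cube_volume_mm3=1.44,
    )


def fixture_cohort_from_counts(
    cc: ConcordanceCounts | None = None,
) -> list[CohortRecord]:
    """Deterministic cohort whose flag/label contingency equals the counts.

    Metric vectors are synthesized so that exactly ``n_flagged`` eyes show a
    partial-attenuation increase at or above the 4 percentage-point rule;
    labels are laid out to reproduce every nested count exactly.
    """
    cc = cc or ConcordanceCounts()
    n_flag_only = cc.n_flagged - cc.n_expert_and_flagged
    n_expert_stable = cc.n_expert_progression - cc.n_expert_and_flagged
    n_clin_later_stable = (cc.n_clinical_total - cc.n_clinical_at_oct2
                           - cc.n_clinical_later_flagged)
    records = []
    for i in range(cc.n_eyes):
        flagged = i < cc.n_flagged
        if i < cc.n_expert_and_flagged:
            expert, delta = True, 10.0
            clin2 = i < cc.n_clinical_at_oct2
            clin_ever = i < cc.n_clinical_at_oct2 + cc.n_clinical_later_flagged
        elif i < cc.n_flagged:
            expert, delta, clin2, clin_ever = False, 10.0, False, False
        elif i < cc.n_flagged + n_expert_stable:
            expert, delta, clin2, clin_ever = True, 2.0, False, False
        elif i < cc.n_flagged + n_expert_stable + n_clin_later_stable:
            expert, delta, clin2, clin_ever = False, 0.0, False, True
        else:
            expert, delta, clin2, clin_ever = False, 0.0, False, False
        base = 2.0
        rec = CohortRecord(
            eye_id=f"FIX-{i + 1:04d}",
            age_hcq_initiated_yr=61.6 if flagged else 50.5,
            age_oct1_yr=(61.6 if flagged else 50.5) + 5.6,
            age_oct2_yr=(61.6 if flagged else 50.5) + 5.6 + 3.1,
            daily_dose_mg=379.4,
            abw_dose_mg_kg=4.8,
            ibw_dose_mg_kg=6.5,
            cumulative_dose_kg=0.8,
            duration_yr=5.6,
            interval_yr=3.1,
            logmar_oct1=0.20 if flagged else 0.08,
            logmar_oct2=0.20 if flagged else 0.09,
            metrics_oct1=_fixture_metrics(base),
            metrics_oct2=_fixture_metrics(base + delta),
            clinician_toxicity_at_oct2=clin2,
            clinician_toxicity_ever=clin_ever,
            expert_toxicity_oct2=expert,
            expert_progression=expert,
        )
        records.append(rec)
    return records
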