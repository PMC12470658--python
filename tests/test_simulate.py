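"""Synthetic thickness fields, intensity cubes, eye pairs and cohorts."""

import numpy as np
import pytest
from scipy.optimize import brentq

import ezmap as ez
from ezmap.simulate import (
    BAND_AMPLITUDE,
    attenuated_fraction_continuum,
    boundary_surfaces_from_field,
    render_intensity_cube,
    truth_profile_um,
)

GEOM = ez.CubeGeometry(n_fast=128, n_slow=64)


class TestThicknessField:
    def test_no_dip_no_noise_means_no_attenuation(self, default_geometry):
        f = ez.simulate_thickness_field(
            ez.PhenotypeParams(noise_sd_um=0.0), default_geometry, 1)
        assert ez.partial_attenuation_percent(f) == 0.0

    def test_same_seed_reproduces_field_exactly(self):
        p = ez.PhenotypeParams(ring_depth_um_t1=20.0)
        a = ez.simulate_thickness_field(p, GEOM, 1, seed=42)
        b = ez.simulate_thickness_field(p, GEOM, 1, seed=42)
        c = ez.simulate_thickness_field(p, GEOM, 1, seed=43)
        assert (a.thickness_um == b.thickness_um).all()
        assert not (a.thickness_um == c.thickness_um).all()

    def test_attenuated_points_form_annulus_matching_radial_roots(
            self, default_geometry):
        """Grid count of attenuated points ~ closed-form annulus area."""
        p = ez.PhenotypeParams(ring_depth_um_t1=40.0, noise_sd_um=0.0)
        f = ez.simulate_thickness_field(p, default_geometry, 1)
        # radial threshold crossings of the noise-free profile
        def h(r):
            return float(truth_profile_um(np.array([r]), p, 40.0)[0]) - 20.0
        r1 = brentq(h, 0.3, p.ring_center_mm)
        r2 = brentq(h, p.ring_center_mm, 2.5)
        area = np.pi * (r2 ** 2 - r1 ** 2)
        expected_pct = 100.0 * area / default_geometry.scan_area_mm2
        got = ez.partial_attenuation_percent(f)
        assert got == pytest.approx(expected_pct, abs=0.2)
        # and the region is a ring: fovea itself is not attenuated
        att = f.thickness_um <= 20.0
        j0 = default_geometry.n_slow // 2
        i0 = default_geometry.n_fast // 2
        assert not att[j0, i0] and att.any()

    @pytest.mark.parametrize("target", [0.0, 2.0, 4.0, 10.0, 25.0])
    def test_ring_depth_solver_recovers_target_fraction(self, target,
                                                        default_geometry):
        depth = ez.ring_depth_for_attenuation(target, geometry=default_geometry)
        p = ez.PhenotypeParams(ring_depth_um_t1=depth, noise_sd_um=0.0)
        f = ez.simulate_thickness_field(p, default_geometry, 1)
        assert ez.partial_attenuation_percent(f) == pytest.approx(target, abs=0.5)

    def test_baseline_central_thickness_realistic(self, default_geometry):
        f = ez.simulate_thickness_field(ez.PhenotypeParams(), default_geometry,
                                        1, seed=0)
        cst = ez.zone_mean_thickness(f, ez.ZoneSpec.central_subfield())
        assert 30.0 <= cst <= 50.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ez.ValidationError):
            ez.PhenotypeParams(noise_sd_um=-1.0)
        with pytest.raises(ez.ValidationError):
            ez.PhenotypeParams(ring_depth_um_t1=30.0, ring_depth_um_t2=10.0)


class TestIntensityCube:
    def test_noise_free_band_maxima_sit_at_truth_depths(self):
        p = ez.PhenotypeParams(noise_sd_um=0.0)
        f = ez.simulate_thickness_field(p, GEOM, 1)
        b = boundary_surfaces_from_field(f)
        cube = render_intensity_cube(b, GEOM, n_axial=320, speckle_sigma=0.0)
        ascan = cube[10, :, 20]
        um = GEOM.axial_um_per_px
        rpe_px = int(round(b.rpe_um[10, 20] / um - 0.5))
        window = ascan[rpe_px - 2: rpe_px + 3]
        assert window.max() >= BAND_AMPLITUDE["rpe"] * 0.9

    def test_speckle_reduces_band_contrast(self):
        f = ez.simulate_thickness_field(
            ez.PhenotypeParams(noise_sd_um=0.0), GEOM, 1)
        b = boundary_surfaces_from_field(f)
        def contrast(sigma):
            cube = render_intensity_cube(b, GEOM, n_axial=320,
                                         speckle_sigma=sigma, seed=0)
            frame = cube[5]
            signal = np.percentile(frame, 99)
            noise_floor = np.median(frame)
            sd = frame[frame < signal / 2].std()
            return (signal - noise_floor) / (sd + 1e-9)
        assert contrast(0.6) < contrast(0.2)

    def test_fixed_seed_reproducible(self):
        f = ez.simulate_thickness_field(
            ez.PhenotypeParams(noise_sd_um=0.0), GEOM, 1)
        b = boundary_surfaces_from_field(f)
        c1 = render_intensity_cube(b, GEOM, n_axial=128, seed=5)
        c2 = render_intensity_cube(b, GEOM, n_axial=128, seed=5)
        assert (c1 == c2).all()


class TestEyePair:
    def test_progressor_crosses_threshold_and_stable_does_not(self):
        prog = ez.simulate_eye_pair(ez.PhenotypeParams.progressor(), GEOM, seed=1)
        d = ez.longitudinal_change(ez.compute_metrics(prog.truth_t1),
                                   ez.compute_metrics(prog.truth_t2))
        assert d.partial_attenuation_pct >= 4.0
        stable = ez.simulate_eye_pair(ez.PhenotypeParams.stable(), GEOM, seed=1)
        ds = ez.longitudinal_change(ez.compute_metrics(stable.truth_t1),
                                    ez.compute_metrics(stable.truth_t2))
        assert abs(ds.partial_attenuation_pct) < 1.0

    def test_different_seeds_differ(self):
        a = ez.simulate_eye_pair(ez.PhenotypeParams.stable(), GEOM, seed=1)
        b = ez.simulate_eye_pair(ez.PhenotypeParams.stable(), GEOM, seed=2)
        assert not (a.truth_t1.thickness_um == b.truth_t1.thickness_um).all()


class TestCohort:
    def test_progressors_are_exactly_the_flagged_eyes(self):
        cp = ez.CohortParams(n_eyes=50, n_progressors=5)
        records = ez.simulate_cohort(cp, GEOM, seed=11)
        flags = ez.compute_flags(records)
        assert flags.sum() == 5

    def test_no_progressors_no_flags(self):
        cp = ez.CohortParams(n_eyes=10, n_progressors=0)
        records = ez.simulate_cohort(cp, GEOM, seed=0)
        assert ez.compute_flags(records).sum() == 0

    def test_covariate_group_means_within_3_se(self):
        small = ez.CubeGeometry(n_fast=32, n_slow=32)
        cp = ez.CohortParams()
        records = ez.simulate_cohort(cp, small, seed=7)
        flags = ez.compute_flags(records)
        ages = np.array([r.age_hcq_initiated_yr for r in records])
        for sel, (mu, sd) in ((flags, cp.age_init_progressor),
                              (~flags, cp.age_init_stable)):
            se = sd / np.sqrt(sel.sum())
            assert abs(ages[sel].mean() - mu) < 3 * se + 0.5  # truncation margin

    def test_inconsistent_progressor_count_rejected(self):
        with pytest.raises(ez.ValidationError):
            ez.CohortParams(n_eyes=10, n_progressors=11)


class TestFixtureCohort:
    def test_default_counts_reproduced_exactly(self):
        records = ez.fixture_cohort_from_counts()
        flags = ez.compute_flags(records)
        assert len(records) == 373
        assert flags.sum() == 34
        assert sum(r.expert_progression for r in records) == 27
        assert sum(r.expert_progression and f for r, f in zip(records, flags)) == 26
        assert sum(r.clinician_toxicity_at_oct2 for r in records) == 3
        assert sum(r.clinician_toxicity_ever for r in records) == 6

    def test_zero_flagged_variant(self):
        cc = ez.ConcordanceCounts(n_eyes=20, n_flagged=0, n_expert_progression=0,
                                  n_expert_and_flagged=0, n_clinical_at_oct2=0,
                                  n_clinical_total=0, n_clinical_later_flagged=0)
        records = ez.fixture_cohort_from_counts(cc)
        assert ez.compute_flags(records).sum() == 0

    def test_nested_count_violation_rejected(self):
        with pytest.raises(ez.ValidationError):
            ez.ConcordanceCounts(n_flagged=400)
        with pytest.raises(ez.ValidationError):
            ez.ConcordanceCounts(n_expert_and_flagged=30, n_expert_progression=27)
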