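"""EZ-RPE map construction and the outer-retinal metric operations."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ezmap as ez
from _oracles import (
    bilinear_loop,
    partial_attenuation_loop,
    thickness_loop,
    zone_mean_loop,
    zone_volume_loop,
)
from conftest import random_map, uniform_map


def _map_from_depths(geometry, ez_um, rpe_um, valid=None):
    shape = geometry.shape
    zeros = np.zeros(shape)
    b = ez.BoundarySet(zeros, zeros + 100.0, np.full(shape, float(ez_um)),
                       np.full(shape, float(rpe_um)),
                       np.ones(shape, bool) if valid is None else valid)
    return ez.build_ezrpe_map(b, geometry)


class TestBuildMap:
    def test_degenerate_gap_gives_zero_map(self, small_geometry):
        m = _map_from_depths(small_geometry, 340.0, 340.0)
        assert (m.thickness_um == 0.0).all()

    def test_uniform_gap(self, small_geometry):
        m = _map_from_depths(small_geometry, 300.0, 340.0)
        assert (m.thickness_um == 40.0).all()

    def test_random_boundaries_match_elementwise_oracle(self, rng):
        g = ez.CubeGeometry(n_fast=5, n_slow=4)
        ez_um = rng.uniform(280, 320, g.shape)
        rpe_um = ez_um + rng.uniform(0, 50, g.shape)
        b = ez.BoundarySet(np.zeros(g.shape), np.full(g.shape, 200.0),
                           ez_um, rpe_um, np.ones(g.shape, bool))
        m = ez.build_ezrpe_map(b, g)
        assert np.allclose(m.thickness_um, np.array(thickness_loop(b)))

    def test_shape_mismatch_is_structural_error(self, small_geometry):
        shape = (3, 3)
        b = ez.BoundarySet(*[np.zeros(shape)] * 4, np.ones(shape, bool))
        with pytest.raises(ez.GeometryError):
            ez.build_ezrpe_map(b, small_geometry)

    def test_all_invalid_is_empty_map_error(self, small_geometry):
        shape = small_geometry.shape
        b = ez.BoundarySet(*[np.zeros(shape)] * 4, np.zeros(shape, bool))
        with pytest.raises(ez.EmptyMapError):
            ez.build_ezrpe_map(b, small_geometry)


class TestAttenuationPercent:
    def test_uniform_thick_map_has_no_attenuation(self, small_geometry):
        assert ez.partial_attenuation_percent(uniform_map(small_geometry, 30.0)) == 0.0

    def test_count_arithmetic_on_10x10(self):
        g = ez.CubeGeometry(n_fast=10, n_slow=10)
        grid = np.full(g.shape, 40.0)
        grid.flat[:4] = 10.0
        m = ez.EZRPEMap(grid, np.ones(g.shape, bool), g)
        assert ez.partial_attenuation_percent(m) == pytest.approx(4.0)

    def test_full_grid_count(self, default_geometry):
        grid = np.full(default_geometry.shape, 40.0)
        grid.flat[:2621] = 10.0
        m = ez.EZRPEMap(grid, np.ones(default_geometry.shape, bool),
                        default_geometry)
        p = ez.partial_attenuation_percent(m)
        assert p == pytest.approx(100.0 * 2621 / 65536)
        assert round(p, 1) == 4.0

    def test_threshold_is_inclusive(self, small_geometry):
        m = uniform_map(small_geometry, 20.0)
        assert ez.partial_attenuation_percent(m) == 100.0

    def test_total_on_uniform_zero_and_five(self, small_geometry):
        assert ez.total_attenuation_percent(uniform_map(small_geometry, 0.0)) == 100.0
        m5 = uniform_map(small_geometry, 5.0)
        assert ez.total_attenuation_percent(m5) == 0.0
        assert ez.partial_attenuation_percent(m5) == 100.0

    def test_empty_map_errors(self, small_geometry):
        m = uniform_map(small_geometry, 30.0)
        m.valid[:] = False
        with pytest.raises(ez.EmptyMapError):
            ez.partial_attenuation_percent(m)

    @given(seed=st.integers(0, 10_000), thr=st.floats(0.0, 60.0))
    def test_total_below_partial_and_monotone_in_threshold(self, seed, thr):
        g = ez.CubeGeometry(n_fast=12, n_slow=8)
        m = random_map(g, np.random.default_rng(seed), invalid_fraction=0.1)
        total = ez.total_attenuation_percent(m)
        partial = ez.partial_attenuation_percent(m)
        at_thr = ez.partial_attenuation_percent(m, threshold_um=thr)
        assert total <= partial <= 100.0
        assert total <= at_thr <= ez.partial_attenuation_percent(m, 60.0)


class TestZoneMetrics:
    def test_uniform_mean(self, default_geometry):
        m = uniform_map(default_geometry, 40.4)
        assert ez.zone_mean_thickness(m, ez.ZoneSpec.central_subfield()) == \
            pytest.approx(40.4)

    def test_piecewise_map_mean_follows_mask_rule(self, default_geometry):
        g = default_geometry
        inside = g.fovea_distance_mm() <= 0.5
        grid = np.where(inside, 50.0, 30.0)
        m = ez.EZRPEMap(grid, np.ones(g.shape, bool), g)
        assert ez.zone_mean_thickness(m, ez.ZoneSpec.central_subfield()) == \
            pytest.approx(50.0)

    def test_all_zone_points_invalid_errors(self, default_geometry):
        m = uniform_map(default_geometry, 40.0)
        m.valid[ez.zone_mask(default_geometry, ez.ZoneSpec.central_subfield())] = False
        with pytest.raises(ez.EmptyMapError):
            ez.zone_mean_thickness(m, ez.ZoneSpec.central_subfield())

    def test_uniform_volumes_reproduce_reported_zone_volumes(self, default_geometry):
        """Cohort-mean thicknesses must yield the printed disc volumes."""
        csf = ez.zone_volume_mm3(uniform_map(default_geometry, 40.4),
                                 ez.ZoneSpec.central_subfield())
        para = ez.zone_volume_mm3(uniform_map(default_geometry, 36.8),
                                  ez.ZoneSpec.parafoveal())
        assert round(csf, 3) == 0.032
        assert round(para, 2) == 0.12

    def test_zero_map_zero_volume(self, default_geometry):
        assert ez.zone_volume_mm3(uniform_map(default_geometry, 0.0),
                                  ez.ZoneSpec.parafoveal()) == 0.0

    def test_disc_volume_converges_to_continuum_at_oversampling(self):
        g = ez.CubeGeometry(n_fast=2048, n_slow=512)
        vol = ez.zone_volume_mm3(uniform_map(g, 40.0), ez.ZoneSpec.parafoveal())
        assert vol == pytest.approx(0.040 * np.pi * 1.0 ** 2, rel=0.02)


class TestPointThickness:
    def test_uniform_map_any_offset(self, default_geometry):
        m = uniform_map(default_geometry, 39.1)
        for side in ("nasal", "temporal"):
            for offset in (0.5, 1.0):
                assert ez.point_thickness(m, offset, side) == pytest.approx(39.1)

    def test_linear_field_interpolates_exactly(self, default_geometry):
        g = default_geometry
        x = g.x_centers_mm()
        grid = 40.0 + 2.0 * np.broadcast_to(x, g.shape)
        m = ez.EZRPEMap(grid, np.ones(g.shape, bool), g)
        # OD: nasal = +x
        assert ez.point_thickness(m, 1.0, "nasal") == pytest.approx(42.0)
        assert ez.point_thickness(m, 1.0, "temporal") == pytest.approx(38.0)

    def test_laterality_mirrors_nasal(self):
        g = ez.CubeGeometry(laterality="OS")
        x = g.x_centers_mm()
        grid = 40.0 + 2.0 * np.broadcast_to(x, g.shape)
        m = ez.EZRPEMap(grid, np.ones(g.shape, bool), g)
        assert ez.point_thickness(m, 1.0, "nasal") == pytest.approx(38.0)

    def test_out_of_bounds_offset_errors(self, default_geometry):
        m = uniform_map(default_geometry, 40.0)
        with pytest.raises(ez.GeometryError):
            ez.point_thickness(m, 10.0, "nasal")

    def test_invalid_neighborhood_errors(self, default_geometry):
        m = uniform_map(default_geometry, 40.0)
        m.valid[:] = False
        m.valid[0, 0] = True
        with pytest.raises(ez.EmptyMapError):
            ez.point_thickness(m, 1.0, "nasal")


class TestComputeMetrics:
    def test_uniform_map_closed_forms(self, default_geometry):
        m = ez.compute_metrics(uniform_map(default_geometry, 40.0))
        assert m.partial_attenuation_pct == 0.0
        assert m.total_attenuation_pct == 0.0
        for name in ("csf_thickness_um", "csf_point_nasal_um",
                     "parafoveal_thickness_um", "parafoveal_point_temporal_um"):
            assert getattr(m, name) == pytest.approx(40.0)
        assert m.cube_volume_mm3 == pytest.approx(0.040 * 36.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_invariant_chain_on_random_maps(self, seed):
        g = ez.CubeGeometry(n_fast=48, n_slow=32)
        m = ez.compute_metrics(random_map(g, np.random.default_rng(seed)))
        assert 0 <= m.total_attenuation_pct <= m.partial_attenuation_pct <= 100
        assert m.csf_volume_mm3 <= m.parafoveal_volume_mm3 <= m.cube_volume_mm3

    def test_every_metric_matches_exhaustive_oracle(self, small_geometry, rng):
        """On a coarse grid, all vectorized metrics equal naive loops."""
        m = random_map(small_geometry, rng, invalid_fraction=0.15)
        got = ez.compute_metrics(m)
        assert got.partial_attenuation_pct == pytest.approx(
            partial_attenuation_loop(m, 20.0), rel=1e-9)
        assert got.total_attenuation_pct == pytest.approx(
            partial_attenuation_loop(m, 0.0), rel=1e-9)
        assert got.csf_thickness_um == pytest.approx(
            zone_mean_loop(m, 0.5), rel=1e-9)
        assert got.parafoveal_thickness_um == pytest.approx(
            zone_mean_loop(m, 1.0), rel=1e-9)
        assert got.csf_volume_mm3 == pytest.approx(
            zone_volume_loop(m, 0.5), rel=1e-9)
        assert got.parafoveal_volume_mm3 == pytest.approx(
            zone_volume_loop(m, 1.0), rel=1e-9)
        assert got.cube_volume_mm3 == pytest.approx(
            zone_volume_loop(m, None), rel=1e-9)
        fx, fy = small_geometry.fovea_xy_mm
        assert got.parafoveal_point_nasal_um == pytest.approx(
            bilinear_loop(m, fx + 1.0, fy), rel=1e-9)
        assert got.csf_point_temporal_um == pytest.approx(
            bilinear_loop(m, fx - 0.5, fy), rel=1e-9)
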