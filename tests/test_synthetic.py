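"""Synthetic field generator: determinism, closure, truths, limit cases."""

import dataclasses

import numpy as np
import pytest
from shapely.geometry import Point

from canopy_yield.grid import GridSpec, InvalidGridError
from canopy_yield.raster_ops import otsu_threshold
from canopy_yield.spectral import BandVector, compute_index
from canopy_yield.synthetic import (
    ScenarioConfig,
    YIELD_FLOOR,
    generate_field,
    latent_vigor,
    load_endmembers,
    make_harvest_points,
    make_reflectance_series,
    make_soil_terrain,
    mixing_weight,
)


def cfg(**kw) -> ScenarioConfig:
    base = dict(
        seed=1,
        grid=GridSpec(100, 100, 1.0),
        n_stages=2,
        canopy_cover_by_stage=(0.4, 0.6),
        stage_labels=("V9", "V14/VT"),
        daps=(64, 83),
    )
    base.update(kw)
    return ScenarioConfig(**base)


class TestConfigValidation:
    def test_invalid_grid_dimensions(self):
        with pytest.raises(InvalidGridError):
            GridSpec(0, 10, 1.0)

    def test_decreasing_canopy_cover_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            cfg(canopy_cover_by_stage=(0.6, 0.4))

    @pytest.mark.parametrize("kw", [{"yield_mean": -1.0}, {"yield_cv": 1.5}, {"nonlinearity": "cubic"}])
    def test_invalid_values_rejected(self, kw):
        with pytest.raises(ValueError):
            cfg(**kw)


class TestSoilTerrain:
    def test_seed_determinism_bit_identical(self):
        a = make_soil_terrain(cfg())
        b = make_soil_terrain(cfg())
        for name in ("sand", "silt", "clay", "om", "bd", "awc", "dem", "slope"):
            np.testing.assert_array_equal(
                getattr(a, name).values, getattr(b, name).values
            )

    def test_different_seeds_differ(self):
        a = make_soil_terrain(cfg(seed=1))
        b = make_soil_terrain(cfg(seed=2))
        assert not np.array_equal(a.sand.values, b.sand.values)

    def test_texture_closure(self):
        s = make_soil_terrain(cfg())
        total = s.sand.values + s.silt.values + s.clay.values
        np.testing.assert_allclose(total, 100.0, atol=1e-6)
        for r in (s.sand, s.silt, s.clay):
            assert (r.values >= 0).all() and (r.values <= 100).all()

    def test_relief_matches_target(self):
        s = make_soil_terrain(cfg(relief_m=8.0))
        assert s.dem.values.max() - s.dem.values.min() == pytest.approx(8.0, abs=0.01)
        s = make_soil_terrain(cfg(relief_m=3.0))
        assert s.dem.values.max() - s.dem.values.min() == pytest.approx(3.0, abs=0.01)

    def test_slope_nonnegative(self):
        s = make_soil_terrain(cfg())
        assert (s.slope.values >= 0).all()


class TestReflectance:
    def test_zero_cover_gives_pure_soil_spectrum(self):
        c = cfg(canopy_cover_by_stage=(0.0, 0.5), band_noise_sd=0.0)
        soil = make_soil_terrain(c)
        stacks = make_reflectance_series(soil, c)
        em = load_endmembers()["bare_soil"]
        for bname, raster in stacks[0].bands().items():
            np.testing.assert_allclose(raster.values, em[bname])

    def test_mixing_identity_at_healthy_endmember(self):
        """Mixing weight 1 reproduces the healthy endmember exactly, so its
        NDVIre equals the healthy endmember's NDVIre."""
        em = load_endmembers()
        m = 1.0
        mixed = {
            b: m * em["healthy_canopy"][b] + (1 - m) * em["stressed_canopy"][b]
            for b in ("red", "rededge")
        }
        got = compute_index("NDVIre", BandVector(red=mixed["red"], rededge=mixed["rededge"]))
        want = compute_index(
            "NDVIre",
            BandVector(red=em["healthy_canopy"]["red"], rededge=em["healthy_canopy"]["rededge"]),
        )
        assert got == pytest.approx(want, abs=1e-15)

    def test_mixing_weight_monotone_and_bounded(self):
        v = np.linspace(-4, 4, 101)
        m = mixing_weight(v)
        assert ((m > 0) & (m < 1)).all()
        assert (np.diff(m) > 0).all()

    def test_ndvire_bimodal_and_otsu_recovers_truth_mask(self):
        """At 50% cover the NDVIre histogram is bimodal; Otsu's threshold
        recovers the generator's stored canopy mask to >= 99% agreement."""
        c = cfg(canopy_cover_by_stage=(0.5, 0.6))
        soil = make_soil_terrain(c)
        stacks = make_reflectance_series(soil, c)
        stack = stacks[0]
        ndvire = compute_index(
            "NDVIre", BandVector(red=stack.red.values, rededge=stack.rededge.values)
        )
        thr = otsu_threshold(ndvire)
        recovered = (ndvire >= thr).astype(np.uint8)
        agreement = (recovered == stack.canopy_mask).mean()
        assert agreement >= 0.99
        # bimodality: both populations present and separated by the threshold
        assert 0.15 < thr < 0.42

    def test_cover_fraction_respected(self):
        c = cfg(canopy_cover_by_stage=(0.3, 0.7))
        soil = make_soil_terrain(c)
        stacks = make_reflectance_series(soil, c)
        for stack, cover in zip(stacks, (0.3, 0.7)):
            assert stack.canopy_mask.mean() == pytest.approx(cover, abs=0.02)

    def test_reflectance_in_unit_interval(self, small_field):
        for stack in small_field.stacks:
            for raster in stack.bands().values():
                assert (raster.values >= 0).all() and (raster.values <= 1).all()


class TestHarvestPoints:
    def test_zero_cv_degenerates_to_mean(self):
        c = cfg(yield_cv=0.0)
        soil = make_soil_terrain(c)
        pts, _ = make_harvest_points(soil, latent_vigor(soil, c), c)
        np.testing.assert_allclose(pts.yield_value, c.yield_mean)

    def test_sample_cv_tracks_configured_cv(self):
        c = ScenarioConfig(
            seed=1, grid=GridSpec(320, 320, 1.0), n_stages=1,
            canopy_cover_by_stage=(0.5,), stage_labels=("V9",), daps=(64,),
        )
        soil = make_soil_terrain(c)
        pts, _ = make_harvest_points(soil, latent_vigor(soil, c), c)
        assert pts.n >= 5000
        sample_cv = pts.yield_value.std() / pts.yield_value.mean()
        assert abs(sample_cv - c.yield_cv) / c.yield_cv < 0.2

    def test_points_strictly_inside_boundary(self, small_field):
        boundary = small_field.config.boundary
        for x, y in zip(small_field.points.x, small_field.points.y):
            assert boundary.contains(Point(x, y))

    def test_yield_floor_and_positivity(self, small_field):
        assert (small_field.points.yield_value >= YIELD_FLOOR).all()

    def test_truth_exposes_generating_coefficients(self, small_field):
        truth = small_field.truth
        assert set(truth["effective_coefficients"]) == {"vigor", "soil", "neg_slope"}
        assert set(truth["design"]) >= {"vigor", "soil", "neg_slope"}
        assert all(len(v) == small_field.points.n for v in truth["design"].values())

    def test_oversized_transect_spacing_errors(self):
        from canopy_yield.raster_ops import EmptyOutputError

        c = cfg(transect_spacing=500.0)
        soil = make_soil_terrain(c)
        with pytest.raises(EmptyOutputError):
            make_harvest_points(soil, latent_vigor(soil, c), c)


class TestFieldTruths:
    def test_full_dataset_determinism(self):
        a = generate_field(cfg())
        b = generate_field(cfg())
        np.testing.assert_array_equal(a.points.yield_value, b.points.yield_value)
        np.testing.assert_array_equal(a.vigor.values, b.vigor.values)
        for sa, sb in zip(a.stacks, b.stacks):
            np.testing.assert_array_equal(sa.nir.values, sb.nir.values)
            np.testing.assert_array_equal(sa.canopy_mask, sb.canopy_mask)

    def test_no_soil_pathway_leaves_no_partial_soil_correlation(self):
        """With soil and slope effects off, soil score explains nothing about
        yield beyond what vigor explains."""
        c = ScenarioConfig(
            seed=3, grid=GridSpec(200, 200, 1.0), n_stages=1,
            canopy_cover_by_stage=(0.5,), stage_labels=("V9",), daps=(64,),
            soil_effect_weight=0.0, slope_effect_weight=0.0,
        )
        soil = make_soil_terrain(c)
        vigor = latent_vigor(soil, c)
        pts, truth = make_harvest_points(soil, vigor, c)
        zv = truth["design"]["vigor"]
        zs = truth["design"]["soil"]
        y = pts.yield_value
        resid_y = y - np.polyval(np.polyfit(zv, y, 1), zv)
        resid_s = zs - np.polyval(np.polyfit(zv, zs, 1), zv)
        pc = np.corrcoef(resid_y, resid_s)[0, 1]
        assert abs(pc) < 0.1  # ~3x the 1/sqrt(n) sampling scale
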