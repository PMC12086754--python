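"""Voxel phantoms: geometry, density sampling, image noise, k-means labels."""

import numpy as np
import pytest

from pedrsp.exceptions import ValidationError
from pedrsp.phantom_synth import (
    DECT_NOISE_HU,
    GeometryPrimitive,
    build_geometric_phantom,
    assign_tissues_kmeans,
    rsp_maps,
    sample_densities,
    simulate_ct,
    simulate_dect,
)
from pedrsp.photon_model import water_composition
from pedrsp.reference_data import TissueComposition


@pytest.fixture(scope="module")
def water_comp():
    return water_composition().__class__(
        tissue_id=1, name="Water", mass_fractions={"H": 0.111894, "O": 0.888106},
        density=1.0,
    )


@pytest.fixture(scope="module")
def bone_comp(pipeline):
    t = next(t for t in __import__("pedrsp").adult70() if t.tissue_id == 56)
    return TissueComposition(tissue_id=2, name=t.name, mass_fractions=t.mass_fractions,
                             density=t.density)


@pytest.fixture()
def water_phantom(water_comp):
    prim = GeometryPrimitive("body", "cylinder", (24.0, 24.0, 24.0), (20.0, 20.0, 20.0), 1)
    return build_geometric_phantom([prim], {1: water_comp}, (24, 24, 24),
                                   (2.0, 2.0, 2.0), background_tissue_id=1)


class TestGeometry:
    def test_single_cylinder_all_water(self, water_phantom):
        assert set(np.unique(water_phantom.labels)) == {1}

    def test_nested_primitives_and_contours(self, water_comp, bone_comp):
        comps = {1: water_comp, 2: bone_comp}
        prims = [
            GeometryPrimitive("body", "cylinder", (32, 32, 32), (30, 30, 30), 1, priority=0),
            GeometryPrimitive("ring", "cylinder", (32, 32, 32), (20, 20, 30), 2, priority=1),
            GeometryPrimitive("target", "ellipsoid", (32, 32, 32), (8, 8, 8), 1, priority=2),
        ]
        ph = build_geometric_phantom(prims, comps, (32, 32, 32), (2.0, 2.0, 2.0),
                                     background_tissue_id=1)
        assert set(ph.contours) == {"body", "ring", "target"}
        # voxelized volumes approximate the analytic ones within discretization
        target_vox = ph.contours["target"].sum() * 8.0  # mm^3
        analytic = 4 / 3 * np.pi * 8**3
        assert target_vox == pytest.approx(analytic, rel=0.1)
        ring_labels = ph.labels[ph.contours["ring"] & ~ph.contours["target"]]
        assert set(np.unique(ring_labels)) == {2}

    def test_unknown_tissue_raises(self, water_comp):
        prim = GeometryPrimitive("x", "box", (1, 1, 1), (1, 1, 1), 99)
        with pytest.raises(ValidationError, match="unknown tissue"):
            build_geometric_phantom([prim], {1: water_comp}, (4, 4, 4), (1, 1, 1))

    def test_determinism(self, water_comp, bone_comp):
        comps = {1: water_comp, 2: bone_comp}
        prims = [GeometryPrimitive("b", "ellipsoid", (8, 8, 8), (6, 5, 4), 2)]
        a = build_geometric_phantom(prims, comps, (16, 16, 16), (1, 1, 1),
                                    background_tissue_id=1)
        b = build_geometric_phantom(prims, comps, (16, 16, 16), (1, 1, 1),
                                    background_tissue_id=1)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestDensitySampling:
    def test_zero_sd_returns_means(self, water_phantom):
        d = sample_densities(water_phantom, rel_sd=0.0)
        np.testing.assert_allclose(d, 1.0)

    def test_sample_sd_matches_request(self, water_phantom):
        d = sample_densities(water_phantom, seed=42)
        assert d.size >= 10_000
        assert np.std(d) == pytest.approx(0.017 / 3, rel=0.05)

    def test_all_samples_within_3sigma_band(self, water_phantom):
        d = sample_densities(water_phantom, seed=7)
        assert np.all(np.abs(d - 1.0) <= 0.017 + 1e-9)

    def test_seed_reproducibility(self, water_phantom):
        np.testing.assert_array_equal(
            sample_densities(water_phantom, seed=3),
            sample_densities(water_phantom, seed=3),
        )


class TestSimulateCT:
    def test_noiseless_water_is_zero(self, water_phantom, pipeline):
        img = simulate_ct(water_phantom, pipeline.spectrum("140kVp"), pipeline.xs,
                          noise_sd_hu=0.0)
        np.testing.assert_allclose(img.hu[0], 0.0, atol=1e-3)

    def test_noise_sd_close_to_7hu(self, water_phantom, pipeline):
        img = simulate_ct(water_phantom, pipeline.spectrum("140kVp"), pipeline.xs,
                          noise_sd_hu=7.0, seed=11)
        assert np.std(img.hu[0]) == pytest.approx(7.0, rel=0.05)

    def test_same_seed_same_image(self, water_phantom, pipeline):
        a = simulate_ct(water_phantom, pipeline.spectrum("140kVp"), pipeline.xs, seed=5)
        b = simulate_ct(water_phantom, pipeline.spectrum("140kVp"), pipeline.xs, seed=5)
        np.testing.assert_array_equal(a.hu[0], b.hu[0])

    def test_dect_pair_noise_levels(self, water_phantom, pipeline):
        img = simulate_dect(water_phantom, pipeline.spectrum("80kVp"),
                            pipeline.spectrum("140kVp-Sn"), pipeline.xs, seed=13)
        assert np.std(img.hu[0]) == pytest.approx(DECT_NOISE_HU[0], rel=0.05)
        assert np.std(img.hu[1]) == pytest.approx(DECT_NOISE_HU[1], rel=0.05)
        # channels are independent
        corr = np.corrcoef(img.hu[0].ravel(), img.hu[1].ravel())[0, 1]
        assert abs(corr) < 0.05


class TestKMeansAssignment:
    def test_single_candidate_fills_contour(self, water_phantom, water_comp, pipeline):
        img = simulate_ct(water_phantom, pipeline.spectrum("140kVp"), pipeline.xs, seed=1)
        mask = np.ones(water_phantom.shape, dtype=bool)
        labels = assign_tissues_kmeans(img.hu[0], mask, [water_comp],
                                       pipeline.spectrum("140kVp"), pipeline.xs, seed=0)
        assert set(np.unique(labels[mask])) == {1}

    def test_noiseless_two_region_exact_recovery(self, water_comp, bone_comp, pipeline):
        comps = {1: water_comp, 2: bone_comp}
        prims = [GeometryPrimitive("slab", "box", (8, 8, 12), (8, 8, 4), 2)]
        ph = build_geometric_phantom(prims, comps, (16, 16, 16), (1, 1, 1),
                                     background_tissue_id=1)
        img = simulate_ct(ph, pipeline.spectrum("140kVp"), pipeline.xs, noise_sd_hu=0.0)
        mask = np.ones(ph.shape, dtype=bool)
        labels = assign_tissues_kmeans(img.hu[0], mask, [water_comp, bone_comp],
                                       pipeline.spectrum("140kVp"), pipeline.xs, seed=0)
        np.testing.assert_array_equal(labels, ph.labels)

    def test_recovery_below_1pct_at_5x_noise_separation(self, pipeline, water_comp):
        # two materials separated by 5x the image noise in HU
        sp = pipeline.spectrum("140kVp")
        noise = 7.0
        dense = water_comp.with_density(1.0 + 5 * noise / 1000.0)  # +35 HU
        dense = TissueComposition(tissue_id=2, name="DenseWater",
                                  mass_fractions=dense.mass_fractions,
                                  density=dense.density)
        comps = {1: water_comp, 2: dense}
        prims = [GeometryPrimitive("slab", "box", (10, 10, 15), (10, 10, 5), 2)]
        ph = build_geometric_phantom(prims, comps, (20, 20, 20), (1, 1, 1),
                                     background_tissue_id=1)
        img = simulate_ct(ph, sp, pipeline.xs, noise_sd_hu=noise, seed=21)
        mask = np.ones(ph.shape, dtype=bool)
        labels = assign_tissues_kmeans(img.hu[0], mask, [water_comp, dense],
                                       sp, pipeline.xs, seed=0)
        error_rate = np.mean(labels != ph.labels)
        assert error_rate < 0.01

    def test_k_exceeding_distinct_values_raises(self, water_comp, bone_comp, pipeline):
        hu = np.zeros((4, 4, 4))
        with pytest.raises(ValidationError, match="distinct"):
            assign_tissues_kmeans(hu, np.ones_like(hu, bool), [water_comp, bone_comp],
                                  pipeline.spectrum("140kVp"), pipeline.xs, seed=0)

    def test_same_seed_same_assignment(self, water_comp, bone_comp, pipeline):
        rng = np.random.default_rng(0)
        hu = rng.normal(100.0, 150.0, (8, 8, 8))
        mask = np.ones_like(hu, bool)
        a = assign_tissues_kmeans(hu, mask, [water_comp, bone_comp],
                                  pipeline.spectrum("140kVp"), pipeline.xs, seed=4)
        b = assign_tissues_kmeans(hu, mask, [water_comp, bone_comp],
                                  pipeline.spectrum("140kVp"), pipeline.xs, seed=4)
        np.testing.assert_array_equal(a, b)


class TestRSPMaps:
    def test_noiseless_water_three_maps_unity(self, water_phantom, pipeline, ctx):
        sect = simulate_ct(water_phantom, pipeline.spectrum("140kVp"), pipeline.xs,
                           noise_sd_hu=0.0)
        dect = simulate_dect(water_phantom, pipeline.spectrum("80kVp"),
                             pipeline.spectrum("140kVp-Sn"), pipeline.xs,
                             noise_sd_hu=(0.0, 0.0))
        ref, s, d = rsp_maps(water_phantom, pipeline.conventional_curve,
                             pipeline.dect_model, sect, dect, ctx)
        np.testing.assert_allclose(ref, 1.0, atol=5e-3)
        # the SECT channel carries the fitted curve's water-point offset
        # (~2%: the soft segment is a compromise line over the adult organs)
        np.testing.assert_allclose(s, 1.0, atol=2.5e-2)
        np.testing.assert_allclose(d, 1.0, atol=5e-3)

    def test_reference_map_scales_with_density(self, water_phantom, pipeline, ctx):
        ph = water_phantom.with_density(water_phantom.density * 1.01)
        sect = simulate_ct(ph, pipeline.spectrum("140kVp"), pipeline.xs, 0.0)
        dect = simulate_dect(ph, pipeline.spectrum("80kVp"),
                             pipeline.spectrum("140kVp-Sn"), pipeline.xs, (0.0, 0.0))
        ref, _, _ = rsp_maps(ph, pipeline.conventional_curve, pipeline.dect_model,
                             sect, dect, ctx)
        np.testing.assert_allclose(ref, 1.01, rtol=1e-6)

    def test_sign_pattern_on_pediatric_phantom(self, pipeline, ctx):
        """Voxelwise errors repeat the per-tissue pattern: soft over-, bone under-estimated."""
        db = pipeline.pediatric_db("1y", "female")
        comps = {t.tissue_id: t for t in db}
        prims = [
            GeometryPrimitive("soft", "box", (8, 8, 6), (8, 8, 6), 41, priority=0),
            GeometryPrimitive("bone", "box", (8, 8, 18), (8, 8, 6), 2, priority=1),
        ]
        ph = build_geometric_phantom(prims, comps, (16, 16, 24), (1, 1, 1),
                                     background_tissue_id=41)
        sect = simulate_ct(ph, pipeline.spectrum("140kVp"), pipeline.xs, 0.0)
        dect = simulate_dect(ph, pipeline.spectrum("80kVp"),
                             pipeline.spectrum("140kVp-Sn"), pipeline.xs, (0.0, 0.0))
        ref, s, _ = rsp_maps(ph, pipeline.conventional_curve, pipeline.dect_model,
                             sect, dect, ctx)
        soft_mask = ph.labels == 41
        bone_mask = ph.labels == 2
        assert np.mean(s[soft_mask] - ref[soft_mask]) > 0
        assert np.mean(s[bone_mask] - ref[bone_mask]) < 0
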