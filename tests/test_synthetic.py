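"""Synthetic generators: fractions, determinism, ROI purity, closure."""

import numpy as np
import pytest

from sarforest import (
    CLASS_CODES,
    ClassSignature,
    build_stack,
    calibrate_dn_to_db,
    classify_scene,
    confusion_matrix,
    forest_connectivity,
    generate_class_mosaic,
    generate_forest_landscape,
    generate_rois,
    generate_scene,
    overall_accuracy,
    rasterize_rois,
)
from sarforest.synthetic import DEFAULT_SIGNATURES, LandscapeSpec


class TestClassMosaic:
    def test_single_class(self):
        spec = LandscapeSpec(shape=(50, 50), fractions={"forest": 1.0}, seed=1)
        grid = generate_class_mosaic(spec)
        assert np.all(grid == CLASS_CODES["forest"])

    def test_fractions_within_tolerance(self):
        spec = LandscapeSpec(
            shape=(200, 200),
            fractions={"water": 0.25, "forest": 0.25, "cropland": 0.25, "other": 0.25},
            seed=7,
        )
        grid = generate_class_mosaic(spec)
        for cname, frac in spec.fractions.items():
            realized = np.mean(grid == CLASS_CODES[cname])
            assert abs(realized - frac) <= 0.02

    def test_same_seed_identical(self):
        spec = LandscapeSpec(shape=(60, 60), seed=3)
        assert np.array_equal(generate_class_mosaic(spec), generate_class_mosaic(spec))

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            LandscapeSpec(fractions={"forest": 0.7, "water": 0.7})


class TestScene:
    def test_default_signatures_satisfy_their_rules(self):
        from sarforest import classify_pixel

        for label, sig in DEFAULT_SIGNATURES.items():
            diff = sig.mean_hh - sig.mean_hv
            ratio = sig.mean_hh / sig.mean_hv
            assert classify_pixel(sig.mean_hh, sig.mean_hv, diff, ratio) == CLASS_CODES[label]

    def test_tiny_noise_full_recovery(self):
        grid = np.full((30, 30), CLASS_CODES["forest"], dtype=np.uint8)
        scene, truth = generate_scene(grid, seed=2, sd=1e-6)
        lc = classify_scene(build_stack(scene))
        assert np.all(lc.classes == CLASS_CODES["forest"])

    def test_default_label_recovery(self):
        grid = generate_class_mosaic(LandscapeSpec(shape=(150, 150), seed=4))
        scene, truth = generate_scene(grid, seed=11, sd=0.3)
        lc = classify_scene(build_stack(scene))
        assert np.mean(lc.classes[truth > 0] == truth[truth > 0]) >= 0.99

    def test_dn_quantization_round_trip(self):
        # at forest-like levels a 1-DN rounding step is < 0.09 dB
        grid = np.full((40, 40), CLASS_CODES["forest"], dtype=np.uint8)
        scene, _ = generate_scene(grid, seed=8, sd=0.3)
        hh_db, _ = calibrate_dn_to_db(scene.hh_dn)
        rng = np.random.default_rng(8)
        drawn = rng.normal(-6.0, 0.3, int((grid > 0).sum()))
        assert np.max(np.abs(np.sort(hh_db.ravel()) - np.sort(drawn))) < 0.09

    def test_missing_signature_raises(self):
        grid = np.full((5, 5), CLASS_CODES["water"], dtype=np.uint8)
        with pytest.raises(ValueError, match="signature"):
            generate_scene(grid, signatures={"forest": DEFAULT_SIGNATURES["forest"]})

    def test_nodata_class_zero_gives_dn_zero(self):
        grid = np.zeros((4, 4), dtype=np.uint8)
        grid[0, 0] = CLASS_CODES["forest"]
        scene, _ = generate_scene(grid, seed=1)
        assert scene.hh_dn[1, 1] == 0
        assert not scene.valid_mask[1, 1]
        assert scene.valid_mask[0, 0]

    def test_determinism(self):
        grid = generate_class_mosaic(LandscapeSpec(shape=(40, 40), seed=5))
        s1, _ = generate_scene(grid, seed=9)
        s2, _ = generate_scene(grid, seed=9)
        assert np.array_equal(s1.hh_dn, s2.hh_dn)
        assert np.array_equal(s1.hv_dn, s2.hv_dn)

    def test_sd_must_be_positive(self):
        with pytest.raises(ValueError):
            ClassSignature("forest", -6, -11, sd=0.0)


class TestForestLandscape:
    def test_cover_extremes(self):
        assert np.all(generate_forest_landscape((20, 20), 1.0).mask == 1)
        assert np.all(generate_forest_landscape((20, 20), 0.0).mask == 0)

    def test_cover_within_tolerance_across_seeds(self):
        for seed in range(20):
            fm = generate_forest_landscape((100, 100), 0.37, clustering=2.0, seed=seed)
            assert abs(fm.mask.mean() - 0.37) <= 0.02

    def test_clustering_raises_connectivity(self):
        lo = generate_forest_landscape((150, 150), 0.5, clustering=0.0, seed=3)
        hi = generate_forest_landscape((150, 150), 0.5, clustering=5.0, seed=3)
        pff_lo = np.nanmean(forest_connectivity(lo, 9))
        pff_hi = np.nanmean(forest_connectivity(hi, 9))
        assert pff_hi > pff_lo

    def test_seed_reproducibility(self):
        a = generate_forest_landscape((50, 50), 0.5, 2.0, seed=3)
        b = generate_forest_landscape((50, 50), 0.5, 2.0, seed=3)
        assert np.array_equal(a.mask, b.mask)

    def test_cover_out_of_range(self):
        with pytest.raises(ValueError):
            generate_forest_landscape((10, 10), 1.5)


class TestROIs:
    def test_single_class_grid(self):
        grid = np.full((30, 30), CLASS_CODES["cropland"], dtype=np.uint8)
        rois = generate_rois(grid, n_per_class=4, seed=1)
        assert len(rois) == 4
        assert all(label == "cropland" for _, label, _ in rois.polygons)

    def test_minimum_area_honored(self):
        grid = generate_class_mosaic(LandscapeSpec(shape=(100, 100), seed=2))
        rois = generate_rois(grid, n_per_class=3, seed=5)
        for geom, _, _ in rois.polygons:
            assert geom.area >= 6 * 50 * 50  # ≥ 1.5 ha at 50-m pixels

    def test_rasterized_rois_are_pure(self):
        from sarforest import GridTransform

        grid = generate_class_mosaic(LandscapeSpec(shape=(100, 100), seed=2))
        rois = generate_rois(grid, n_per_class=3, seed=5)
        labels = rasterize_rois(rois, grid.shape, GridTransform())
        sel = labels > 0
        assert sel.any()
        assert np.array_equal(labels[sel], grid[sel])

    def test_missing_class_named_in_error(self):
        grid = np.full((20, 20), CLASS_CODES["forest"], dtype=np.uint8)
        grid[0, 0] = CLASS_CODES["water"]  # 1 pixel: no 6-pixel block
        with pytest.raises(ValueError, match="water"):
            generate_rois(grid, n_per_class=1, seed=1)


def test_full_pipeline_closure_near_diagonal():
    """scene → classify → validate against generated ROIs ≈ diagonal matrix."""
    from sarforest import GridTransform

    grid = generate_class_mosaic(LandscapeSpec(shape=(150, 150), seed=13))
    scene, _ = generate_scene(grid, seed=17, sd=0.3)
    lc = classify_scene(build_stack(scene))
    rois = generate_rois(grid, n_per_class=5, seed=19)
    ref = rasterize_rois(rois, grid.shape, GridTransform())
    cm = confusion_matrix(lc.classes, ref)
    off_diag = 1.0 - np.trace(cm.counts) / cm.total
    assert off_diag < 0.01
    assert overall_accuracy(cm) >= 99.0
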