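"""Image quantification: magnification, grid geometry, morphometry, masking."""

import numpy as np
import pytest

from chorodiurnal.experiments import flood_fill_components, full_frame_grid
from chorodiurnal.quantify import (
    EnFaceImage,
    GridGeometryError,
    MaskedBinaryMap,
    apply_vessel_mask,
    average_replicates,
    binarize,
    build_etdrs_grid,
    compute_correction_factor,
    correct_flow_deficit_size,
    flow_deficit_metrics,
    perfusion_density,
    register_sessions,
    FlowDeficitMetrics,
    PerfusionMetrics,
)
from chorodiurnal.synthetic import (
    generate_choriocapillaris_image,
    generate_deep_choroid_image,
)


def make_image(pixels, scan_mm=3.0, layer="choriocapillaris", **kw):
    return EnFaceImage(np.asarray(pixels, dtype=float), scan_mm, layer, **kw)


class TestCorrectionFactor:
    def test_reference_eye_gives_unity(self):
        assert compute_correction_factor(24.46).correction_factor == pytest.approx(1.0)

    def test_monotone_in_axial_length(self):
        f_short = compute_correction_factor(23.0).correction_factor
        f_long = compute_correction_factor(26.0).correction_factor
        assert f_short < 1.0 < f_long

    def test_linear_default_is_axial_length_ratio(self):
        f = compute_correction_factor(26.0).correction_factor
        assert f == pytest.approx(26.0 / 24.46, abs=1e-12)

    def test_reduced_eye_variant_unity_at_reference(self):
        m = compute_correction_factor(24.46, method="reduced_eye")
        assert m.correction_factor == pytest.approx(1.0)

    def test_out_of_band_biometry_rejected(self):
        with pytest.raises(ValueError):
            compute_correction_factor(19.0)
        with pytest.raises(ValueError):
            compute_correction_factor(31.0)


class TestCorrectedSize:
    @pytest.mark.parametrize(
        "size,factor,expected",
        [(100.0, 1.0, 100.0), (100.0, 1.1, 121.0), (0.0, 2.3, 0.0), (50.0, 0.9, 40.5)],
    )
    def test_size_scales_with_factor_squared(self, size, factor, expected):
        assert correct_flow_deficit_size(size, factor) == pytest.approx(expected)

    def test_negative_size_rejected(self):
        with pytest.raises(ValueError):
            correct_flow_deficit_size(-1.0, 1.0)


class TestETDRSGrid:
    def test_subfoveal_pixel_count_approximates_disk_area(self):
        # 512 px over 3 mm -> pitch 5.86 um; sub-foveal radius 500 um
        img = make_image(np.zeros((512, 512)))
        grid = build_etdrs_grid(img, 1.0)
        r_px = 500.0 / img.nominal_pixel_pitch_um
        analytic = np.pi * r_px**2
        counted = grid.zone_masks["sub_foveal"].sum()
        assert abs(counted - analytic) / analytic < 0.01

    def test_quadrants_partition_annulus_evenly(self):
        img = make_image(np.zeros((512, 512)))
        grid = build_etdrs_grid(img, 1.0)
        annulus = grid.zone_masks["sub_parafoveal"]
        counts = [
            (annulus & grid.quadrant_masks[qd]).sum()
            for qd in ("superior", "inferior", "nasal", "temporal")
        ]
        assert sum(counts) == annulus.sum()  # exact partition
        assert (max(counts) - min(counts)) / max(counts) < 0.01

    def test_magnification_shrinks_pixel_radii(self):
        img = make_image(np.zeros((512, 512)))
        g1 = build_etdrs_grid(img, 1.0)
        g2 = build_etdrs_grid(img, 1.1)
        for zone in g1.zone_radii_px:
            _, r1 = g1.zone_radii_px[zone]
            _, r2 = g2.zone_radii_px[zone]
            assert r2 == pytest.approx(r1 / 1.1)

    def test_zone_outside_image_raises(self):
        # a small correction factor inflates pixel radii past the image edge
        img = make_image(np.zeros((64, 64)))
        with pytest.raises(GridGeometryError):
            build_etdrs_grid(img, 0.5)
        # off-center fovea leaves too little room for the outer annulus
        off = make_image(np.zeros((64, 64)), fovea_center_px=(5.0, 32.0))
        with pytest.raises(GridGeometryError):
            build_etdrs_grid(off, 1.0)

    def test_scan_size_selects_zones(self):
        img3 = make_image(np.zeros((512, 512)), scan_mm=3.0)
        img6 = make_image(np.zeros((512, 512)), scan_mm=6.0)
        assert set(build_etdrs_grid(img3).zones) == {"sub_foveal", "sub_parafoveal"}
        assert set(build_etdrs_grid(img6).zones) == {"sub_perifoveal"}


class TestBinarize:
    def test_dark_disk_on_bright_field_is_foreground(self):
        pixels = np.full((128, 128), 200.0)
        rr, cc = np.mgrid[0:128, 0:128]
        disk = (rr - 64) ** 2 + (cc - 64) ** 2 <= 10**2
        pixels[disk] = 10.0
        bmap = binarize(make_image(pixels))
        assert bmap.foreground[disk].mean() > 0.95
        assert bmap.foreground[~disk].mean() < 0.01

    def test_constant_image_has_empty_foreground(self):
        bmap = binarize(make_image(np.full((64, 64), 37.0)))
        assert not bmap.foreground.any()

    def test_choriocapillaris_density_recovered_from_truth(self):
        img, truth = generate_choriocapillaris_image(
            width_px=256, height_px=256, deficit_count=40, seed=8
        )
        bmap = binarize(img)
        recovered = 100.0 * bmap.foreground.mean()
        assert abs(recovered - truth.true_density_percent) <= 1.5

    def test_deep_choroid_perfusion_recovered_from_truth(self):
        img, truth = generate_deep_choroid_image(
            target_perfusion_percent=50.0, seed=3
        )
        bmap = binarize(img)
        recovered = 100.0 * bmap.foreground.mean()
        assert abs(recovered - truth.perfusion_density_percent) <= 2.0


class TestVesselMask:
    def test_empty_mask_is_identity(self):
        img, _ = generate_choriocapillaris_image(deficit_count=10, seed=0)
        bmap = binarize(img)
        out = apply_vessel_mask(bmap, np.zeros(bmap.foreground.shape, dtype=bool))
        np.testing.assert_array_equal(out.foreground, bmap.foreground)
        np.testing.assert_array_equal(out.excluded, bmap.excluded)

    def test_full_mask_excludes_everything(self):
        img, _ = generate_choriocapillaris_image(deficit_count=10, seed=0)
        bmap = apply_vessel_mask(binarize(img), np.ones(img.pixels.shape, dtype=bool))
        assert not bmap.foreground.any()
        grid = full_frame_grid(img.pixels.shape)
        m = flow_deficit_metrics(bmap, grid, "frame", 1.0)
        assert m.missing and "zone_fully_excluded" in m.flags

    def test_masked_density_matches_brute_force(self, rng):
        shape = (64, 64)
        fg = rng.random(shape) < 0.2
        vessels = rng.random(shape) < 0.3
        bmap = apply_vessel_mask(
            MaskedBinaryMap(fg, np.zeros(shape, dtype=bool)), vessels
        )
        grid = full_frame_grid(shape)
        m = flow_deficit_metrics(bmap, grid, "frame", 1.0)
        expected = 100.0 * (fg & ~vessels).sum() / (~vessels).sum()
        assert m.density_percent == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        img, _ = generate_choriocapillaris_image(deficit_count=1, seed=0)
        with pytest.raises(ValueError):
            apply_vessel_mask(binarize(img), np.zeros((8, 8), dtype=bool))


class TestRegistration:
    def test_identity_registration(self):
        img, _ = generate_choriocapillaris_image(deficit_count=10, seed=2)
        res = register_sessions(img, img)
        assert (res.dx_px, res.dy_px) == (0.0, 0.0)
        assert res.confidence > 0.99 and res.ok

    def test_pure_noise_pair_flagged(self, rng):
        a = make_image(rng.normal(128, 30, (128, 128)))
        b = make_image(rng.normal(128, 30, (128, 128)))
        res = register_sessions(a, b)
        assert not res.ok

    def test_mismatched_layers_rejected(self):
        a = make_image(np.zeros((64, 64)), layer="choriocapillaris")
        b = make_image(np.zeros((64, 64)), layer="deep_choroid")
        with pytest.raises(ValueError):
            register_sessions(a, b)


class TestFlowDeficitMetrics:
    def test_toy_grid_oracle(self):
        # 8x8 map with a 3-px L-blob and a 2-px pair, pixel area 100 um^2
        fg = np.zeros((8, 8), dtype=bool)
        fg[1, 1] = fg[1, 2] = fg[2, 1] = True  # 3 px
        fg[5, 5] = fg[5, 6] = True  # 2 px
        bmap = MaskedBinaryMap(fg, np.zeros((8, 8), dtype=bool))
        grid = full_frame_grid((8, 8))
        m = flow_deficit_metrics(bmap, grid, "frame", pixel_area_um2=100.0)
        assert m.count == 2
        assert m.mean_size_um2 == pytest.approx(250.0)
        assert m.density_percent == pytest.approx(5 / 64 * 100)

    def test_empty_foreground(self):
        bmap = MaskedBinaryMap(np.zeros((8, 8), bool), np.zeros((8, 8), bool))
        m = flow_deficit_metrics(bmap, full_frame_grid((8, 8)), "frame", 1.0)
        assert m.count == 0 and m.density_percent == 0.0 and m.mean_size_um2 is None

    def test_all_foreground_density_is_100(self):
        bmap = MaskedBinaryMap(np.ones((8, 8), bool), np.zeros((8, 8), bool))
        m = flow_deficit_metrics(bmap, full_frame_grid((8, 8)), "frame", 1.0)
        assert m.density_percent == pytest.approx(100.0)
        assert m.count == 1

    def test_diagonal_pixels_are_one_deficit(self):
        fg = np.zeros((8, 8), dtype=bool)
        fg[2, 2] = fg[3, 3] = True  # touching only diagonally: 8-connected
        bmap = MaskedBinaryMap(fg, np.zeros((8, 8), bool))
        m = flow_deficit_metrics(bmap, full_frame_grid((8, 8)), "frame", 1.0)
        assert m.count == 1

    def test_random_maps_agree_with_flood_fill(self, rng):
        grid = full_frame_grid((64, 64))
        for _ in range(50):
            fg = rng.random((64, 64)) < 0.15
            bmap = MaskedBinaryMap(fg, np.zeros((64, 64), bool))
            m = flow_deficit_metrics(bmap, grid, "frame", 1.0)
            comps = flood_fill_components(fg)
            assert m.count == len(comps)
            assert m.density_percent == pytest.approx(
                100.0 * sum(len(c) for c in comps) / 4096, abs=1e-12
            )

    def test_end_to_end_count_recovery_on_synthetic_image(self):
        img, truth = generate_choriocapillaris_image(
            width_px=256, height_px=256, deficit_count=12,
            deficit_size_range_um2=(800.0, 2000.0), seed=6,
        )
        bmap = binarize(img)
        grid = full_frame_grid(img.pixels.shape)
        m = flow_deficit_metrics(
            bmap, grid, "frame", img.nominal_pixel_area_um2, min_size_px=3
        )
        assert m.count == truth.deficit_count


class TestPerfusionDensity:
    def test_half_foreground_is_50(self):
        fg = np.zeros((8, 8), bool)
        fg[:4] = True
        bmap = MaskedBinaryMap(fg, np.zeros((8, 8), bool))
        p = perfusion_density(bmap, full_frame_grid((8, 8)), "frame")
        assert p.density_percent == pytest.approx(50.0)

    def test_zero_foreground_is_0(self):
        bmap = MaskedBinaryMap(np.zeros((8, 8), bool), np.zeros((8, 8), bool))
        p = perfusion_density(bmap, full_frame_grid((8, 8)), "frame")
        assert p.density_percent == 0.0

    def test_synthetic_image_matches_truth_within_2_points(self):
        img, truth = generate_deep_choroid_image(target_perfusion_percent=45.0, seed=9)
        p = perfusion_density(binarize(img), full_frame_grid(img.pixels.shape), "frame")
        assert abs(p.density_percent - truth.perfusion_density_percent) <= 2.0


class TestAverageReplicates:
    def test_arithmetic_mean_per_field(self):
        a = PerfusionMetrics(10.0, "sub_foveal")
        b = PerfusionMetrics(12.0, "sub_foveal")
        assert average_replicates(a, b).density_percent == pytest.approx(11.0)

    def test_idempotent_on_equal_replicates(self):
        a = FlowDeficitMetrics(5, 100.0, 3.0, "sub_foveal")
        out = average_replicates(a, a)
        assert (out.count, out.mean_size_um2, out.density_percent) == (5, 100.0, 3.0)

    def test_non_integer_session_count_permitted(self):
        a = FlowDeficitMetrics(272, 100.0, 3.0, "sub_foveal")
        b = FlowDeficitMetrics(273, 110.0, 3.2, "sub_foveal")
        assert average_replicates(a, b).count == pytest.approx(272.5)

    def test_single_replicate_flagged(self):
        a = PerfusionMetrics(10.0, "sub_foveal")
        b = PerfusionMetrics(None, "sub_foveal", flags=("zone_fully_excluded",))
        out = average_replicates(a, b)
        assert out.density_percent == 10.0
        assert "single_replicate" in out.flags

    def test_both_missing_stays_missing(self):
        a = PerfusionMetrics(None, "sub_foveal")
        out = average_replicates(a, a)
        assert out.missing and "both_missing" in out.flags
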