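import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scopeloop import (
    AffineMap,
    BenchModel,
    CalibrationError,
    CalibrationParams,
    FrameSpec,
    IlluminableRegion,
    VirtualBench,
    calibrate,
    detect_illuminable_region,
    estimate_magnification,
    estimate_zone_positions,
    fit_affine,
    measure_grid_magnification,
    place_scan_zones,
    random_bench,
    run_axis_scan,
    scan_zone_breadth,
    scan_zone_breadth_combined,
)
from scopeloop.calibration import (
    ScanProfile,
    ScanZone,
    scan_zone_breadth_combined_raw,
    scan_zone_breadth_raw,
)

from conftest import SMALL_CAMERA, frame_grid

positive = st.floats(1e-3, 1e3, allow_nan=False, allow_infinity=False)


def square_region(lo=0, hi=100):
    mask = np.zeros((hi + 30, hi + 30), bool)
    mask[lo : hi + 1, lo : hi + 1] = True
    return IlluminableRegion.from_mask(mask)


class TestMagnification:
    def test_equal_ratios_give_unity(self):
        assert estimate_magnification(10, 3, 10, 3) == pytest.approx(1.0)

    def test_formula(self):
        assert estimate_magnification(G_p=10, g_p=2, G_c=10, g_c=4) == pytest.approx(2.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="G_c"):
            estimate_magnification(10, 2, 0, 4)

    def test_grid_measurement_recovers_pure_scale(self):
        # projector->camera scale 3: the measured projected-grid pitch vs
        # the reference grid must recover M within 10%
        scale = 3.0
        proj = FrameSpec(128, 72, "projector")
        cam = SMALL_CAMERA
        gt = AffineMap.from_linear(
            np.eye(2) * scale, (0.0, 0.0), source="projector", target="camera"
        )
        bench = VirtualBench(BenchModel(
            ground_truth_map=gt, camera=cam, projector=proj,
            background_level=10.0, noise_sigma=1.0, blur_sigma=0.5, rng_seed=2,
        ))
        region = detect_illuminable_region(bench, 200, 50)
        M, pitch = measure_grid_magnification(bench, region, 200)
        assert M == pytest.approx(scale, rel=0.10)
        assert np.isfinite(pitch)


class TestScanZoneBreadth:
    def test_doubling_and_odd_rounding(self):
        assert scan_zone_breadth(10, 1.0) == 21  # 2*10 -> next odd
        assert scan_zone_breadth(1, 0.5) == 1

    def test_combined_equals_composed_raw(self):
        # sizing rule written in one shot equals magnification-then-double
        a = scan_zone_breadth_combined_raw(10, G_p=32, g_p=1, G_c=16, g_c=1)
        b = scan_zone_breadth_raw(10, estimate_magnification(32, 1, 16, 1))
        assert a == pytest.approx(b, rel=1e-12)
        assert scan_zone_breadth_combined(10, 32, 1, 16, 1) == 41

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(l_p=st.integers(1, 50), G_p=positive, g_p=positive, G_c=positive,
           g_c=positive)
    def test_combined_identity_property(self, l_p, G_p, g_p, G_c, g_c):
        direct = scan_zone_breadth_combined_raw(l_p, G_p, g_p, G_c, g_c)
        composed = scan_zone_breadth_raw(
            l_p, estimate_magnification(G_p, g_p, G_c, g_c)
        )
        assert abs(direct - composed) <= 1e-12 * max(abs(direct), 1e-300)


class TestPlaceScanZones:
    def test_b_zero_centres_on_bbox_border(self):
        zones = place_scan_zones(square_region(), b=0.0, s_c=11)
        centres = sorted(z.centre for z in zones)
        assert centres == [(0, 0), (0, 100), (100, 0), (100, 100)]

    def test_b_one_zones_mutually_adjacent_at_centre(self):
        zones = place_scan_zones(square_region(), b=1.0, s_c=10)
        centres = sorted(z.centre for z in zones)
        assert centres == [(45, 45), (45, 55), (55, 45), (55, 55)]

    def test_b_one_third_interpolation(self):
        zones = place_scan_zones(square_region(), b=1.0 / 3.0, s_c=10)
        centres = sorted(z.centre for z in zones)
        # per-axis offset = (2/3)*50 + (1/3)*5 = 35 from the centre at 50
        assert np.allclose(centres, [(15, 15), (15, 85), (85, 15), (85, 85)])

    def test_border_distance_monotone_in_b(self):
        prev = None
        for b in np.linspace(0, 1, 11):
            zones = place_scan_zones(square_region(), b=b, s_c=5)
            d = min(min(z.centre) for z in zones)  # distance from bbox corner
            if prev is not None:
                assert d >= prev - 1e-9
            prev = d

    def test_region_too_small_raises(self):
        with pytest.raises(CalibrationError, match="too small"):
            place_scan_zones(square_region(hi=10), b=1.0, s_c=31)

    def test_zones_nudged_into_mask(self):
        # circular region: bbox corners are outside the disk
        yy, xx = np.mgrid[0:121, 0:121]
        mask = (xx - 60) ** 2 + (yy - 60) ** 2 <= 55**2
        region = IlluminableRegion.from_mask(mask)
        zones = place_scan_zones(region, b=0.0, s_c=9)
        frame = __import__("scopeloop").FrameSpec(121, 121, "camera")
        for z in zones:
            ys, xs = z.slices(frame)
            assert mask[ys, xs].any()  # zone square reaches illuminated pixels


class TestAxisScan:
    def identity_bench(self, **kw):
        proj = FrameSpec(SMALL_CAMERA.width, SMALL_CAMERA.height, "projector")
        defaults = dict(
            ground_truth_map=AffineMap.identity("projector", "camera"),
            camera=SMALL_CAMERA, projector=proj, background_level=0.0,
        )
        defaults.update(kw)
        return VirtualBench(BenchModel(**defaults))

    def test_identity_band_containing_zone_peaks(self):
        bench = self.identity_bench()
        zones = [ScanZone(centre=(105.0, 80.0), breadth=21)]
        profile = run_axis_scan(bench, "columns", 10, zones)
        assert int(np.argmax(profile.intensities[0])) == 10  # cols 100-109

    def test_zone_outside_footprint_is_flat_and_flagged(self):
        bench = self.identity_bench(illum_coverage=0.25)
        inside = ScanZone(centre=(SMALL_CAMERA.width / 2, SMALL_CAMERA.height / 2), breadth=21)
        outside = ScanZone(centre=(5.0, 5.0), breadth=9)
        cols = run_axis_scan(bench, "columns", 10, [inside, outside])
        rows = run_axis_scan(bench, "rows", 10, [inside, outside])
        assert cols.intensities[1].max() < 1.0
        # the flat zone is excluded with a warning, leaving too few zones
        with pytest.warns(UserWarning, match="excluded"), \
                pytest.raises(CalibrationError, match="usable"):
            estimate_zone_positions(cols, rows, 10)

    def test_banded_argmax_matches_single_column_oracle(self):
        # brute-force oracle: illuminate one projector column at a time
        gt = AffineMap.similarity(
            1.3, 6.0, (25.0, -10.0), source="projector", target="camera"
        )
        proj = FrameSpec(160, 120, "projector")
        bench = VirtualBench(BenchModel(
            ground_truth_map=gt, camera=SMALL_CAMERA, projector=proj,
            background_level=0.0,
        ))
        l_p = 10
        zones = [ScanZone(centre=tuple(gt.apply([(60.0, 55.0)])[0]), breadth=27)]
        profile = run_axis_scan(bench, "columns", l_p, zones)
        band_star = int(np.argmax(profile.intensities[0]))

        col_response = []
        for c in range(proj.width):
            pattern = np.zeros(proj.shape, np.float32)
            pattern[:, c] = 200.0
            img = bench.capture(pattern).astype(float)
            ys, xs = zones[0].slices(bench.camera)
            col_response.append(img[ys, xs].mean())
        col_star = int(np.argmax(col_response))
        assert abs((band_star + 0.5) * l_p - (col_star + 0.5)) <= l_p


class TestEstimateZonePositions:
    def profile(self, intensities, axis="columns"):
        return ScanProfile(axis=axis, band_breadth=10,
                           intensities=np.asarray(intensities, float),
                           dark_noise_mad=0.0)

    def test_one_hot_profile(self):
        # a single responding band localises to that band's central pixel
        # coordinate: band 3 covers columns 30..39, centre 34.5
        cols = self.profile([[0, 0, 0, 5, 0, 0]])
        rows = self.profile([[5, 0, 0, 0, 0, 0]], axis="rows")
        for mode in ("halfmass", "centroid", "argmax"):
            pos, kept = estimate_zone_positions(cols, rows, 10, mode=mode)
            assert pos[0] == (34.5, 4.5)
            assert kept == [0]

    def test_symmetric_tie_gives_band_boundary(self):
        # equal responses in bands 3 and 4 -> the shared edge of columns
        # 39 and 40, i.e. 39.5
        cols = self.profile([[0, 0, 0, 5, 5, 0]])
        rows = self.profile([[5, 0, 0, 0, 0, 0]], axis="rows")
        for mode in ("halfmass", "centroid"):
            pos, _ = estimate_zone_positions(cols, rows, 10, mode=mode)
            assert pos[0][0] == pytest.approx(39.5)

    def test_argmax_mode_breaks_ties_low(self):
        cols = self.profile([[0, 0, 0, 5, 5, 0]])
        rows = self.profile([[5, 0, 0, 0, 0, 0]], axis="rows")
        pos, _ = estimate_zone_positions(cols, rows, 10, mode="argmax")
        assert pos[0][0] == 34.5

    def test_halfmass_exact_for_offset_box_aperture(self):
        # 21-wide aperture of columns 50..70: responses 10, 10, 1 across
        # bands 5-7; the half-mass point recovers the true centre 60 exactly
        cols = self.profile([[0, 0, 0, 0, 0, 10, 10, 1]])
        rows = self.profile([[0, 10, 10, 1, 0, 0, 0, 0]], axis="rows")
        pos, _ = estimate_zone_positions(cols, rows, 10)
        assert pos[0] == pytest.approx((60.0, 20.0))

    def test_positions_match_ground_truth_mapping(self):
        # estimated projector positions within l_p/2 of the true mapped centres
        model = random_bench(17)
        model.noise_sigma, model.blur_sigma = 0.5, 0.5
        bench = VirtualBench(model)
        region = detect_illuminable_region(bench, 200, 50)
        M = model.ground_truth_map.mean_scale
        s_c = scan_zone_breadth(10, M)
        zones = place_scan_zones(region, 1 / 3, s_c)
        cols = run_axis_scan(bench, "columns", 10, zones)
        rows = run_axis_scan(bench, "rows", 10, zones)
        pos, kept = estimate_zone_positions(cols, rows, 10)
        inv = model.ground_truth_map.inverse()
        for i, p in zip(kept, pos):
            truth = inv.apply([zones[i].centre])[0]
            assert np.linalg.norm(np.array(p) - truth) < 5.0


class TestDetectIlluminableRegion:
    def test_half_frame_footprint(self):
        cam = FrameSpec(200, 100, "camera")
        proj = FrameSpec(100, 100, "projector")
        bench = VirtualBench(BenchModel(
            ground_truth_map=AffineMap.identity("projector", "camera"),
            camera=cam, projector=proj, background_level=0.0,
        ))
        region = detect_illuminable_region(bench, 200, 100)
        assert region.bbox == (0, 0, 99, 99)
        assert region.mask[:, :100].all()
        assert not region.mask[:, 100:].any()

    def test_threshold_above_brightness_errors_with_max_diff(self):
        cam = FrameSpec(100, 100, "camera")
        bench = VirtualBench(BenchModel(
            ground_truth_map=AffineMap.identity("projector", "camera"),
            camera=cam, projector=cam, background_level=0.0,
        ))
        with pytest.raises(CalibrationError, match="max observed difference"):
            detect_illuminable_region(bench, brightness=100, threshold=200)

    def test_partial_coverage_area_matches_polygon_oracle(self):
        import shapely.geometry as sg

        model = random_bench(23, noise_sigma_max=0.0, blur_sigma_max=0.0)
        model.illum_coverage = 0.6
        bench = VirtualBench(model)
        region = detect_illuminable_region(bench, 200, 50)
        # oracle: projector quad warped by the ground truth, clipped to the
        # camera frame and the coverage rectangle
        cam, proj = model.camera, model.projector
        quad = sg.Polygon(model.ground_truth_map.apply(proj.corners()))
        frame = sg.box(-0.5, -0.5, cam.width - 0.5, cam.height - 0.5)
        cx, cy = cam.center
        hw = cam.width * np.sqrt(0.6) / 2
        hh = cam.height * np.sqrt(0.6) / 2
        cover = sg.box(cx - hw, cy - hh, cx + hw, cy + hh)
        expected = quad.intersection(frame).intersection(cover).area
        assert region.area == pytest.approx(expected, rel=0.05)


class TestFitAffine:
    def test_identity_pairs(self):
        pairs = [((0, 0), (0, 0)), ((10, 0), (10, 0)), ((0, 10), (0, 10)),
                 ((10, 10), (10, 10))]
        res = fit_affine(pairs)
        assert res.map.isclose(AffineMap.identity())
        assert res.residual == pytest.approx(0.0, abs=1e-12)

    def test_three_point_translation(self):
        pairs = [((0, 0), (5, 7)), ((4, 0), (9, 7)), ((0, 3), (5, 10))]
        res = fit_affine(pairs)
        assert res.map.isclose(AffineMap.translation(5, 7), atol=1e-9)

    def test_recovers_random_affine_and_matches_skimage_oracle(self):
        from skimage.transform import estimate_transform

        rng = np.random.default_rng(4)
        true = AffineMap(rng.normal(size=(2, 3)) + np.array([[1., 0, 0], [0, 1., 0]]))
        src = rng.uniform(0, 300, size=(4, 2))
        dst = true.apply(src)
        res = fit_affine(list(zip(map(tuple, src), map(tuple, dst))))
        assert np.allclose(res.map.matrix, true.matrix, atol=1e-6)
        assert res.residual < 1e-9
        oracle = estimate_transform("affine", src, dst)
        assert np.allclose(res.map.as_homogeneous(), oracle.params, atol=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(CalibrationError, match="degenerate"):
            fit_affine([((0, 0), (0, 0)), ((1, 1), (1, 1))])
        collinear = [((i, 2.0 * i), (i, i)) for i in range(4)]
        with pytest.raises(CalibrationError, match="collinear"):
            fit_affine(collinear)


class TestCalibratePipeline:
    def test_identity_bench_recovers_identity(self, identity_bench):
        res = calibrate(identity_bench, CalibrationParams(M=1.0))
        pts = frame_grid(identity_bench.camera)
        err = np.linalg.norm(res.map.apply(pts) - pts, axis=1)
        assert err.max() < 0.1

    def test_threshold_error_names_first_stage(self, identity_bench):
        params = CalibrationParams(brightness=50.0, threshold=200.0)
        with pytest.raises(CalibrationError, match="detect_illuminable_region"):
            calibrate(identity_bench, params)

    def test_warped_noisy_bench_recovered_within_2px(self):
        # translation + 5 deg rotation + scale 1.3, blur 1 px, noise sigma 2
        cam = SMALL_CAMERA
        proj = FrameSpec(330, 190, "projector")
        gt = AffineMap.similarity(
            1.3, 5.0, (20.0, -12.0), center=proj.center,
            source="projector", target="camera",
        )
        gt = AffineMap(gt.matrix + np.array([[0, 0, cam.center[0] - proj.center[0]],
                                             [0, 0, cam.center[1] - proj.center[1]]]),
                       "projector", "camera")
        bench = VirtualBench(BenchModel(
            ground_truth_map=gt, camera=cam, projector=proj,
            blur_sigma=1.0, noise_sigma=2.0, background_level=15.0, rng_seed=5,
        ))
        res = calibrate(bench)
        pts = frame_grid(cam)
        err = np.linalg.norm(res.map.apply(pts) - gt.inverse().apply(pts), axis=1)
        assert err.mean() < 2.0

    def test_result_serialisation_round_trip(self, identity_bench, tmp_path):
        res = calibrate(identity_bench, CalibrationParams(M=1.0))
        path = tmp_path / "calibration.json"
        res.save(path)
        loaded = type(res).load(path)
        assert loaded.map.isclose(res.map)
        assert loaded.residual == pytest.approx(res.residual)
        assert len(loaded.correspondences) == len(res.correspondences)

    def test_interactive_mode_drives_batch_pipeline(self, identity_bench):
        answers = iter([
            "200",   # brightness
            "50",    # threshold
            "y",     # accept region
            "0.333", # b
            "10",    # l_p
            "y",     # enter grid observations
            "32",    # G_p
            "32",    # G_c
            "1.0",   # g_c
            "1.0",   # g_p
        ])
        echoed = []
        res = calibrate(
            identity_bench, CalibrationParams(),
            interactive=True,
            input_fn=lambda prompt: next(answers, ""),
            echo=echoed.append,
        )
        pts = frame_grid(identity_bench.camera)
        err = np.linalg.norm(res.map.apply(pts) - pts, axis=1)
        assert err.max() < 0.1
        assert any("illuminable region" in str(m) for m in echoed)
        assert any("magnification" in str(m) for m in echoed)
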