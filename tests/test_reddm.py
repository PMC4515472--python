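import numpy as np
import pytest

from gutquant.imaging import ChannelStack, ImagePlane
from gutquant.reddm import (
    CellClassReport,
    NoTissueError,
    NucleusRecord,
    SegmentationParams,
    assign_cell_classes,
    classify_ploidy,
    count_spots,
    detect_gut_area,
    measure_diameter,
    quantify_gut,
    segment_nuclei,
)
from gutquant.synth import SceneParams, generate_scene


def make_record(area_um2, label=1):
    return NucleusRecord(
        label=label, centroid=(0.0, 0.0), area_um2=area_um2, mean_intensity={}
    )


class TestDetectGutArea:
    def test_band_scene_iou(self):
        params = SceneParams(noise_sd_fraction=0.0, background_gradient=0.0)
        scene, stack = generate_scene(params, "virgin", seed=3)
        mask = detect_gut_area(stack, SegmentationParams())
        iou = (mask & scene.gut_mask).sum() / (mask | scene.gut_mask).sum()
        assert iou >= 0.95
        # single connected component
        from scipy import ndimage as ndi

        assert ndi.label(mask)[1] == 1

    def test_full_frame_tissue(self):
        stack = ChannelStack({"DAPI": np.full((1, 64, 64), 0.3)}, 0.5)
        assert detect_gut_area(stack, SegmentationParams()).all()

    def test_all_zero_raises(self):
        stack = ChannelStack({"DAPI": np.zeros((1, 32, 32))}, 0.5)
        with pytest.raises(NoTissueError):
            detect_gut_area(stack, SegmentationParams())


class TestSegmentNuclei:
    def test_recovers_disjoint_disks(self, disk_image):
        rng = np.random.default_rng(4)
        centres = [(r, c) for r in range(20, 120, 33) for c in range(20, 120, 33)]
        radii = rng.uniform(5, 8, len(centres))
        px_size = 0.5
        img = disk_image((128, 128), centres, radii)
        plane = ImagePlane(img, px_size, "DAPI")
        records = segment_nuclei(
            plane, np.ones((128, 128), bool), SegmentationParams(smoothing_sigma_px=0)
        )
        assert len(records) == len(centres)
        found_areas = sorted(r.area_um2 for r in records)
        expected = sorted(np.pi * (radii * px_size) ** 2)
        np.testing.assert_allclose(found_areas, expected, rtol=0.10)

    def test_blank_plane_returns_empty(self):
        plane = ImagePlane(np.zeros((32, 32)), 0.5, "DAPI")
        with pytest.warns(UserWarning):
            records = segment_nuclei(plane, np.ones((32, 32), bool), SegmentationParams())
        assert records == []

    def test_split_touching_toggle(self, disk_image):
        img = disk_image((64, 64), [(32, 24), (32, 40)], [9, 9])
        plane = ImagePlane(img, 1.0, "DAPI")
        mask = np.ones((64, 64), bool)
        split = segment_nuclei(
            plane, mask, SegmentationParams(split_touching=True, smoothing_sigma_px=0)
        )
        merged = segment_nuclei(
            plane, mask, SegmentationParams(split_touching=False, smoothing_sigma_px=0)
        )
        assert len(split) == 2
        assert len(merged) == 1

    def test_labels_are_contiguous(self, disk_image):
        img = disk_image((96, 96), [(20, 20), (50, 50), (80, 80)], [6, 6, 6])
        plane = ImagePlane(img, 1.0, "DAPI")
        records = segment_nuclei(plane, np.ones((96, 96), bool), SegmentationParams())
        assert [r.label for r in records] == list(range(1, len(records) + 1))


class TestClassifyPloidy:
    def test_fixed_threshold_rule(self):
        records = [make_record(a, i) for i, a in enumerate((20.0, 25.0, 400.0))]
        out = classify_ploidy(
            records, SegmentationParams(ploidy_area_threshold_um2=100.0)
        )
        assert [r.ploidy for r in out] == ["diploid", "diploid", "polyploid"]

    def test_all_below_threshold(self):
        records = [make_record(a, i) for i, a in enumerate((10.0, 20.0, 30.0))]
        out = classify_ploidy(
            records, SegmentationParams(ploidy_area_threshold_um2=100.0)
        )
        assert all(r.ploidy == "diploid" for r in out)

    def test_auto_needs_four_nuclei(self):
        records = [make_record(a, i) for i, a in enumerate((10.0, 400.0))]
        with pytest.raises(ValueError, match="explicitly"):
            classify_ploidy(records, SegmentationParams())

    def test_auto_split_on_bimodal_mixture(self):
        rng = np.random.default_rng(9)
        diploid = np.pi * np.clip(rng.normal(2.5, 0.25, 100), 0.5, None) ** 2
        polyploid = np.pi * np.clip(rng.normal(6.0, 0.6, 100), 0.5, None) ** 2
        records = [make_record(a, i) for i, a in enumerate(np.r_[diploid, polyploid])]
        out = classify_ploidy(records, SegmentationParams())
        truth = ["diploid"] * 100 + ["polyploid"] * 100
        agree = np.mean([r.ploidy == t for r, t in zip(out, truth)])
        assert agree >= 0.98


class TestAssignCellClasses:
    def _example_scene(self):
        # fixed composition: 10 pre-existing ECs, 5 progenitors, 3 new ECs
        params = SceneParams(
            noise_sd_fraction=0.0,
            background_gradient=0.0,
            deterministic_counts=True,
            class_means={
                "preexisting_ec": 10,
                "preexisting_diploid": 0,
                "progenitor": 5,
                "new_ec": 3,
                "new_eec": 0,
            },
        )
        return generate_scene(params, "virgin", seed=21)

    def test_example_report_counts(self):
        scene, stack = self._example_scene()
        _, report = quantify_gut(stack)
        assert report.n_total_nuclei == 18
        assert report.n_ec == 13
        assert report.n_rfp == 8
        assert report.n_gfp == 5
        assert report.n_new_progeny == 3
        assert report.n_anomalous_gfp_only == 0

    def test_blank_channels_everything_preexisting(self):
        scene, stack = self._example_scene()
        blank = np.zeros_like(stack.channels["RFP"])
        stack2 = ChannelStack(
            {"DAPI": stack.channels["DAPI"], "RFP": blank, "GFP": blank.copy()},
            stack.pixel_size_um,
        )
        records, report = quantify_gut(stack2)
        assert report.n_rfp == 0 and report.n_gfp == 0
        assert all(r.cell_class == "preexisting" for r in records)

    def test_every_nucleus_gets_one_class(self):
        scene, stack = generate_scene(SceneParams(seed=13), "mated", seed=13)
        records, report = quantify_gut(stack)
        assert all(r.cell_class in ("progenitor", "new_progeny", "preexisting")
                   for r in records)
        by_class = sum(
            sum(1 for r in records if r.cell_class == c)
            for c in ("progenitor", "new_progeny", "preexisting")
        )
        assert by_class == report.n_total_nuclei
        assert report.n_new_progeny == report.n_rfp - report.n_gfp >= 0

    def test_report_invariant_validation(self):
        with pytest.raises(ValueError):
            CellClassReport(
                n_total_nuclei=5, n_ec=1, n_rfp=2, n_gfp=3,
                n_new_progeny=-1, gut_area_um2=1.0, density_per_mm2=1.0,
            )


class TestMeasureDiameter:
    def test_horizontal_band(self):
        mask = np.zeros((100, 100), bool)
        mask[30:70, :] = True
        assert measure_diameter(mask, 2.0) == 80.0

    def test_circle_diameter(self, disk_image):
        mask = disk_image((120, 120), [(60, 60)], [50]).astype(bool)
        d = measure_diameter(mask, 1.0)
        assert 99.0 <= d <= 101.0

    def test_band_missing_centre_raises(self):
        mask = np.zeros((100, 100), bool)
        mask[10:20, 0:30] = True  # stops left of the centre column
        with pytest.raises(ValueError, match="re-centre"):
            measure_diameter(mask, 1.0)


class TestCountSpots:
    def test_disjoint_bright_disks(self, disk_image):
        img = disk_image((128, 128), [(20 + 15 * i, 20 + 13 * i) for i in range(7)],
                         [4] * 7)
        plane = ImagePlane(img, 1.0, "PH3")
        assert count_spots(plane, np.ones((128, 128), bool), SegmentationParams()) == 7

    def test_blank_plane(self):
        plane = ImagePlane(np.zeros((64, 64)), 1.0, "PH3")
        assert count_spots(plane, np.ones((64, 64), bool), SegmentationParams()) == 0

    def test_seeded_spot_scene(self, disk_image):
        rng = np.random.default_rng(17)
        n = 9
        centres = []
        while len(centres) < n:
            cand = tuple(rng.uniform(12, 116, 2))
            if all(np.hypot(cand[0] - r, cand[1] - c) > 14 for r, c in centres):
                centres.append(cand)
        img = disk_image((128, 128), centres, [3.5] * n, amplitude=5.0)
        img = img + rng.normal(0, 1.0, img.shape)  # SNR 5
        plane = ImagePlane(np.clip(img, 0, None), 1.0, "PH3")
        assert count_spots(plane, np.ones((128, 128), bool), SegmentationParams()) == n


class TestDensityInvariance:
    def test_density_stable_under_pixel_size_change(self):
        common = dict(
            noise_sd_fraction=0.0,
            background_gradient=0.0,
            deterministic_counts=True,
        )
        fine = SceneParams(field_size_px=512, pixel_size_um=0.5, **common)
        coarse = SceneParams(field_size_px=256, pixel_size_um=1.0, **common)
        _, stack_f = generate_scene(fine, "virgin", seed=8)
        _, stack_c = generate_scene(coarse, "virgin", seed=8)
        _, rep_f = quantify_gut(stack_f)
        _, rep_c = quantify_gut(stack_c)
        assert rep_c.density_per_mm2 == pytest.approx(rep_f.density_per_mm2, rel=0.05)
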