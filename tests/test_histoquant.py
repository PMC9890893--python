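"""Image quantification: area fractions, particles, skeletons, neighborhoods."""

import numpy as np
import pandas as pd
import pytest

from trem2quant import histoquant as hq
from trem2quant import synthdata as sd
from trem2quant.histoquant import ImagePlane, RoiMask


def separated_plaque_scene(seed=0, n_large=10, n_small=5, size=300.0, px=0.5):
    """Well-separated disks on a grid: n_large of 12 um, n_small of 5 um."""
    plaques = []
    spots = [(30 + 55 * (i % 5), 40 + 55 * (i // 5)) for i in range(n_large)]
    plaques += [{"center_um": c, "diameter_um": 12.0} for c in spots]
    plaques += [{"center_um": (30 + 55 * i, 250), "diameter_um": 5.0}
                for i in range(n_small)]
    return sd.gen_scene(size, px, plaques=plaques, seed=seed)


class TestAreaFraction:
    def test_all_below_threshold_is_zero(self):
        plane = ImagePlane(np.full((50, 50), 0.2), 1.0)
        assert hq.area_fraction(plane, RoiMask.full(plane), 0.5) == 0.0

    def test_half_roi_above_threshold(self):
        img = np.zeros((40, 40))
        img[:20] = 1.0
        plane = ImagePlane(img, 1.0)
        assert hq.area_fraction(plane, RoiMask.full(plane), 0.5) == pytest.approx(50.0)

    def test_planted_coverage_recovered(self):
        scene, gt = separated_plaque_scene()
        plane, roi = scene["channels"]["plaque"], scene["roi"]
        true_pct = 100 * gt.params["plaques"]["area_um2"].sum() / roi.area_um2
        assert hq.area_fraction(plane, roi, 0.5) == pytest.approx(true_pct, abs=0.2)

    def test_restricted_roi_only_counts_inside(self):
        img = np.zeros((40, 40))
        img[:, :] = 1.0
        mask = np.zeros((40, 40), bool)
        mask[:10, :10] = True
        plane = ImagePlane(img, 1.0)
        assert hq.area_fraction(plane, RoiMask(mask, 1.0), 0.5) == pytest.approx(100.0)


class TestDetectParticles:
    def test_diameter_filter_keeps_only_large_plaques(self):
        scene, _ = separated_plaque_scene()
        _, summ = hq.detect_particles(scene["channels"]["plaque"], scene["roi"], 0.5)
        assert summ["count"] == 10

    def test_raising_min_diameter_empties_the_table(self):
        scene, _ = separated_plaque_scene()
        _, summ = hq.detect_particles(scene["channels"]["plaque"], scene["roi"], 0.5,
                                      min_diameter_um=13.0)
        assert summ["count"] == 0

    def test_density_times_area_equals_count(self):
        scene, _ = separated_plaque_scene()
        _, summ = hq.detect_particles(scene["channels"]["plaque"], scene["roi"], 0.5)
        assert summ["density_per_mm2"] * scene["roi"].area_um2 / 1e6 == \
            pytest.approx(summ["count"])

    def test_random_separated_scenes_counted_exactly(self):
        """Counts equal ground truth on random non-overlapping disk scenes."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            centers = [(25 + 50 * (i % 4) + rng.uniform(-8, 8),
                        25 + 50 * (i // 4) + rng.uniform(-8, 8)) for i in range(12)]
            plaques = [{"center_um": c, "diameter_um": float(rng.uniform(9, 14))}
                       for c in centers]
            scene, gt = sd.gen_scene(220, 0.5, plaques=plaques, seed=seed)
            _, summ = hq.detect_particles(scene["channels"]["plaque"],
                                          scene["roi"], 0.5)
            assert summ["count"] == len(gt.params["plaques"])

    def test_monotone_in_threshold_and_diameter(self):
        scene, _ = separated_plaque_scene(seed=3)
        plane, roi = scene["channels"]["plaque"], scene["roi"]
        fracs = [hq.area_fraction(plane, roi, th) for th in (0.2, 0.5, 0.8)]
        assert fracs == sorted(fracs, reverse=True)
        counts = [hq.detect_particles(plane, roi, 0.5, min_diameter_um=d)[1]["count"]
                  for d in (4, 8, 11, 13)]
        assert counts == sorted(counts, reverse=True)

    def test_empty_roi_not_constructible(self):
        with pytest.raises(ValueError):
            RoiMask(np.zeros((10, 10), bool), 1.0)


class TestSomata:
    def test_density_counts_per_mm2(self):
        mg = [{"soma_center_um": (100 + 200 * (i % 4), 150 + 200 * (i // 4)),
               "soma_diameter_um": 10.0, "branches": []} for i in range(12)]
        scene, _ = sd.gen_scene(1000.0, 2.0, microglia=mg)  # 1 mm^2 ROI
        res = hq.microglia_somata(scene["channels"]["microglia"], 0.5)
        assert res["count"] == 12
        assert res["density_per_mm2"] == pytest.approx(12.0)

    def test_empty_scene_density_zero(self):
        scene, _ = sd.gen_scene(100, 1.0)
        res = hq.microglia_somata(scene["channels"]["microglia"], 0.5)
        assert res["density_per_mm2"] == 0.0

    def test_soma_areas_match_planted_disks(self):
        errs = []
        for seed in range(25):
            rng = np.random.default_rng(seed)
            mg = [{"soma_center_um": (20 + 35 * (i % 3) + rng.uniform(-4, 4),
                                      25 + 40 * (i // 3) + rng.uniform(-4, 4)),
                   "soma_diameter_um": float(rng.uniform(7, 12)), "branches": []}
                  for i in range(6)]
            scene, gt = sd.gen_scene(120, 0.5, microglia=mg, seed=seed)
            res = hq.microglia_somata(scene["channels"]["microglia"], 0.5)
            errs.append(res["mean_soma_area_um2"]
                        / gt.params["microglia"]["soma_area_um2"].mean() - 1)
        assert np.max(np.abs(errs)) < 0.05


class TestSkeleton:
    def test_straight_bar(self):
        scene, _ = sd.gen_scene(60, 0.5, microglia=[{
            "soma_center_um": (20.0, 30.0), "soma_diameter_um": 2.0,
            "branches": [[(20.0, 30.0), (40.0, 30.0)]]}])
        rec = hq.skeleton_morphometry(scene["channels"]["microglia"], 0.2)
        assert len(rec) == 1
        assert rec.loc[0, "branch_count"] == 1
        assert rec.loc[0, "junction_count"] == 0
        assert rec.loc[0, "total_branch_length_um"] == pytest.approx(20.0, abs=1.0)

    def test_cross_of_four_arms(self):
        c = (50.0, 50.0)
        scene, _ = sd.gen_scene(100, 0.5, microglia=[{
            "soma_center_um": c, "soma_diameter_um": 2.0,
            "branches": [[c, (70.0, 50.0)], [c, (30.0, 50.0)],
                         [c, (50.0, 70.0)], [c, (50.0, 30.0)]]}])
        rec = hq.skeleton_morphometry(scene["channels"]["microglia"], 0.2)
        assert rec.loc[0, "branch_count"] == 4
        assert rec.loc[0, "junction_count"] == 1
        # tolerance: one pixel per arm
        assert rec.loc[0, "total_branch_length_um"] == pytest.approx(80.0, abs=4 * 0.5)

    def test_planted_trees_branch_counts_and_lengths(self):
        """Random planted star-shaped cells: branch counts exact; total
        length within the digital-geometry bound for (1, sqrt 2) step
        weights: an 8-connected chain overestimates a straight segment by
        at most cos(22.5) + (sqrt 2 - 1) sin(22.5) - 1 = 8.2%, plus about
        one pixel per arm of endpoint quantization."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            c = np.array([60.0, 60.0]) + rng.uniform(-10, 10, 2)
            k = int(rng.integers(3, 6))
            thetas = np.linspace(0, 2 * np.pi, k, endpoint=False) + rng.uniform(0, 0.4)
            branches = [[tuple(c), tuple(c + rng.uniform(15, 25)
                                         * np.array([np.cos(th), np.sin(th)]))]
                        for th in thetas]
            scene, gt = sd.gen_scene(120, 0.5, microglia=[{
                "soma_center_um": tuple(c), "soma_diameter_um": 2.0,
                "branches": branches}], seed=seed)
            rec = hq.skeleton_morphometry(scene["channels"]["microglia"], 0.2)
            truth = gt.params["microglia"].iloc[0]
            assert rec.loc[0, "branch_count"] == truth["branch_count"]
            true_len = truth["total_branch_length_um"]
            measured = rec.loc[0, "total_branch_length_um"]
            bound = 1.082 * true_len + truth["branch_count"] * 0.5
            assert 0.95 * true_len <= measured <= bound

    def test_no_foreground_gives_empty_record(self):
        scene, _ = sd.gen_scene(50, 1.0)
        rec = hq.skeleton_morphometry(scene["channels"]["microglia"], 0.5)
        assert rec.empty


class TestNeighborhood:
    def scene_with_somata_at(self, dists, radius_scene=200.0):
        plaque = {"center_um": (100.0, 100.0), "diameter_um": 12.0}
        mg = [{"soma_center_um": (100.0 + d, 100.0), "soma_diameter_um": 8.0,
               "branches": []} for d in dists]
        return sd.gen_scene(radius_scene, 0.5, plaques=[plaque], microglia=mg)

    def test_counts_somata_within_radius(self):
        scene, _ = self.scene_with_somata_at([10.0, 20.0, 40.0])
        nb = hq.plaque_neighborhood(scene["channels"]["plaque"],
                                    scene["channels"]["microglia"], 30.0,
                                    plaque_threshold=0.5, microglia_threshold=0.3,
                                    soma_threshold=0.5)
        assert len(nb) == 1
        assert nb.loc[0, "microglia_count"] == 2

    def test_no_microglia_flags_coverage(self):
        scene, _ = self.scene_with_somata_at([])
        nb = hq.plaque_neighborhood(scene["channels"]["plaque"],
                                    scene["channels"]["microglia"], 30.0,
                                    plaque_threshold=0.5, microglia_threshold=0.3)
        assert nb.loc[0, "microglia_count"] == 0
        assert np.isnan(nb.loc[0, "coverage_per_microglion_um2"])
        assert nb.loc[0, "flag"]

    def test_counts_match_brute_force_distance_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            plaques = [{"center_um": tuple(rng.uniform(30, 170, 2)),
                        "diameter_um": 12.0} for _ in range(3)]
            mg = [{"soma_center_um": tuple(rng.uniform(10, 190, 2)),
                   "soma_diameter_um": 8.0, "branches": []} for _ in range(8)]
            scene, gt = sd.gen_scene(200, 0.5, plaques=plaques, microglia=mg,
                                     seed=seed)
            nb = hq.plaque_neighborhood(
                scene["channels"]["plaque"], scene["channels"]["microglia"], 30.0,
                plaque_threshold=0.5, microglia_threshold=0.3, soma_threshold=0.5)
            # brute force on the planted geometry (O(n^2) distances)
            pc = gt.params["plaques"][["center_x_um", "center_y_um"]].to_numpy()
            sc = gt.params["microglia"][["soma_x_um", "soma_y_um"]].to_numpy()
            order = np.argsort(nb["centroid_x_um"].to_numpy(), kind="stable")
            truth_order = np.argsort(pc[:, 0], kind="stable")
            for row_i, true_i in zip(order, truth_order):
                d = np.hypot(*(sc - pc[true_i]).T)
                assert nb.loc[row_i, "microglia_count"] == int((d <= 30.0).sum())


class TestColocalization:
    def test_identical_masks_fraction_one(self):
        img = np.zeros((60, 60))
        img[10:40, 10:40] = 1.0
        p = ImagePlane(img, 1.0)
        res = hq.colocalized_area(p, p, thresholds=(0.5, 0.5))
        assert res["fraction"] == 1.0

    def test_disjoint_masks_fraction_zero(self):
        a = np.zeros((60, 60)); a[:20] = 1.0
        b = np.zeros((60, 60)); b[40:] = 1.0
        res = hq.colocalized_area(ImagePlane(a, 1.0), ImagePlane(b, 1.0),
                                  thresholds=(0.5, 0.5))
        assert res["fraction"] == 0.0
        assert res["area_um2"] == 0.0

    def test_planted_overlap_fraction(self):
        """Rectangles overlapping 30% of their union, fixed thresholds."""
        a = np.zeros((100, 100)); b = np.zeros((100, 100))
        a[0:20, 0:65] = 1.0          # 1300 px
        b[0:20, 35:100] = 1.0        # 1300 px; overlap 20 x 30 = 600, union 2000
        res = hq.colocalized_area(ImagePlane(a, 1.0), ImagePlane(b, 1.0),
                                  thresholds=(0.5, 0.5))
        assert res["fraction"] == pytest.approx(0.30, abs=0.01)

    def test_auto_threshold_on_constant_channel_errors(self):
        p = ImagePlane(np.ones((30, 30)), 1.0)
        with pytest.raises(ValueError, match="constant"):
            hq.colocalized_area(p, p)

    def test_auto_threshold_recovers_correlated_overlap(self):
        rng = np.random.default_rng(0)
        base = np.zeros((80, 80))
        base[20:60, 20:60] = 1.0
        a = base + rng.normal(0, 0.05, base.shape) + 0.2
        b = 0.8 * base + rng.normal(0, 0.05, base.shape) + 0.1
        res = hq.colocalized_area(ImagePlane(np.clip(a, 0, None), 1.0),
                                  ImagePlane(np.clip(b, 0, None), 1.0))
        assert 0.5 < res["fraction"] <= 1.0


class TestGeometricInvariance:
    def test_translation_and_rotation_invariance(self):
        scene, _ = separated_plaque_scene(seed=5)
        plane, roi = scene["channels"]["plaque"], scene["roi"]
        base_frac = hq.area_fraction(plane, roi, 0.5)
        base_count = hq.detect_particles(plane, roi, 0.5)[1]["count"]
        rot = ImagePlane(np.rot90(plane.data).copy(), plane.pixel_size_um)
        roi_rot = RoiMask(np.rot90(roi.mask).copy(), roi.pixel_size_um)
        assert hq.area_fraction(rot, roi_rot, 0.5) == pytest.approx(base_frac)
        assert hq.detect_particles(rot, roi_rot, 0.5)[1]["count"] == base_count
        shifted = ImagePlane(np.roll(plane.data, (7, 11), axis=(0, 1)),
                             plane.pixel_size_um)
        assert hq.area_fraction(shifted, roi, 0.5) == pytest.approx(base_frac)


def test_tiff_roundtrip(tmp_path):
    scene, _ = separated_plaque_scene(seed=1)
    sd.write_scene(scene, tmp_path)
    back = hq.read_plane(tmp_path / "plaque.tiff", tmp_path / "plaque.yaml")
    assert back.pixel_size_um == scene["channels"]["plaque"].pixel_size_um
    np.testing.assert_allclose(back.data, scene["channels"]["plaque"].data,
                               atol=1e-6)
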