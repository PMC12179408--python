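"""Synthetic generator: geometry oracles, determinism, population bookkeeping."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cardiomorph.synth import (CellSpec, GROUP_PARAMS, calibrated_depth_ratio,
                               capsule_area, capsule_spheroid_volume,
                               largest_remainder_counts, place_population,
                               render_cuboid_stack, render_scene, render_stack,
                               sample_population)


class TestRenderScene:
    def test_single_rod_area_matches_analytic_capsule(self):
        spec = CellSpec("intact_rod", 137.81, 28.53, orientation_deg=25.0,
                        center_um=(120.0, 100.0))
        scene = render_scene((320, 320), 0.65, [spec], noise_sd=0.0, seed=0)
        labels = np.unique(scene.label_map)
        assert list(labels) == [0, 1]
        drawn = (scene.label_map == 1).sum() * 0.65 ** 2
        assert drawn == pytest.approx(capsule_area(137.81, 28.53), rel=0.03)

    def test_empty_spec_list_gives_blank_scene(self):
        scene = render_scene((64, 64), 0.65, [], noise_sd=0.0, seed=0)
        assert scene.truth == []
        assert not scene.label_map.any()
        assert not scene.image.pixels.any()

    def test_same_seed_renders_bit_identically(self):
        spec = CellSpec("intact_rod", 120.0, 25.0, orientation_deg=77.0,
                        center_um=(100.0, 100.0), sarcomere_period_um=1.8)
        a = render_scene((300, 300), 0.65, [spec], noise_sd=0.1, seed=5)
        b = render_scene((300, 300), 0.65, [spec], noise_sd=0.1, seed=5)
        assert np.array_equal(a.image.pixels, b.image.pixels)
        assert np.array_equal(a.label_map, b.label_map)

    def test_overlap_ties_go_to_lower_index(self):
        s1 = CellSpec("rounded", 40.0, 40.0, center_um=(50.0, 50.0))
        s2 = CellSpec("rounded", 40.0, 40.0, center_um=(65.0, 50.0))
        scene = render_scene((160, 160), 0.65, [s1, s2], noise_sd=0.0, seed=0)
        # pixels inside both discs belong to label 1
        yy, xx = np.mgrid[:160, :160]
        x_um, y_um = (xx + 0.5) * 0.65, (yy + 0.5) * 0.65
        both = (((x_um - 50) ** 2 + (y_um - 50) ** 2 <= 20 ** 2)
                & ((x_um - 65) ** 2 + (y_um - 50) ** 2 <= 20 ** 2))
        assert (scene.label_map[both] == 1).all()

    def test_touching_pair_is_one_label_with_overlapping_capsules(self):
        spec = CellSpec("touching_pair", 100.0, 25.0, orientation_deg=10.0,
                        center_um=(120.0, 80.0), pair_length_um=90.0,
                        pair_width_um=22.0, pair_overlap_um=4 * 0.65)
        scene = render_scene((320, 320), 0.65, [spec], noise_sd=0.0, seed=0)
        assert scene.label_map.max() == 1
        area = (scene.label_map == 1).sum() * 0.65 ** 2
        # union of the two capsules, minus the overlap sliver
        assert area < capsule_area(100, 25) + capsule_area(90, 22)
        assert area > capsule_area(100, 25) + 0.5 * capsule_area(90, 22)

    def test_edge_cell_is_flagged_clipped(self):
        inside = CellSpec("rounded", 40.0, 40.0, center_um=(100.0, 100.0))
        at_edge = CellSpec("rounded", 40.0, 40.0, center_um=(3.0, 100.0))
        scene = render_scene((320, 320), 0.65, [inside, at_edge],
                             noise_sd=0.0, seed=0)
        assert scene.clipped == [False, True]

    def test_nonpositive_pixel_size_rejected(self):
        with pytest.raises(ValueError, match="pixel_size"):
            render_scene((64, 64), 0.0, [], seed=0)


class TestSamplePopulation:
    def test_exact_class_composition(self):
        specs = sample_population("control", 100,
                                  {"intact_rod": 0.97, "rounded": 0.03},
                                  seed=0)
        classes = [s.cell_class for s in specs]
        assert classes.count("intact_rod") == 97
        assert classes.count("rounded") == 3

    def test_single_cell_population(self):
        specs = sample_population("control", 1, {"intact_rod": 1.0}, seed=0)
        assert len(specs) == 1
        assert specs[0].cell_class == "intact_rod"

    def test_mean_length_recovers_generator_parameters(self):
        specs = sample_population("control", 2000, {"intact_rod": 1.0}, seed=0)
        lengths = np.array([s.length_um for s in specs])
        se = 33.06 / np.sqrt(2000)
        assert abs(lengths.mean() - 139.42) < 3 * se

    def test_geometric_invariants_hold(self):
        specs = sample_population(
            "old", 400, {"intact_rod": 0.5, "touching_pair": 0.2,
                         "rounded": 0.2, "fragment": 0.1}, seed=3)
        for s in specs:
            assert s.width_um >= 5.0 or s.cell_class == "fragment"
            assert s.length_um >= s.width_um
            if s.cell_class == "rounded":
                assert s.length_um == s.width_um
                assert s.sarcomere_period_um is None
            if s.cell_class == "fragment":
                assert capsule_area(s.length_um, s.width_um) < 4 * 500.0

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            sample_population("control", 10, {"intact_rod": 0.5}, seed=0)
        with pytest.raises(ValueError, match="negative"):
            sample_population({"length_um": (-1.0, 1.0),
                               "width_um": (20.0, 1.0)}, 10,
                              {"intact_rod": 1.0}, seed=0)

    @given(n=st.integers(1, 500),
           p=st.floats(0.01, 0.99))
    def test_largest_remainder_is_exact_and_total_preserving(self, n, p):
        counts = largest_remainder_counts(
            n, {"intact_rod": p, "rounded": 1.0 - p})
        assert sum(counts.values()) == n
        assert counts["intact_rod"] in (int(np.floor(n * p)),
                                        int(np.floor(n * p)) + 1)


class TestRenderStack:
    def test_cuboid_truth_volume_is_exact(self):
        scene = render_cuboid_stack((20, 10, 5), (0.5, 0.5, 1.0))
        assert scene.truth_volumes_um3[0] == pytest.approx(250.0)
        count = (scene.stack > 0.5).sum()
        assert count * 0.25 == pytest.approx(250.0)

    def test_stack_rendering_is_deterministic(self):
        spec = CellSpec("intact_rod", 140.0, 30.0, orientation_deg=20.0,
                        sarcomere_period_um=1.8)
        a = render_stack(spec, (0.5, 0.5, 1.0), seed=4, noise_sd=0.02)
        b = render_stack(spec, (0.5, 0.5, 1.0), seed=4, noise_sd=0.02)
        assert np.array_equal(a.stack, b.stack)

    def test_voxel_count_matches_analytic_volume(self):
        spec = CellSpec("intact_rod", 140.0, 30.0, orientation_deg=20.0)
        scene = render_stack(spec, (0.5, 0.5, 1.0), depth_ratio=0.5)
        count = (scene.stack > 0.5).sum()
        analytic = capsule_spheroid_volume(140.0, 30.0, 0.5)
        assert count * 0.25 == pytest.approx(analytic, rel=0.05)
        assert scene.truth_volumes_um3[0] == pytest.approx(analytic)

    def test_depth_ratio_calibration_matches_group_volume(self):
        # expected population volume under the calibrated ratio equals the
        # group target (checked by Monte Carlo on the generator itself)
        specs = sample_population("control", 4000, {"intact_rod": 1.0}, seed=9)
        vols = [capsule_spheroid_volume(s.length_um, s.width_um, s.depth_ratio)
                for s in specs]
        target = GROUP_PARAMS["control"]["volume_um3"][0]
        assert np.mean(vols) == pytest.approx(target, rel=0.05)

    def test_bad_inputs_rejected(self):
        spec = CellSpec("intact_rod", 100.0, 20.0)
        with pytest.raises(ValueError, match="voxel"):
            render_stack(spec, (0.5, -1.0, 1.0))
        with pytest.raises(ValueError, match="depth_slices"):
            render_stack(spec, (0.5, 0.5, 1.0), depth_slices=2)


class TestPlacement:
    def test_no_two_placed_cells_overlap(self):
        specs = sample_population("control", 30, {"intact_rod": 1.0}, seed=2)
        fields = place_population(specs, (1024, 1024), 0.65,
                                  cells_per_field=15, seed=3)
        assert sum(len(f) for f in fields) == 30
        for fspecs in fields:
            scene = render_scene((1024, 1024), 0.65, fspecs, noise_sd=0.0,
                                 seed=0)
            drawn = (scene.label_map > 0).sum() * 0.65 ** 2
            total = sum(capsule_area(s.length_um, s.width_um) for s in fspecs)
            assert drawn == pytest.approx(total, rel=0.03)
            assert not any(scene.clipped)
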