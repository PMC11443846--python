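import csv
import json

import numpy as np
import pytest

from fociquant import (
    AnalysisParams,
    GrayImage,
    generate_scene,
    ground_truth_records,
    quantify_pair,
    render_scene,
    simulate,
)
from fociquant.errors import PlacementError
from fociquant.synth import disk_offsets, ellipse_mask


class TestGenerateScene:
    def test_empty_scene_renders_blank(self):
        scene = generate_scene(0, seed=1)
        marker, damage = render_scene(scene)
        assert (marker == scene.background_level).all()
        assert (damage == scene.background_level).all()
        assert ground_truth_records(scene) == []

    def test_same_seed_reproduces_scene_and_render(self):
        a = generate_scene(5, noise_sigma=4.0, seed=42)
        b = generate_scene(5, noise_sigma=4.0, seed=42)
        assert a == b
        ma, da = render_scene(a)
        mb, db = render_scene(b)
        assert (ma == mb).all() and (da == db).all()

    def test_different_seeds_differ(self):
        assert generate_scene(5, seed=1) != generate_scene(5, seed=2)

    def test_recorded_areas_are_exact_rasterized_counts(self):
        scene = generate_scene(5, area_range=(1000, 1300), seed=9)
        for nuc in scene.nuclei:
            assert 1000 <= nuc.area_px <= 1300
            mask = ellipse_mask(
                scene.image_shape, nuc.center, nuc.semi_axes, nuc.orientation
            )
            assert int(mask.sum()) == nuc.area_px
        for nuc_foci in scene.foci:
            for f in nuc_foci:
                assert f.area_px == len(disk_offsets(f.radius))

    def test_nuclei_keep_clear_separation(self):
        scene = generate_scene(8, seed=13)
        masks = [
            ellipse_mask(scene.image_shape, n.center, n.semi_axes, n.orientation)
            for n in scene.nuclei
        ]
        union = np.zeros(scene.image_shape, dtype=int)
        for m in masks:
            union += m
        assert union.max() == 1  # pairwise disjoint

    def test_impossible_placement_raises(self):
        with pytest.raises(PlacementError):
            generate_scene(4, image_shape=(64, 64), area_range=(2000, 2500), seed=1)


class TestRenderScene:
    def test_noise_free_marker_threshold_recovers_areas(self):
        scene = generate_scene(6, seed=21)
        marker, _ = render_scene(scene)
        level = (scene.background_level + scene.nuclei[0].marker_intensity) // 2
        fg = marker > level
        assert int(fg.sum()) == sum(n.area_px for n in scene.nuclei)

    def test_damage_background_flat_without_foci_or_noise(self):
        scene = generate_scene(2, foci_count_range=(0, 0), seed=3)
        _, damage = render_scene(scene)
        assert (damage == scene.background_level).all()

    def test_pan_nuclear_fills_whole_nucleus(self):
        scene = generate_scene(3, pan_nuclear_fraction=1.0, seed=8)
        assert all(n.pan_nuclear for n in scene.nuclei)
        _, damage = render_scene(scene)
        fg = damage > (scene.background_level + scene.foci_intensity) // 2
        assert int(fg.sum()) == sum(n.area_px for n in scene.nuclei)

    def test_noise_is_seeded_and_bounded(self):
        scene = generate_scene(2, noise_sigma=5.0, seed=14)
        _, d1 = render_scene(scene)
        _, d2 = render_scene(scene)
        assert (d1 == d2).all()
        assert d1.dtype == np.uint8


class TestGroundTruthRecords:
    def test_arithmetic_and_conservation(self):
        scene = generate_scene(6, foci_count_range=(0, 9), seed=31)
        records = ground_truth_records(scene, "x.png")
        total_focus_px = sum(f.area_px for foci in scene.foci for f in foci)
        assert sum(r.total_foci_area for r in records) == total_focus_px
        for rec, nuc_foci in zip(records, scene.foci):
            assert rec.foci_count == len(nuc_foci)
            if rec.foci_count:
                assert rec.mean_foci_area == rec.total_foci_area / rec.foci_count
            else:
                assert rec.mean_foci_area == 0.0

    def test_ids_follow_raster_order(self):
        scene = generate_scene(7, seed=55)
        firsts = [n.first_pixel for n in scene.nuclei]
        assert firsts == sorted(firsts)
        assert [r.nucleus_id for r in ground_truth_records(scene)] == list(
            range(1, 8)
        )

    def test_clump_mode_merges_into_oversized_component(self):
        """Overlapping nuclei merge into one component whose area exceeds the
        gate, so size gating drops the clump - the automated analogue of
        excluding clumped nuclei by inspection."""
        for seed in range(40):
            scene = generate_scene(
                2,
                image_shape=(160, 160),
                area_range=(1000, 1400),
                foci_count_range=(0, 0),
                allow_overlap=True,
                seed=seed,
            )
            masks = [
                ellipse_mask(scene.image_shape, n.center, n.semi_axes, n.orientation)
                for n in scene.nuclei
            ]
            overlap = (masks[0] & masks[1]).any()
            if overlap and int((masks[0] | masks[1]).sum()) > 1400:
                break
        else:
            pytest.fail("no overlapping pair sampled")
        marker, damage = render_scene(scene)
        params = AnalysisParams(
            marker_area_min=1000, marker_area_max=1400, c_offset=0
        )
        records = quantify_pair(
            (GrayImage(marker, "clump.png"), GrayImage(damage, "clump.png")), params
        )
        assert records == []


class TestSimulate:
    def test_writes_folder_pair_and_ground_truth(self, tmp_path):
        scenes = simulate(
            tmp_path / "sim",
            n_images=2,
            n_nuclei_range=(3, 4),
            seed=7,
            image_shape=(256, 256),
        )
        assert len(scenes) == 2
        assert len(list((tmp_path / "sim" / "marker").glob("*.png"))) == 2
        assert len(list((tmp_path / "sim" / "damage").glob("*.png"))) == 2
        with open(tmp_path / "sim" / "ground_truth.csv") as fh:
            rows = list(csv.reader(fh))
        assert len(rows) - 1 == sum(len(s.nuclei) for s in scenes)
        meta = json.loads((tmp_path / "sim" / "scene.json").read_text())
        assert meta["seed"] == 7 and meta["n_images"] == 2

    def test_same_seed_byte_identical_images(self, tmp_path):
        simulate(tmp_path / "a", n_images=2, n_nuclei_range=(3, 3), seed=5,
                 image_shape=(192, 192))
        simulate(tmp_path / "b", n_images=2, n_nuclei_range=(3, 3), seed=5,
                 image_shape=(192, 192))
        for sub in ("marker", "damage"):
            for pa in sorted((tmp_path / "a" / sub).glob("*.png")):
                pb = tmp_path / "b" / sub / pa.name
                assert pa.read_bytes() == pb.read_bytes()
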