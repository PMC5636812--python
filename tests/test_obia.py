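"""OBIA extraction: segmentation correctness, index rule, mask assembly."""

import numpy as np
import pytest
from brute_force import brute_force_segment

from shadowcensus import (
    ObiaParams,
    RasterScene,
    SceneSpec,
    classify,
    compute_indices,
    count_shadow_pixels,
    extract_shadows,
    flag_large,
    generate_scene,
    segment,
    to_binary_mask,
)
from shadowcensus.obia import SegmentObject, attach_indices, objects_table


def _partition_of(objects, shape):
    cover = np.zeros(shape, dtype=int)
    for o in objects:
        cover[o.pixels[:, 0], o.pixels[:, 1]] += 1
    return cover


class TestSegment:
    def test_constant_image_is_one_object(self, flat_scene):
        objects = segment(flat_scene)
        assert len(objects) == 1
        assert objects[0].area_px == 64

    def test_step_image_splits_into_the_two_halves(self, step_scene):
        objects = segment(step_scene, ObiaParams(scale=2.0))
        assert len(objects) == 2
        halves = {frozenset(o.pixel_indices) for o in objects}
        left = frozenset((r, c) for r in range(8) for c in range(4))
        right = frozenset((r, c) for r in range(8) for c in range(8))
        assert halves == {left, right - left}

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_merger_on_noisy_8x8(self, seed):
        """Greedy heap implementation reproduces a full-recompute merger:
        identical merge-cost history and identical final partition."""
        rng = np.random.default_rng(seed)
        base = np.full((8, 8), 0.75)
        base[2:5, 1:6] = 0.15
        img = np.clip(base + rng.normal(0, 0.05, (8, 8)), 0, 1)
        scene = RasterScene(img, resolution_m=0.1)
        params = ObiaParams(scale=15.0)
        history = []
        objects = segment(scene, params, merge_history=history)
        oracle_regions, oracle_history = brute_force_segment(img, params.scale)
        assert history == pytest.approx(oracle_history, abs=1e-8)
        assert {frozenset(o.pixel_indices) for o in objects} == set(oracle_regions)

    def test_output_is_a_partition(self, dense_scene):
        _, scene, _ = dense_scene
        objects = segment(scene)
        cover = _partition_of(objects, scene.shape)
        assert (cover == 1).all()
        for o in objects:
            assert o.area_px == len(o.pixels)

    def test_eight_connectivity_merges_diagonal_neighbours(self):
        img = np.full((4, 4), 0.9)
        img[0, 0] = img[1, 1] = img[2, 2] = img[3, 3] = 0.1
        scene = RasterScene(img, resolution_m=0.1)
        rook = segment(scene, ObiaParams(scale=2.0, connectivity=4))
        queen = segment(scene, ObiaParams(scale=2.0, connectivity=8))
        dark_rook = [o for o in rook if o.mean_intensity < 0.5]
        dark_queen = [o for o in queen if o.mean_intensity < 0.5]
        assert len(dark_rook) == 4
        assert len(dark_queen) == 1

    def test_synthetic_scene_yields_one_dark_object_per_penguin(self, dense_scene):
        _, scene, _ = dense_scene
        objects = segment(scene)
        n_dark = sum(1 for o in objects if o.mean_intensity < 0.4)
        assert abs(n_dark - 50) <= 5


class TestIndices:
    def test_whole_image_object_has_zero_brightness_index(self, dense_scene):
        _, scene, _ = dense_scene
        rows, cols = scene.shape
        px = np.argwhere(np.ones(scene.shape, dtype=bool))
        whole = SegmentObject(
            label=0, pixels=px, area_px=rows * cols,
            mean_intensity=float(scene.intensity.mean()),
        )
        out = compute_indices(whole, scene)
        assert out.brightness_index == pytest.approx(0.0, abs=1e-12)

    def test_dark_uniform_object_in_bright_scene(self):
        img = np.full((16, 16), 0.75)
        img[4:8, 4:8] = 0.15
        scene = RasterScene(img, resolution_m=0.1)
        obj = SegmentObject(
            label=0,
            pixels=np.argwhere(img < 0.5),
            area_px=16,
            mean_intensity=0.15,
        )
        out = compute_indices(obj, scene)
        assert out.brightness_index > 0
        assert out.mean_deviation_index < 0.85

    def test_bright_object_has_negative_brightness_index(self):
        img = np.full((16, 16), 0.3)
        img[0:4, 0:4] = 0.9
        scene = RasterScene(img, resolution_m=0.1)
        obj = SegmentObject(
            label=0, pixels=np.argwhere(img > 0.5), area_px=16, mean_intensity=0.9
        )
        assert compute_indices(obj, scene).brightness_index < 0

    def test_uniform_scene_defines_indices_as_zero(self, flat_scene):
        obj = segment(flat_scene)[0]
        out = compute_indices(obj, flat_scene)
        assert out.brightness_index == 0.0
        assert out.mean_deviation_index == 0.0

    def test_attach_indices_matches_scalar_path(self, dense_scene):
        _, scene, _ = dense_scene
        objects = segment(scene)
        batch = attach_indices(objects, scene)
        single = [compute_indices(o, scene) for o in objects]
        for a, b in zip(batch, single):
            assert a.brightness_index == pytest.approx(b.brightness_index)
            assert a.mean_deviation_index == pytest.approx(b.mean_deviation_index)


def _obj(bi, mdi, area=10, label=0):
    return SegmentObject(
        label=label,
        pixels=np.zeros((area, 2), dtype=int),
        area_px=area,
        mean_intensity=0.2,
        brightness_index=bi,
        mean_deviation_index=mdi,
    )


class TestClassifyAndFlag:
    def test_rule_keeps_dark_homogeneous_objects_only(self):
        kept = classify([_obj(0.5, 0.3), _obj(-0.2, 0.3), _obj(0.5, 0.9)])
        assert len(kept) == 1
        assert kept[0].brightness_index == 0.5

    def test_thresholds_are_strict_inequalities(self):
        assert classify([_obj(0.0, 0.3)]) == []
        assert classify([_obj(0.5, 0.85)]) == []
        assert len(classify([_obj(1e-9, 0.84999)])) == 1

    def test_empty_input_gives_empty_result(self):
        assert classify([]) == []
        assert flag_large([]) == []

    def test_classification_is_idempotent_and_order_independent(self):
        objs = [_obj(0.5, 0.3, label=1), _obj(-1, 0.3, label=2), _obj(2, 0.2, label=3)]
        once = classify(objs)
        assert classify(once) == once
        reversed_kept = classify(list(reversed(objs)))
        assert {o.label for o in reversed_kept} == {o.label for o in once}

    def test_review_flag_boundary_at_45_pixels(self):
        flagged = flag_large([_obj(1, 0.1, area=45), _obj(1, 0.1, area=46)])
        assert [o.flagged_for_review for o in flagged] == [False, True]


class TestMask:
    def test_counts_union_of_disjoint_objects(self, flat_scene):
        a = SegmentObject(
            label=0, pixels=np.argwhere(np.arange(64).reshape(8, 8) < 10),
            area_px=10, mean_intensity=0.5,
        )
        b = SegmentObject(
            label=1, pixels=np.argwhere((np.arange(64).reshape(8, 8) >= 10)
                                        & (np.arange(64).reshape(8, 8) < 24)),
            area_px=14, mean_intensity=0.5,
        )
        mask = to_binary_mask([a, b], flat_scene)
        assert count_shadow_pixels(mask) == 24

    def test_no_objects_gives_empty_mask(self, flat_scene):
        assert count_shadow_pixels(to_binary_mask([], flat_scene)) == 0


class TestExtractChain:
    def test_count_close_to_truth_on_synthetic_scene(self, dense_scene):
        _, scene, layout = dense_scene
        _, _, count = extract_shadows(scene)
        truth = layout.truth_mask.sum()
        assert abs(count - truth) <= 0.15 * truth

    def test_noise_free_scene_recall_at_least_95_percent(self):
        spec = SceneSpec(
            n_penguins=40, image_size_px=(80, 80), noise_sd=0.0, seed=8
        )
        scene, layout = generate_scene(spec)
        mask, _, _ = extract_shadows(scene)
        truth = layout.truth_mask
        recall = (mask & truth).sum() / truth.sum()
        assert recall >= 0.95

    def test_drop_flagged_removes_oversized_objects_from_mask(self):
        # a 10x10 dark block (100 px) far exceeds the 45 px review cap
        img = np.full((40, 40), 0.75)
        img[5:15, 5:15] = 0.15
        img[25:28, 25:30] = 0.15  # 15 px: plausible shadow, stays
        scene = RasterScene(img, resolution_m=0.1)
        _, objects, count = extract_shadows(scene)
        assert any(o.flagged_for_review for o in objects)
        assert count == 115
        _, _, kept_count = extract_shadows(scene, drop_flagged=True)
        assert kept_count == 15

    def test_objects_table_columns(self, dense_scene):
        _, scene, _ = dense_scene
        _, objects, _ = extract_shadows(scene)
        table = objects_table(objects)
        assert list(table.columns) == [
            "id", "area_px", "mean_intensity", "brightness_index",
            "mean_deviation_index", "flagged",
        ]
        assert len(table) == len(objects)
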