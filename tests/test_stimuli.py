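"""Stimulus generator: determinism, rigid motion, object ground truth."""

import numpy as np
import pytest

from retinasim.stimuli import (
    SCENARIOS,
    SceneSpec,
    composite_object,
    make_background,
    object_masks,
    scenario,
)


def spec(**kw) -> SceneSpec:
    base = dict(height=12, width=12, n_frames=4, seed=7, texture="random")
    base.update(kw)
    return SceneSpec(**base)


class TestBackground:
    def test_zero_motion_identity(self):
        stack = make_background(spec(bg_velocity=(0, 0)))
        assert np.array_equal(stack.frames, np.broadcast_to(
            stack.frames[0], stack.frames.shape))

    def test_rigid_translation_is_a_roll(self):
        stack = make_background(spec(bg_velocity=(0, 1), height=4, width=4,
                                     n_frames=3))
        assert np.array_equal(stack.frames[2], np.roll(stack.frames[0], 2, axis=1))

    def test_seed_determinism_bit_exact(self):
        a = make_background(spec(bg_velocity=(1, 2)))
        b = make_background(spec(bg_velocity=(1, 2)))
        assert np.array_equal(a.frames, b.frames)

    def test_different_seed_differs(self):
        a = make_background(spec())
        b = make_background(spec(seed=8))
        assert not np.array_equal(a.frames, b.frames)

    def test_non_integer_velocity_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            spec(bg_velocity=(0.5, 0))

    @pytest.mark.parametrize("texture", ["random", "checker", "lines"])
    def test_global_motion_is_a_permutation(self, texture):
        # wrap translation permutes pixel values, so the value multiset is
        # frame-invariant
        stack = make_background(spec(texture=texture, bg_velocity=(1, 1)))
        ref = np.sort(stack.frames[0].ravel())
        for t in range(1, stack.n_frames):
            assert np.array_equal(np.sort(stack.frames[t].ravel()), ref)


class TestObject:
    def test_fixed_object_static_background_static_scene(self):
        s = spec(bg_velocity=(0, 0), object_shape="square",
                 object_center=(6, 6), object_half_width=2)
        stack, masks = composite_object(make_background(s), s)
        assert np.array_equal(stack.frames, np.broadcast_to(
            stack.frames[0], stack.frames.shape))
        assert np.array_equal(masks, np.broadcast_to(masks[0], masks.shape))

    def test_loom_mask_sides_grow_arithmetically(self):
        s = spec(height=30, width=30, object_shape="square",
                 object_center=(15, 15), object_half_width=2,
                 object_motion="loom", growth_rate=1, n_frames=4)
        masks = object_masks(s)
        sides = [int(np.sqrt(m.sum())) for m in masks]
        assert sides == [5, 7, 9, 11]

    def test_translate_leading_edge_dims_trailing_brightens(self):
        # dark square moving right on a uniform bright background: brute-force
        # the per-transition pixel differences against the returned masks
        s = spec(texture="checker", texture_contrast=0.0, base_intensity=1.0,
                 bg_velocity=(0, 0), object_shape="square",
                 object_polarity="dark", object_center=(6, 3),
                 object_half_width=2, object_motion="translate",
                 object_velocity=(0, 1), n_frames=4)
        stack, masks = composite_object(make_background(s), s)
        for t in range(1, s.n_frames):
            diff = stack.frames[t] - stack.frames[t - 1]
            leading = masks[t] & ~masks[t - 1]
            trailing = masks[t - 1] & ~masks[t]
            assert leading.any() and trailing.any()
            assert np.all(diff[leading] < 0)
            assert np.all(diff[trailing] > 0)
            assert np.all(diff[~(leading | trailing)] == 0)

    def test_object_exit_reports_first_offending_frame(self):
        s = spec(object_shape="square", object_center=(6, 9),
                 object_half_width=2, object_motion="translate",
                 object_velocity=(0, 1), n_frames=4)
        with pytest.raises(ValueError, match="frame 1"):
            object_masks(s)

    def test_disc_mask_is_circular(self):
        s = spec(height=21, width=21, object_shape="disc",
                 object_center=(10, 10), object_half_width=4, n_frames=1)
        m = object_masks(s)[0]
        rows, cols = np.ogrid[:21, :21]
        assert np.array_equal(m, (rows - 10) ** 2 + (cols - 10) ** 2 <= 16)


class TestScenarios:
    def test_unknown_name_lists_valid_scenarios(self):
        with pytest.raises(ValueError) as err:
            scenario("nope")
        for name in SCENARIOS:
            assert name in str(err.value)

    def test_global_only_object_is_static(self):
        _, truth = scenario("oms_global_only", seed=1)
        masks = truth["masks"]
        assert np.array_equal(masks, np.broadcast_to(masks[0], masks.shape))

    def test_translate_preserves_object_area(self):
        _, truth = scenario("ld_translate", seed=1)
        areas = truth["object_area"]
        assert len(set(areas.tolist())) == 1

    @pytest.mark.parametrize("name", ["ld_loom_dark", "ld_loom_bright"])
    def test_loom_area_strictly_increases(self, name):
        _, truth = scenario(name, seed=1)
        areas = truth["object_area"]
        assert np.all(np.diff(areas) > 0)

    def test_scenarios_record_meta_and_are_deterministic(self):
        a, _ = scenario("oms_global_plus_object", seed=5)
        b, _ = scenario("oms_global_plus_object", seed=5)
        assert a.meta["scenario"] == "oms_global_plus_object"
        assert np.array_equal(a.frames, b.frames)
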