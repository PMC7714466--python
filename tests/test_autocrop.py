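"""Autocrop: thresholding, components, boxes, merging, full pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucmorph import (
    BoundingBox3D,
    CalibratedStack,
    Calibration,
    CoordinateTable,
    autocrop_stack,
    component_to_box,
    crop_other_channels,
    filter_components,
    find_components,
    merge_boxes,
    otsu_threshold,
    threshold_stack,
)
from nucmorph.autocrop import AutocropConfig, SingleClassError

from conftest import ACQ_CAL


def brute_force_otsu(hist):
    """Independent oracle: exhaustive between-class variance scan."""
    hist = np.asarray(hist, dtype=float)
    total = hist.sum()
    best_t, best_v = 0, -1.0
    for t in range(len(hist) - 1):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[: t + 1] * np.arange(t + 1)).sum() / w0
        m1 = (hist[t + 1:] * np.arange(t + 1, len(hist))).sum() / w1
        v = w0 * w1 * (m0 - m1) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


class TestOtsu:
    def test_two_value_image_separates_perfectly(self):
        img = np.full((4, 8, 8), 10, dtype=np.uint8)
        img[:, :4] = 200
        stack = CalibratedStack(img, Calibration())
        fg = threshold_stack(stack)
        assert np.array_equal(fg, img == 200)

    def test_matches_brute_force_on_gaussian_mixture(self):
        rng = np.random.default_rng(1234)
        vals = np.concatenate([
            np.clip(rng.normal(30, 10, 100_000), 0, 255),
            np.clip(rng.normal(180, 10, 100_000), 0, 255),
        ]).astype(np.uint8)
        hist = np.bincount(vals, minlength=256)
        t = otsu_threshold(hist)
        assert abs(t - brute_force_otsu(hist)) <= 3
        from skimage.filters import threshold_otsu

        assert abs(t - threshold_otsu(hist=(hist, np.arange(256)))) <= 1

    def test_constant_image_raises_single_class(self):
        with pytest.raises(SingleClassError):
            otsu_threshold(np.bincount(np.full(1000, 7), minlength=256))

    def test_noise_free_field_recovers_ground_truth(self, clean_single_nucleus):
        f = clean_single_nucleus
        fg = threshold_stack(f.stack)
        assert np.array_equal(fg, f.nucleus_labels > 0)


class TestComponents:
    def test_corner_touching_voxels_are_one_component(self):
        g = np.zeros((4, 4, 4), bool)
        g[1, 1, 1] = g[2, 2, 2] = True  # share only a corner
        comps = find_components(g, Calibration())
        assert len(comps) == 1

    def test_gap_separates_components(self):
        g = np.zeros((4, 4, 6), bool)
        g[1, 1, 1] = g[1, 1, 3] = True
        comps = find_components(g, Calibration())
        assert len(comps) == 2

    def test_physical_volume_of_digitized_sphere(self):
        from nucmorph import make_digitized_sphere

        sph = make_digitized_sphere(5, membership="center")
        comps = find_components(sph.grid, Calibration(0.1, 0.1, 0.1))
        assert len(comps) == 1
        assert comps[0].volume_um3 == pytest.approx(0.515, rel=1e-9)

    def test_volume_filter(self):
        g = np.zeros((6, 30, 30), bool)
        g[2, 2:4, 2:4] = True  # 8 voxels
        g[2:5, 10:20, 10:20] = True  # 300 voxels
        comps = find_components(g, Calibration(0.5, 0.5, 0.5))  # 1 and 37.5 um3
        assert len(filter_components(comps)) == 1  # 1.0 not > 1.0: dropped
        assert len(filter_components(comps, 0.0)) == 2
        assert filter_components(comps, 1000.0) == []


class TestBoxes:
    def _component_at(self, x0, x1, shape=(40, 40, 100)):
        g = np.zeros(shape, bool)
        g[10:20, 10:20, x0:x1 + 1] = True
        return find_components(g, Calibration())[0], shape

    def test_padding_clamped_at_origin(self):
        comp, shape = self._component_at(5, 10)
        box = component_to_box(comp, 20, shape)
        assert box.x_start == 0 and box.width == 31  # 10 + 20 inclusive

    def test_padding_interior(self):
        comp, shape = self._component_at(40, 60)
        box = component_to_box(comp, 20, shape)
        assert box.x_start == 20 and box.width == 61

    def test_zero_padding_is_tight(self):
        comp, shape = self._component_at(40, 60)
        box = component_to_box(comp, 0, shape)
        assert (box.x_start, box.width) == (40, 21)
        assert (box.y_start, box.height) == (10, 10)
        assert (box.z_start, box.depth) == (10, 10)

    def test_merge_identical_and_disjoint(self):
        a = BoundingBox3D(0, 0, 0, 0, 10, 10, 10)
        b = BoundingBox3D(1, 0, 0, 0, 10, 10, 10)
        c = BoundingBox3D(2, 50, 50, 0, 10, 10, 10)
        merged = merge_boxes([a, b, c])
        assert len(merged) == 2
        assert [m.id for m in merged] == [0, 1]

    def test_merge_half_overlap_slab(self):
        # two 10^3 boxes sharing a 5x10x10 slab = 50% of the smaller
        a = BoundingBox3D(0, 0, 0, 0, 10, 10, 10)
        b = BoundingBox3D(1, 5, 0, 0, 10, 10, 10)
        merged = merge_boxes([a, b], 0.5)
        assert len(merged) == 1
        assert (merged[0].width, merged[0].height, merged[0].depth) == (15, 10, 10)
        # one voxel less overlap than half: kept apart
        b2 = BoundingBox3D(1, 6, 0, 0, 10, 10, 10)
        assert len(merge_boxes([a, b2], 0.5)) == 2

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(0, 30), st.integers(0, 30), st.integers(0, 10),
                  st.integers(1, 12), st.integers(1, 12), st.integers(1, 6)),
        min_size=1, max_size=6,
    ))
    def test_merge_reaches_fixed_point(self, raw_boxes):
        """Merging is idempotent and never increases the box count."""
        boxes = [BoundingBox3D(i, x, y, z, w, h, d)
                 for i, (x, y, z, w, h, d) in enumerate(raw_boxes)]
        once = merge_boxes(boxes, 0.5)
        twice = merge_boxes(once, 0.5)
        assert len(once) <= len(boxes)
        assert [b.slices for b in twice] == [b.slices for b in once]
        assert [b.id for b in once] == list(range(len(once)))


class TestPipeline:
    def test_nine_nuclei_detected_and_contained(self, nine_nucleus_field):
        f = nine_nucleus_field
        result = autocrop_stack(f.stack)
        assert len(result.table.boxes) == 9
        # every ground-truth nucleus fully inside exactly one box
        for rec in f.records:
            m = f.nucleus_mask(rec.label)
            assert sum(b.contains_mask(m) for b in result.table.boxes) == 1

    def test_crops_are_verbatim_subgrids(self, nine_nucleus_field):
        f = nine_nucleus_field
        result = autocrop_stack(f.stack)
        rebuilt = np.zeros_like(f.stack.data)
        for box, crop in zip(result.table.boxes, result.crops):
            rebuilt[box.slices] = crop.data
        for box in result.table.boxes:
            assert np.array_equal(rebuilt[box.slices], f.stack.data[box.slices])

    def test_bead_field_ids_consecutive(self):
        from nucmorph import make_bead_stack

        beads = make_bead_stack(2.5, n_beads=7, seed=4)
        result = autocrop_stack(beads.stack)
        assert [b.id for b in result.table.boxes] == list(range(len(result.table.boxes)))
        assert len(result.table.boxes) == 7

    def test_constant_stack_yields_zero_crops(self):
        stack = CalibratedStack(np.zeros((8, 16, 16), np.uint8), ACQ_CAL)
        result = autocrop_stack(stack)
        assert result.table.boxes == []
        assert result.crops == []

    def test_coordinate_table_roundtrip(self, tmp_path, nine_nucleus_field):
        table = autocrop_stack(nine_nucleus_field.stack).table
        path = tmp_path / "coords.tsv"
        table.to_tsv(path)
        back = CoordinateTable.from_tsv(path)
        assert back.boxes == table.boxes
        assert back.source == table.source

    def test_projection_annotated(self, nine_nucleus_field):
        result = autocrop_stack(nine_nucleus_field.stack)
        proj = result.projection
        assert proj.shape == nine_nucleus_field.stack.data.shape[1:]
        b = result.table.boxes[0]  # outline drawn in black on the inverted image
        assert (proj[b.y_start, b.x_start:b.x_start + b.width] == 0).all()


class TestMultiChannel:
    def test_identical_geometry_across_channels(self, clean_single_nucleus):
        f = clean_single_nucleus
        table = autocrop_stack(f.stack).table
        other = CalibratedStack(f.stack.data * 0.5, f.stack.calibration, name="probe")
        crops = crop_other_channels(table, {"dna": f.stack, "cy3": other})
        assert set(crops) == {"dna", "cy3"}
        for a, b in zip(crops["dna"], crops["cy3"]):
            assert a.shape == b.shape
            assert np.array_equal(b.data * 2.0, a.data)

    def test_dimension_mismatch_is_hard_error(self, clean_single_nucleus):
        f = clean_single_nucleus
        table = autocrop_stack(f.stack).table
        bad = CalibratedStack(np.zeros((4, 8, 8)), f.stack.calibration)
        with pytest.raises(ValueError):
            crop_other_channels(table, {"dna": f.stack, "bad": bad})

    def test_empty_table_is_no_op(self, clean_single_nucleus):
        crops = crop_other_channels(CoordinateTable(), {"dna": clean_single_nucleus.stack})
        assert crops == {"dna": []}
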