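"""Tiling schemes: grids, justifications, integrity constraint, filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diatile import (
    GroundTruth,
    Rect,
    SlideImage,
    TilingParams,
    apply_integrity_constraint,
    filter_empty_tiles,
    fixed_stride_tiles,
    object_based_oic_tiles,
    object_based_tiles,
    oversize_exception,
)
from diatile.tiling import JUSTIFICATIONS, TilingError

from conftest import make_rect_instance, make_slide


class TestTilingParams:
    @pytest.mark.parametrize("kw", [
        {"stride": 0}, {"stride": 600}, {"margin": -1},
        {"integrity_threshold": 1.5}, {"integrity_threshold": -0.1},
    ])
    def test_invalid_params(self, kw):
        with pytest.raises(ValueError):
            TilingParams(**kw)


class TestFixedStride:
    def test_1024_grid_brute_force(self):
        """Defaults on 1024x1024: origins {0,256,512} per axis, 9 tiles,
        every interior pixel covered by exactly 4."""
        slide = make_slide(1024, 1024)
        gt = GroundTruth((1024, 1024), [])
        tiles = fixed_stride_tiles(slide, gt)
        origins = {t.origin for t in tiles}
        expected = {(r, c) for r in (0, 256, 512) for c in (0, 256, 512)}
        assert origins == expected
        # brute-force coverage count for a probe of interior pixels
        for p in [(256, 256), (400, 700), (767, 767), (511, 512)]:
            n = sum(
                t.window.r0 <= p[0] < t.window.r1
                and t.window.c0 <= p[1] < t.window.c1
                for t in tiles
            )
            assert n == 4

    def test_exact_tile_region_single_tile(self):
        slide = make_slide(512, 512)
        tiles = fixed_stride_tiles(slide, GroundTruth((512, 512), []))
        assert len(tiles) == 1 and tiles[0].origin == (0, 0)

    def test_adjacent_tiles_overlap_half(self):
        slide = make_slide(1024, 1024)
        tiles = fixed_stride_tiles(slide, GroundTruth((1024, 1024), []))
        by_origin = {t.origin: t for t in tiles}
        a, b = by_origin[(0, 0)].window, by_origin[(0, 256)].window
        inter = a.intersect(b)
        assert (inter.height, inter.width) == (512, 256)
        assert inter.area / (512 * 512) == 0.5

    def test_clamped_final_origin_covers_region(self):
        slide = make_slide(700, 900)
        gt = GroundTruth((700, 900), [])
        tiles = fixed_stride_tiles(slide, gt)
        covered = np.zeros((700, 900), dtype=bool)
        for t in tiles:
            w = t.window
            assert 0 <= w.r0 and w.r1 <= 700 and 0 <= w.c0 and w.c1 <= 900
            covered[w.r0:w.r1, w.c0:w.c1] = True
        assert covered.all()
        rows = sorted({t.origin[0] for t in tiles})
        assert rows == [0, 188]  # clamped to 700 - 512

    def test_mask_includes_truncated_objects(self, rect_world):
        slide, gt = rect_world
        tiles = fixed_stride_tiles(slide, gt)
        total = sum(t.mask_patch.sum() for t in tiles)
        assert total > 0
        for t in tiles:
            expected = gt.mask_window(t.window)
            assert np.array_equal(t.mask_patch, expected)

    def test_small_region_rejected(self):
        slide = make_slide(300, 900)
        with pytest.raises(TilingError):
            fixed_stride_tiles(slide, GroundTruth((300, 900), []))


class TestObjectBased:
    def test_nine_tiles_per_centered_object(self):
        slide = make_slide(2000, 2000)
        inst = make_rect_instance(1, 950, 970, 100, 60)
        gt = GroundTruth((2000, 2000), [inst])
        tiles = object_based_tiles(slide, gt)
        assert len(tiles) == 9
        assert {t.provenance["justification"] for t in tiles} == set(
            JUSTIFICATIONS
        )
        # every tile contains at least one anchor pixel
        for t in tiles:
            assert inst.pixels_in(t.window) > 0

    def test_corner_justification_margin(self):
        slide = make_slide(2000, 2000)
        inst = make_rect_instance(1, 950, 970, 100, 60)
        gt = GroundTruth((2000, 2000), [inst])
        tiles = {t.provenance["justification"]: t
                 for t in object_based_tiles(slide, gt)}
        tl = tiles[("top", "left")]
        # bbox minimum corner at tile-local (margin, margin)
        assert (inst.bbox.r0 - tl.origin[0],
                inst.bbox.c0 - tl.origin[1]) == (10, 10)
        br = tiles[("bottom", "right")]
        assert (br.window.r1 - inst.bbox.r1,
                br.window.c1 - inst.bbox.c1) == (10, 10)

    def test_center_justification_floors_odd_slack(self):
        slide = make_slide(2000, 2000)
        inst = make_rect_instance(1, 900, 900, 101, 101)  # odd slack 411
        gt = GroundTruth((2000, 2000), [inst])
        tiles = {t.provenance["justification"]: t
                 for t in object_based_tiles(slide, gt)}
        cc = tiles[("center", "center")]
        assert cc.origin == (900 - 205, 900 - 205)

    def test_zero_instances_zero_tiles(self):
        slide = make_slide(1024, 1024)
        assert object_based_tiles(slide, GroundTruth((1024, 1024), [])) == []

    def test_edge_clamping_keeps_nine_tiles(self):
        slide = make_slide(1024, 1024)
        inst = make_rect_instance(1, 500, 3, 40, 40)  # near left edge
        gt = GroundTruth((1024, 1024), [inst])
        tiles = object_based_tiles(slide, gt)
        assert len(tiles) == 9
        for t in tiles:
            w = t.window
            assert 0 <= w.c0 and w.c1 <= 1024
        # left justification would start at column 3-10=-7 -> clamped to 0
        by_just = {t.provenance["justification"]: t for t in tiles}
        assert by_just[("top", "left")].origin[1] == 0

    def test_dedupe_drops_coincident_origins(self):
        slide = make_slide(1024, 1024)
        inst = make_rect_instance(1, 500, 0, 40, 40)  # flush with the edge
        gt = GroundTruth((1024, 1024), [inst])
        full = object_based_tiles(slide, gt)
        deduped = object_based_tiles(slide, gt, dedupe=True)
        assert len(full) == 9
        assert len(deduped) < 9
        assert len({t.origin for t in full}) == len(deduped)

    def test_neighbors_appear_in_anchor_tiles(self):
        slide = make_slide(2000, 2000)
        anchor = make_rect_instance(1, 950, 950, 80, 60)
        neighbor = make_rect_instance(2, 950, 1050, 40, 40)
        gt = GroundTruth((2000, 2000), [anchor, neighbor])
        tiles = object_based_tiles(slide, gt)
        assert len(tiles) == 18  # 9 per instance
        tl = next(t for t in tiles
                  if t.provenance["anchor_id"] == 1
                  and t.provenance["justification"] == ("top", "left"))
        assert neighbor.pixels_in(tl.window) == neighbor.area
        assert tl.mask_patch.sum() == anchor.area + neighbor.area


class TestIntegrityConstraint:
    def _world(self, neighbor_cols_inside):
        """Anchor fully in tile; 1000-px neighbor (10x100) with a chosen
        number of its columns inside the anchor's top-left tile."""
        slide = make_slide(2000, 2000)
        anchor = make_rect_instance(1, 1000, 1000, 80, 80)
        # top-left tile window: rows [990,1502), cols [990,1502)
        c0 = 1502 - neighbor_cols_inside
        neighbor = make_rect_instance(2, 1100, c0, 10, 100)
        gt = GroundTruth((2000, 2000), [anchor, neighbor])
        tiles = object_based_tiles(slide, gt)
        tl = next(t for t in tiles
                  if t.provenance["anchor_id"] == 1
                  and t.provenance["justification"] == ("top", "left"))
        assert neighbor.pixels_in(tl.window) == neighbor_cols_inside * 10
        return tl, gt, anchor, neighbor

    def test_neighbor_above_threshold_included(self):
        tl, gt, anchor, neighbor = self._world(80)  # fraction 0.8
        out = apply_integrity_constraint(tl, gt)
        assert out.mask_patch.sum() == anchor.area + 800

    def test_neighbor_below_threshold_excluded(self):
        tl, gt, anchor, neighbor = self._world(74)  # fraction 0.74 < 0.75
        out = apply_integrity_constraint(tl, gt)
        assert out.mask_patch.sum() == anchor.area
        # neighbor still visible in the image patch (mask-only exclusion)
        assert out.image_patch.shape == (512, 512)

    def test_anchor_fully_inside_always_included(self):
        tl, gt, anchor, _ = self._world(10)
        out = apply_integrity_constraint(tl, gt)
        assert (out.mask_patch.sum() >= anchor.area)

    def test_inclusion_monotone_in_area_fraction(self):
        included = []
        for cols in range(1, 101, 3):
            tl, gt, anchor, _ = self._world(cols)
            out = apply_integrity_constraint(tl, gt)
            included.append(out.mask_patch.sum() > anchor.area)
        # once included, stays included as the fraction grows
        assert included == sorted(included)

    def test_threshold_zero_recovers_unconstrained_mask(self):
        tl, gt, *_ = self._world(40)
        params = TilingParams(integrity_threshold=0)
        out = apply_integrity_constraint(tl, gt, params)
        assert np.array_equal(out.mask_patch, tl.mask_patch)

    def test_oic_scheme_masks_subset_of_plain(self, small_slide):
        slide, gt = small_slide
        plain = object_based_tiles(slide, gt)
        oic = object_based_oic_tiles(slide, gt)
        assert len(plain) == len(oic)
        for p, o in zip(plain, oic):
            assert p.origin == o.origin
            assert not (o.mask_patch & ~p.mask_patch).any()


class TestOversizeException:
    def _tile(self):
        slide = make_slide(2000, 2000)
        return slide, Rect(500, 500, 1012, 1012)

    def _cut(self, slide, inst):
        from diatile.tiling import _cut_tile

        return _cut_tile(slide, GroundTruth((2000, 2000), [inst]),
                         (500, 500), 512, {"scheme": "object_based",
                                           "anchor_id": inst.instance_id,
                                           "justification": ("top", "left")})

    def test_wide_object_spanning_two_quadrants(self):
        slide, _ = self._tile()
        inst = make_rect_instance(1, 700, 450, 20, 600)  # spans both halves
        tile = self._cut(slide, inst)
        assert oversize_exception(inst, tile)

    def test_wide_object_in_single_quadrant(self):
        slide, _ = self._tile()
        # 600 px wide but only its tail enters the tile's top-left quadrant
        inst = make_rect_instance(1, 600, 0, 20, 600)
        tile = self._cut(slide, inst)
        assert inst.pixels_in(Rect(500, 500, 756, 756)) > 0
        assert not oversize_exception(inst, tile)

    def test_not_oversize_raises(self):
        slide, _ = self._tile()
        inst = make_rect_instance(1, 700, 700, 100, 100)
        tile = self._cut(slide, inst)
        with pytest.raises(ValueError):
            oversize_exception(inst, tile)

    def test_oversize_included_despite_low_fraction(self):
        """A 600-px-wide object mostly outside the tile is kept by the
        quarter rule even though its area fraction is below 75%."""
        slide = make_slide(2000, 2000)
        anchor = make_rect_instance(1, 600, 600, 80, 80)
        wide = make_rect_instance(2, 700, 300, 20, 1200)
        gt = GroundTruth((2000, 2000), [anchor, wide])
        tiles = object_based_tiles(slide, gt)
        tl = next(t for t in tiles
                  if t.provenance["anchor_id"] == 1
                  and t.provenance["justification"] == ("top", "left"))
        inside = wide.pixels_in(tl.window)
        assert 0 < inside / wide.area < 0.75
        out = apply_integrity_constraint(tl, gt)
        assert out.mask_patch.sum() == anchor.area + inside


class TestFilterEmptyTiles:
    def test_counts_and_fraction(self, rect_world):
        slide, gt = rect_world
        tiles = fixed_stride_tiles(slide, gt)
        nonempty = sum(bool(t.mask_patch.any()) for t in tiles)
        kept, frac = filter_empty_tiles(tiles)
        assert len(kept) == nonempty
        assert frac == (len(tiles) - nonempty) / len(tiles)

    def test_blank_slide_all_removed(self):
        slide = make_slide(1024, 1024)
        tiles = fixed_stride_tiles(slide, GroundTruth((1024, 1024), []))
        kept, frac = filter_empty_tiles(tiles)
        assert kept == [] and frac == 1.0

    def test_empty_input_flagged_undefined(self):
        kept, frac = filter_empty_tiles([])
        assert kept == [] and frac is None

    def test_empty_fraction_monotone_in_object_count(self):
        from diatile import SyntheticConfig, generate_slide

        fracs = []
        for n in (8, 4, 1):
            cfg = SyntheticConfig(width=1536, height=1536, n_objects=n,
                                  n_fragments=0, n_debris=0, n_bands=0,
                                  seed=21, object_length_range=(60, 120))
            slide, gt = generate_slide(cfg)
            _, frac = filter_empty_tiles(fixed_stride_tiles(slide, gt))
            fracs.append(frac)
        assert fracs == sorted(fracs)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    h=st.integers(min_value=512, max_value=1400),
    w=st.integers(min_value=512, max_value=1400),
)
def test_all_tiles_exact_size_and_inside_region(h, w):
    slide = make_slide(h, w)
    gt = GroundTruth((h, w), [make_rect_instance(1, h // 2, w // 2, 8, 8)])
    for scheme in (fixed_stride_tiles, object_based_tiles):
        for t in scheme(slide, gt):
            assert t.image_patch.shape == (512, 512)
            assert t.mask_patch.shape == (512, 512)
            win = t.window
            assert 0 <= win.r0 and win.r1 <= h
            assert 0 <= win.c0 and win.c1 <= w
            # mask is the slide-level mask restricted to the window
            assert np.array_equal(t.mask_patch, gt.mask_window(win))
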