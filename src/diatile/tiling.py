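"""Training-tile generation: fixed-stride and object-based schemes.

Three schemes prepare 512x512 training tiles from an annotated slide region:

* fixed-stride sliding-window tiling (stride 256, i.e. 50% overlap);
* object-based positioning: nine tiles per annotated object, justifying the
  object's bounding box to each of the 3x3 left/center/right x
  top/center/bottom combinations with a 10 px margin;
* object-based positioning with the object integrity constraint: same
  positions, but any object covered by less than 75% of its area inside a
  tile is dropped from that tile's mask (it stays visible in the image).
  Objects taller or wider than the tile are instead kept when they occupy at
  least two of the tile's four quadrants.

Tiles never extend outside the region: origins are clamped at region borders
(training tiles are never padded).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .annotations import GroundTruth, Instance, Rect, SlideImage


class TilingError(ValueError):
    """Raised when a region cannot be tiled as requested."""


@dataclass(frozen=True)
class TilingParams:
    """Constants of the tiling schemes.

    tile_size: side length of the square tiles, px.
    stride: fixed-stride grid step, px (256 -> 50% overlap at 512 tiles).
    margin: gap between an object's bbox and the justified tile edge, px.
    integrity_threshold: minimum in-tile area fraction for an object to be
        kept in the mask under the integrity constraint.
    """

    tile_size: int = 512
    stride: int = 256
    margin: int = 10
    integrity_threshold: float = 0.75

    def __post_init__(self) -> None:
        if not 0 < self.stride <= self.tile_size:
            raise ValueError(
                f"stride must be in (0, tile_size], got {self.stride}"
            )
        if self.margin < 0:
            raise ValueError(f"margin must be >= 0, got {self.margin}")
        if not 0 < self.integrity_threshold <= 1 and self.integrity_threshold != 0:
            raise ValueError(
                "integrity_threshold must be in (0, 1] (0 disables the rule), "
                f"got {self.integrity_threshold}"
            )


JUSTIFICATIONS = [
    (v, h)
    for v in ("top", "center", "bottom")
    for h in ("left", "center", "right")
]


@dataclass
class Tile:
    """A square window of the slide with its local segmentation ground truth."""

    origin: tuple[int, int]  # (row, col) of the window's top-left, slide frame
    size: int
    image_patch: np.ndarray
    mask_patch: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = (self.size, self.size)
        if self.image_patch.shape != expected:
            raise TilingError(
                f"image patch shape {self.image_patch.shape} != {expected}"
            )
        if self.mask_patch.shape != expected:
            raise TilingError(
                f"mask patch shape {self.mask_patch.shape} != {expected}"
            )

    @property
    def window(self) -> Rect:
        r, c = self.origin
        return Rect(r, c, r + self.size, c + self.size)

    def name(self) -> str:
        tag = self.provenance.get("scheme", "tile")
        if "grid_index" in self.provenance:
            gi, gj = self.provenance["grid_index"]
            return f"{tag}_r{gi:04d}_c{gj:04d}.tif"
        anchor = self.provenance.get("anchor_id", 0)
        just = self.provenance.get("justification", ("", ""))
        return f"{tag}_obj{anchor:05d}_{just[0]}_{just[1]}.tif"


def _grid_starts(extent: int, tile: int, stride: int) -> list[int]:
    starts = list(range(0, extent - tile + 1, stride))
    if starts[-1] != extent - tile:
        starts.append(extent - tile)  # clamped final origin for full coverage
    return starts


def _cut_tile(
    slide: SlideImage, gt: GroundTruth, origin: tuple[int, int],
    size: int, provenance: dict,
) -> Tile:
    r, c = origin
    window = Rect(r, c, r + size, c + size)
    return Tile(
        origin=origin,
        size=size,
        image_patch=slide.pixels[r : r + size, c : c + size],
        mask_patch=gt.mask_window(window),
        provenance=provenance,
    )


def fixed_stride_tiles(
    slide: SlideImage,
    gt: GroundTruth,
    params: TilingParams = TilingParams(),
    rect: Rect | None = None,
) -> list[Tile]:
    """Sliding-window tiles on a regular grid covering the region.

    Grid origins are multiples of ``params.stride``; when the region extent is
    not a multiple of the stride, one extra origin clamped to
    ``extent - tile_size`` is appended per axis so the region is fully
    covered.  Masks include every ground-truth pixel inside each window —
    objects may be truncated arbitrarily by tile borders.
    """
    rect = rect or slide.rect
    t = params.tile_size
    if rect.height < t or rect.width < t:
        raise TilingError(
            f"region {rect.height}x{rect.width} smaller than tile size {t}"
        )
    rows = _grid_starts(rect.height, t, params.stride)
    cols = _grid_starts(rect.width, t, params.stride)
    tiles = []
    for i, dr in enumerate(rows):
        for j, dc in enumerate(cols):
            tiles.append(
                _cut_tile(
                    slide, gt, (rect.r0 + dr, rect.c0 + dc), t,
                    {"scheme": "fixed_stride", "grid_index": (i, j)},
                )
            )
    return tiles


def _justified_origin(
    bbox: Rect, just: tuple[str, str], params: TilingParams
) -> tuple[int, int]:
    t, m = params.tile_size, params.margin
    v, h = just
    if v == "top":
        r = bbox.r0 - m
    elif v == "bottom":
        r = bbox.r1 + m - t
    else:
        r = bbox.r0 - (t - bbox.height) // 2  # floor offset on odd slack
    if h == "left":
        c = bbox.c0 - m
    elif h == "right":
        c = bbox.c1 + m - t
    else:
        c = bbox.c0 - (t - bbox.width) // 2
    return r, c


def object_based_tiles(
    slide: SlideImage,
    gt: GroundTruth,
    params: TilingParams = TilingParams(),
    rect: Rect | None = None,
    dedupe: bool = False,
) -> list[Tile]:
    """Nine justification tiles per annotated object.

    For every instance, a tile is placed for each of the 3x3 justifications
    of its bounding box, with ``params.margin`` px between the box and the
    tile boundary on the justified sides; center justification centers the
    box (floor rounding of the top/left offset on odd slack).  Origins are
    clamped so tiles stay inside the region, so near a border several
    justifications may coincide; all nine are still emitted unless
    ``dedupe=True`` drops coincident (origin, anchor) duplicates.  Masks
    include every ground-truth pixel inside the window, including
    coincidentally contained neighboring objects.

    Tiles are ordered by instance id, then justification row-major.
    """
    rect = rect or slide.rect
    t = params.tile_size
    if rect.height < t or rect.width < t:
        raise TilingError(
            f"region {rect.height}x{rect.width} smaller than tile size {t}"
        )
    tiles = []
    for inst in sorted(gt.instances, key=lambda i: i.instance_id):
        seen = set()
        for just in JUSTIFICATIONS:
            r, c = _justified_origin(inst.bbox, just, params)
            r = int(np.clip(r, rect.r0, rect.r1 - t))
            c = int(np.clip(c, rect.c0, rect.c1 - t))
            if dedupe and (r, c) in seen:
                continue
            seen.add((r, c))
            tiles.append(
                _cut_tile(
                    slide, gt, (r, c), t,
                    {
                        "scheme": "object_based",
                        "anchor_id": inst.instance_id,
                        "justification": just,
                    },
                )
            )
    return tiles


def oversize_exception(instance: Instance, tile: Tile) -> bool:
    """Quadrant rule for objects taller or wider than the tile.

    Only meaningful when the instance's bbox exceeds the tile in at least one
    dimension (otherwise the plain area-fraction rule governs).  Returns True
    iff the instance has at least one pixel in two or more of the tile's four
    equal quadrants (tile split at its midlines).
    """
    w = tile.window
    if instance.bbox.height <= w.height and instance.bbox.width <= w.width:
        raise ValueError(
            "oversize exception consulted for an instance not exceeding the tile"
        )
    rm = w.r0 + w.height // 2
    cm = w.c0 + w.width // 2
    quadrants = [
        Rect(w.r0, w.c0, rm, cm),
        Rect(w.r0, cm, rm, w.c1),
        Rect(rm, w.c0, w.r1, cm),
        Rect(rm, cm, w.r1, w.c1),
    ]
    occupied = sum(instance.pixels_in(q) > 0 for q in quadrants)
    return occupied >= 2


def _instance_included(
    inst: Instance, tile: Tile, params: TilingParams
) -> bool:
    inside = inst.pixels_in(tile.window)
    if inside == 0:
        return False
    if params.integrity_threshold == 0:
        return True
    if inside / inst.area >= params.integrity_threshold:
        return True
    w = tile.window
    if inst.bbox.height > w.height or inst.bbox.width > w.width:
        return oversize_exception(inst, tile)
    return False


def apply_integrity_constraint(
    tile: Tile, gt: GroundTruth, params: TilingParams = TilingParams()
) -> Tile:
    """Rewrite a tile's mask keeping only sufficiently complete objects.

    An object's in-window pixels stay in the mask iff its in-window area
    fraction reaches ``params.integrity_threshold`` (areas are exact pixel
    counts), or it is larger than the tile and passes the quadrant rule.
    Excluded objects remain visible in the image patch.  The rule is applied
    uniformly to every instance, anchor included (a non-oversize anchor is
    fully contained by construction, so it always passes).
    """
    window = tile.window
    mask = np.zeros_like(tile.mask_patch)
    for inst in gt.instances:
        if not _instance_included(inst, tile, params):
            continue
        inter = inst.bbox.intersect(window)
        sub = inst.mask[
            inter.r0 - inst.bbox.r0 : inter.r1 - inst.bbox.r0,
            inter.c0 - inst.bbox.c0 : inter.c1 - inst.bbox.c0,
        ]
        mask[
            inter.r0 - window.r0 : inter.r1 - window.r0,
            inter.c0 - window.c0 : inter.c1 - window.c0,
        ] |= sub
    prov = dict(tile.provenance)
    prov["scheme"] = "object_based_oic"
    return replace(tile, mask_patch=mask, provenance=prov)


def object_based_oic_tiles(
    slide: SlideImage,
    gt: GroundTruth,
    params: TilingParams = TilingParams(),
    rect: Rect | None = None,
    dedupe: bool = False,
) -> list[Tile]:
    """Object-based positioning with the integrity constraint applied."""
    return [
        apply_integrity_constraint(t, gt, params)
        for t in object_based_tiles(slide, gt, params, rect, dedupe)
    ]


def filter_empty_tiles(tiles: list[Tile]) -> tuple[list[Tile], float | None]:
    """Drop tiles whose mask has no diatom pixel.

    Returns ``(kept, empty_fraction)``; the fraction is None (undefined) for
    empty input.  In sparse slides most sliding-window tiles are empty, so
    this filter is what keeps the diatom/background class balance workable.
    """
    if not tiles:
        return [], None
    kept = [t for t in tiles if t.mask_patch.any()]
    return kept, (len(tiles) - len(kept)) / len(tiles)
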