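"""Core data model: slides, instance ground truth, partitioning, COCO export.

Coordinate convention: all rectangles are 0-based, half-open
``[r0, r1) x [c0, c1)`` in (row, column) order.  A :class:`Rect` therefore has
``height == r1 - r0`` and ``width == c1 - c0``, and two rectangles touch
without overlapping when one's ``r1`` equals the other's ``r0``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from skimage.measure import find_contours, label as cc_label


class Rect(NamedTuple):
    """Axis-aligned half-open rectangle [r0, r1) x [c0, c1)."""

    r0: int
    c0: int
    r1: int
    c1: int

    @property
    def height(self) -> int:
        return self.r1 - self.r0

    @property
    def width(self) -> int:
        return self.c1 - self.c0

    @property
    def area(self) -> int:
        return max(self.height, 0) * max(self.width, 0)

    def intersect(self, other: "Rect") -> "Rect":
        return Rect(
            max(self.r0, other.r0),
            max(self.c0, other.c0),
            min(self.r1, other.r1),
            min(self.c1, other.c1),
        )

    def is_empty(self) -> bool:
        return self.r1 <= self.r0 or self.c1 <= self.c0

    def contains(self, other: "Rect") -> bool:
        return (
            self.r0 <= other.r0
            and self.c0 <= other.c0
            and other.r1 <= self.r1
            and other.c1 <= self.c1
        )


@dataclass
class SlideImage:
    """A 2-D 8-bit grayscale raster in the slide coordinate frame."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("slide raster must be 2-D")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("slide raster must be at least 1x1")
        if self.pixels.dtype != np.uint8:
            raise ValueError("slide raster must be 8-bit (uint8)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def rect(self) -> Rect:
        return Rect(0, 0, self.pixels.shape[0], self.pixels.shape[1])


@dataclass
class Instance:
    """One relevant object: a binary mask stored locally within its bbox."""

    instance_id: int
    bbox: Rect
    mask: np.ndarray  # bool, shape (bbox.height, bbox.width)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.bbox.height, self.bbox.width):
            raise ValueError("instance mask shape does not match its bbox")
        if not self.mask.any():
            raise ValueError("instance mask must contain at least one pixel")

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    def pixels_in(self, rect: Rect) -> int:
        """Count instance pixels falling inside ``rect`` (slide frame)."""
        inter = self.bbox.intersect(rect)
        if inter.is_empty():
            return 0
        sub = self.mask[
            inter.r0 - self.bbox.r0 : inter.r1 - self.bbox.r0,
            inter.c0 - self.bbox.c0 : inter.c1 - self.bbox.c0,
        ]
        return int(sub.sum())

    def clipped(self, rect: Rect) -> "Instance | None":
        """Return a copy clipped to ``rect``, or None if nothing remains."""
        inter = self.bbox.intersect(rect)
        if inter.is_empty():
            return None
        sub = self.mask[
            inter.r0 - self.bbox.r0 : inter.r1 - self.bbox.r0,
            inter.c0 - self.bbox.c0 : inter.c1 - self.bbox.c0,
        ]
        if not sub.any():
            return None
        return Instance(self.instance_id, inter, sub.copy(), dict(self.provenance))


@dataclass
class GroundTruth:
    """Per-object instance masks over a slide, plus the derived binary mask.

    The class ontology is fixed: a pixel is "diatom" iff it belongs to some
    instance, otherwise "background".
    """

    shape: tuple[int, int]
    instances: list[Instance] = field(default_factory=list)

    classes = ("diatom", "background")

    def __post_init__(self) -> None:
        ids = [inst.instance_id for inst in self.instances]
        if len(ids) != len(set(ids)):
            raise ValueError("instance ids must be unique")
        frame = Rect(0, 0, self.shape[0], self.shape[1])
        for inst in self.instances:
            if not frame.contains(inst.bbox):
                raise ValueError(
                    f"instance {inst.instance_id} extends outside the raster"
                )

    @property
    def binary_mask(self) -> np.ndarray:
        """Union of all instance masks (bool, slide-shaped)."""
        out = np.zeros(self.shape, dtype=bool)
        for inst in self.instances:
            b = inst.bbox
            out[b.r0 : b.r1, b.c0 : b.c1] |= inst.mask
        return out

    def label_image(self) -> np.ndarray:
        """16-bit instance-label raster: 0 = background, k = instance k."""
        out = np.zeros(self.shape, dtype=np.uint16)
        for inst in self.instances:
            b = inst.bbox
            region = out[b.r0 : b.r1, b.c0 : b.c1]
            region[inst.mask] = inst.instance_id
        return out

    def mask_window(self, rect: Rect) -> np.ndarray:
        """Binary diatom mask restricted to a window (window-local frame)."""
        out = np.zeros((rect.height, rect.width), dtype=bool)
        for inst in self.instances:
            inter = inst.bbox.intersect(rect)
            if inter.is_empty():
                continue
            sub = inst.mask[
                inter.r0 - inst.bbox.r0 : inter.r1 - inst.bbox.r0,
                inter.c0 - inst.bbox.c0 : inter.c1 - inst.bbox.c0,
            ]
            out[
                inter.r0 - rect.r0 : inter.r1 - rect.r0,
                inter.c0 - rect.c0 : inter.c1 - rect.c0,
            ] |= sub
        return out


class PartitionError(ValueError):
    """Raised for degenerate partition regions or fractions."""


SECTION_ORDER = ("train", "validation", "evaluation")


@dataclass
class Partition:
    """Three contiguous non-overlapping strips of an annotated rectangle."""

    sections: dict[str, Rect]
    fractions: tuple[float, float, float]
    axis: str

    def __post_init__(self) -> None:
        rects = [self.sections[name] for name in SECTION_ORDER]
        total = sum(r.area for r in rects)
        union = Rect(
            min(r.r0 for r in rects),
            min(r.c0 for r in rects),
            max(r.r1 for r in rects),
            max(r.c1 for r in rects),
        )
        if total != union.area:
            raise PartitionError("sections must tile the region exactly")


def partition_slide(
    gt_region: Rect,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    axis: str = "rows",
) -> Partition:
    """Split a rectangle into train/validation/evaluation strips.

    Strips are contiguous along ``axis`` in the order train, validation,
    evaluation.  Integer strip extents follow the cumulative-floor rule:
    boundary k is placed at ``floor(sum(fractions[:k]) * extent)``, so realized
    areas match the targets up to one line of pixels.
    """
    if axis not in ("rows", "columns"):
        raise PartitionError(f"axis must be 'rows' or 'columns', got {axis!r}")
    if len(fractions) != 3:
        raise PartitionError("exactly three fractions are required")
    if any(f <= 0 for f in fractions):
        raise PartitionError(f"fractions must be positive, got {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise PartitionError(f"fractions must sum to 1, got {fractions}")
    extent = gt_region.height if axis == "rows" else gt_region.width
    if extent < 3:
        raise PartitionError("region too small for three non-empty strips")

    cuts = [0]
    acc = 0.0
    for f in fractions:
        acc += f
        cuts.append(int(np.floor(acc * extent + 1e-9)))
    cuts[-1] = extent
    if any(cuts[i + 1] - cuts[i] < 1 for i in range(3)):
        raise PartitionError(
            f"fractions {fractions} leave an empty strip on extent {extent}"
        )

    sections = {}
    for name, lo, hi in zip(SECTION_ORDER, cuts[:-1], cuts[1:]):
        if axis == "rows":
            sections[name] = Rect(
                gt_region.r0 + lo, gt_region.c0, gt_region.r0 + hi, gt_region.c1
            )
        else:
            sections[name] = Rect(
                gt_region.r0, gt_region.c0 + lo, gt_region.r1, gt_region.c0 + hi
            )
    return Partition(sections=sections, fractions=tuple(fractions), axis=axis)


def assign_instances(
    partition: Partition, gt: GroundTruth
) -> dict[str, GroundTruth]:
    """Assign each instance to the section holding the majority of its pixels.

    Ties go to the earlier section in train < validation < evaluation order.
    Output masks are clipped to their section's bounds; the slide frame is
    retained.
    """
    out: dict[str, list[Instance]] = {name: [] for name in SECTION_ORDER}
    for inst in gt.instances:
        counts = [inst.pixels_in(partition.sections[name]) for name in SECTION_ORDER]
        winner = SECTION_ORDER[int(np.argmax(counts))]  # argmax takes first on ties
        clipped = inst.clipped(partition.sections[winner])
        if clipped is None:
            # Majority section gets the instance even if clipping empties it
            # (cannot happen when the winner holds >= 1 pixel, which argmax
            # guarantees for any instance overlapping the region).
            continue
        out[winner].append(clipped)
    return {name: GroundTruth(gt.shape, out[name]) for name in SECTION_ORDER}


def clip_training_subset(
    section: Rect, gt: GroundTruth, fraction: float
) -> Rect:
    """Leftmost horizontal clip of ``section`` holding a target object share.

    Returns the smallest clip ``[r0, r1) x [c0, c)`` whose contained relevant
    object count is the smallest count >= ``fraction`` times the section's
    object count.  An object belongs to the clip when the majority of its
    pixels (ties toward the clip) lie inside it.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    members = [
        inst
        for inst in gt.instances
        if inst.pixels_in(section) * 2 >= inst.area  # majority-in-section
    ]
    if not members:
        raise ValueError("section contains no relevant objects")
    if fraction == 1.0:
        return section
    target = int(np.ceil(fraction * len(members) - 1e-9))

    # Column at which each object's majority first enters the left clip.
    entry_cols = []
    for inst in members:
        cols = np.zeros(inst.bbox.width, dtype=np.int64)
        cols += inst.mask.sum(axis=0)
        cum = np.cumsum(cols)
        need = int(np.ceil(inst.area / 2))
        k = int(np.searchsorted(cum, need))
        entry_cols.append(inst.bbox.c0 + k + 1)  # clip must extend past column
    entry_cols.sort()
    cut = max(entry_cols[target - 1], section.c0 + 1)
    cut = min(cut, section.c1)
    return Rect(section.r0, section.c0, section.r1, cut)


# ---------------------------------------------------------------------------
# COCO export / import
# ---------------------------------------------------------------------------

DIATOM_CATEGORY_ID = 1


class CocoError(ValueError):
    """Raised on malformed COCO documents or inconsistent tiles."""


def _mask_to_polygons(mask: np.ndarray) -> list[list[float]]:
    """Trace a binary mask into COCO xy polygons (outer rings and holes).

    Contours are extracted with marching squares at level 0.5 on a
    zero-padded copy, so single-pixel components yield valid polygons.
    Pixel (r, c) has its center at continuous coordinates (c + 0.5, r + 0.5);
    holes become additional polygons under COCO even-odd semantics.
    """
    padded = np.pad(mask.astype(float), 1)
    polygons = []
    for contour in find_contours(padded, 0.5):
        # (row, col) index space of the padded array -> COCO xy.
        xy = np.empty_like(contour)
        xy[:, 0] = contour[:, 1] - 1 + 0.5  # x
        xy[:, 1] = contour[:, 0] - 1 + 0.5  # y
        if len(xy) < 3:
            continue
        polygons.append([round(float(v), 3) for v in xy[:-1].ravel()])
    return polygons


def _polygons_to_mask(
    polygons: Sequence[Sequence[float]], height: int, width: int
) -> np.ndarray:
    """Rasterize COCO polygons with even-odd fill on pixel centers."""
    from matplotlib.path import Path

    out = np.zeros((height, width), dtype=bool)
    for poly in polygons:
        pts = np.asarray(poly, dtype=float).reshape(-1, 2)
        if len(pts) < 3:
            continue
        c0 = max(int(np.floor(pts[:, 0].min() - 1)), 0)
        c1 = min(int(np.ceil(pts[:, 0].max() + 1)), width)
        r0 = max(int(np.floor(pts[:, 1].min() - 1)), 0)
        r1 = min(int(np.ceil(pts[:, 1].max() + 1)), height)
        if r1 <= r0 or c1 <= c0:
            continue
        cols, rows = np.meshgrid(
            np.arange(c0, c1) + 0.5, np.arange(r0, r1) + 0.5
        )
        centers = np.column_stack([cols.ravel(), rows.ravel()])
        inside = Path(pts).contains_points(centers).reshape(r1 - r0, c1 - c0)
        out[r0:r1, c0:c1] ^= inside  # even-odd across polygons of one annot.
    return out


def export_coco(tiles: Iterable) -> dict:
    """Convert tiles into a COCO document (one annotation per component).

    Each contiguous foreground component of a tile's mask becomes one
    annotation with polygon segmentation, bbox ``[x, y, w, h]`` and exact
    pixel area.  The category list contains only "diatom".
    """
    images = []
    annotations = []
    ann_id = 1
    for img_id, tile in enumerate(tiles, start=1):
        h, w = tile.image_patch.shape
        if tile.mask_patch.shape != (h, w):
            raise CocoError(
                f"tile {img_id}: mask shape {tile.mask_patch.shape} does not "
                f"match image shape {(h, w)}"
            )
        images.append(
            {
                "id": img_id,
                "width": int(w),
                "height": int(h),
                "file_name": tile.name(),
            }
        )
        labels = cc_label(tile.mask_patch, connectivity=2)
        for comp in range(1, labels.max() + 1):
            comp_mask = labels == comp
            rows, cols = np.nonzero(comp_mask)
            polys = _mask_to_polygons(comp_mask)
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": img_id,
                    "category_id": DIATOM_CATEGORY_ID,
                    "segmentation": polys,
                    "area": int(comp_mask.sum()),
                    "bbox": [
                        float(cols.min()),
                        float(rows.min()),
                        float(cols.max() - cols.min() + 1),
                        float(rows.max() - rows.min() + 1),
                    ],
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    return {
        "images": images,
        "annotations": annotations,
        "categories": [
            {"id": DIATOM_CATEGORY_ID, "name": "diatom", "supercategory": "object"}
        ],
    }


def import_coco(document: dict | str) -> list[np.ndarray]:
    """Rasterize a COCO document back into per-image binary masks.

    Returns one bool mask per image record, in the document's image order.
    Polygons within one annotation combine with even-odd parity (holes);
    separate annotations combine by union.
    """
    if isinstance(document, str):
        try:
            document = json.loads(document)
        except json.JSONDecodeError as exc:
            raise CocoError(f"malformed COCO JSON: {exc}") from exc
    for key in ("images", "annotations", "categories"):
        if key not in document:
            raise CocoError(f"COCO document missing {key!r}")
    cat_ids = {c["name"]: c["id"] for c in document["categories"]}
    if "diatom" not in cat_ids:
        raise CocoError("COCO document has no 'diatom' category")
    diatom_id = cat_ids["diatom"]
    known = {c["id"] for c in document["categories"]}

    masks = {
        img["id"]: np.zeros((img["height"], img["width"]), dtype=bool)
        for img in document["images"]
    }
    for ann in document["annotations"]:
        if ann["category_id"] not in known:
            raise CocoError(f"annotation {ann.get('id')} has unknown category")
        if ann["category_id"] != diatom_id:
            continue
        if ann["image_id"] not in masks:
            raise CocoError(f"annotation {ann.get('id')} references unknown image")
        m = masks[ann["image_id"]]
        m |= _polygons_to_mask(ann["segmentation"], *m.shape)
    return [masks[img["id"]] for img in document["images"]]
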