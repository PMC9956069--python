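"""On-disk formats: TIFF rasters, instance-label images, JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .annotations import GroundTruth, Instance, Rect, SlideImage
from .tiling import Tile


def write_slide(path: str | Path, slide: SlideImage) -> None:
    tifffile.imwrite(path, slide.pixels, photometric="minisblack")


def read_slide(path: str | Path) -> SlideImage:
    return SlideImage(tifffile.imread(path))


def write_ground_truth(path: str | Path, gt: GroundTruth) -> None:
    """Instance-label TIFF (uint16) plus a JSON sidecar with bboxes."""
    path = Path(path)
    tifffile.imwrite(path, gt.label_image(), photometric="minisblack")
    sidecar = {
        "shape": list(gt.shape),
        "classes": list(gt.classes),
        "instances": [
            {
                "instance_id": inst.instance_id,
                "bbox": list(inst.bbox),
                "area": inst.area,
                "provenance": _jsonable(inst.provenance),
            }
            for inst in gt.instances
        ],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_ground_truth(path: str | Path) -> GroundTruth:
    labels = tifffile.imread(path)
    instances = []
    for k in np.unique(labels):
        if k == 0:
            continue
        rows, cols = np.nonzero(labels == k)
        bbox = Rect(int(rows.min()), int(cols.min()),
                    int(rows.max()) + 1, int(cols.max()) + 1)
        local = labels[bbox.r0 : bbox.r1, bbox.c0 : bbox.c1] == k
        instances.append(Instance(int(k), bbox, local))
    return GroundTruth(shape=labels.shape, instances=instances)


def write_tiles(out_dir: str | Path, tiles: list[Tile]) -> list[dict]:
    """Paired image/mask TIFFs per tile; returns the manifest entries."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for tile in tiles:
        stem = Path(tile.name()).stem
        img_path = out_dir / f"{stem}_image.tif"
        mask_path = out_dir / f"{stem}_mask.tif"
        tifffile.imwrite(img_path, tile.image_patch, photometric="minisblack")
        tifffile.imwrite(
            mask_path,
            tile.mask_patch.astype(np.uint8) * 255,
            photometric="minisblack",
        )
        entries.append(
            {
                "image": img_path.name,
                "mask": mask_path.name,
                "origin": list(tile.origin),
                "size": tile.size,
                "mask_pixels": int(tile.mask_patch.sum()),
                "provenance": _jsonable(tile.provenance),
            }
        )
    return entries


def write_score_matrix(path: str | Path, scores: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(scores, dtype=np.float32))


def write_binary_mask(path: str | Path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(mask, dtype=bool).astype(np.uint8) * 255)


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(_jsonable(manifest), indent=1))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
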