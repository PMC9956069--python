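"""Seeded generator of synthetic annotated slides.

Emulates bright-field virtual-slide imagery of cleaned diatom material:
sparse dark objects on a bright noisy background, surrounded by clutter that
a segmentation model must learn to ignore — sub-75% valve fragments, thin
girdle-band-like arcs, and amorphous debris blobs.  Only the intact objects
enter the ground truth; every distractor is rendered in the image but absent
from the mask, mirroring the definition of a relevant object as one that is
at least 75% complete.

All randomness flows from a single seeded generator; each placed shape draws
its parameters from that stream in a fixed order, so identical config + seed
yields bit-identical rasters and masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotations import GroundTruth, Instance, Rect, SlideImage


class ConfigError(ValueError):
    """Invalid synthetic-slide configuration; names the offending field."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic slide.

    Counts are numbers of shapes to place; ``n_objects`` are intact relevant
    objects (the only ones annotated), the rest are distractors.  Gray levels
    are 8-bit values; objects are darker than the background (bright-field).
    """

    width: int = 2048
    height: int = 2048
    n_objects: int = 12
    n_fragments: int = 6
    n_debris: int = 10
    n_bands: int = 4
    object_length_range: tuple[float, float] = (80.0, 260.0)
    object_aspect_range: tuple[float, float] = (1.2, 4.0)
    background_level: int = 220
    object_level_range: tuple[int, int] = (40, 140)
    noise_sd: float = 6.0
    seed: int = 0
    illumination_gradient: bool = False
    allow_overlap: bool = False
    striation_prob: float = 0.5

    def validate(self) -> None:
        for name in ("n_objects", "n_fragments", "n_debris", "n_bands"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.width < 1:
            raise ConfigError("width must be >= 1")
        if self.height < 1:
            raise ConfigError("height must be >= 1")
        lo, hi = self.object_length_range
        if not 0 < lo < hi:
            raise ConfigError("object_length_range must be a non-degenerate "
                              "positive interval")
        if hi > min(self.width, self.height):
            raise ConfigError("object_length_range exceeds the raster bounds")
        alo, ahi = self.object_aspect_range
        if not 1.0 <= alo < ahi:
            raise ConfigError("object_aspect_range must be non-degenerate "
                              "and >= 1")
        if not 0 <= self.background_level <= 255:
            raise ConfigError("background_level must be a gray value 0-255")
        glo, ghi = self.object_level_range
        if not 0 <= glo < ghi <= 255:
            raise ConfigError("object_level_range must be a non-degenerate "
                              "gray interval within 0-255")
        if ghi >= self.background_level:
            raise ConfigError("object_level_range must stay below "
                              "background_level (dark objects on bright field)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


def _shape_mask(
    length: float, width_px: float, angle: float, kind: str
) -> np.ndarray:
    """Render one rotated shape (ellipse or capsule) as a tight local mask."""
    half = length / 2
    pad = int(np.ceil(half)) + 2
    size = 2 * pad + 1
    yy, xx = np.mgrid[-pad : pad + 1, -pad : pad + 1].astype(float)
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * xx + sa * yy   # along the major axis
    v = -sa * xx + ca * yy  # across
    if kind == "ellipse":
        mask = (u / half) ** 2 + (v / (width_px / 2)) ** 2 <= 1.0
    else:  # capsule: segment of half-length (half - r) dilated by radius r
        r = width_px / 2
        seg = max(half - r, 0.0)
        du = np.clip(np.abs(u) - seg, 0, None)
        mask = du**2 + v**2 <= r**2
    assert mask.shape == (size, size)
    return mask


def _striate(patch_vals: np.ndarray, u: np.ndarray, period: float,
             depth: float) -> np.ndarray:
    """Periodic striation texture along the major axis (cheap valve look)."""
    mod = 1.0 + depth * np.sin(2 * np.pi * u / period)
    return patch_vals * mod


def _clip_to_fragment(mask: np.ndarray, rng: np.random.Generator,
                      max_keep: float = 0.70) -> np.ndarray:
    """Cut a full shape with a random chord, retaining < 75% of its area."""
    rows, cols = np.nonzero(mask)
    angle = rng.uniform(0, np.pi)
    proj = np.cos(angle) * cols + np.sin(angle) * rows
    keep_frac = rng.uniform(0.30, max_keep)
    cut = np.quantile(proj, keep_frac)
    out = mask.copy()
    out[np.nonzero(mask)[0][proj > cut], np.nonzero(mask)[1][proj > cut]] = False
    return out


def _tight(mask: np.ndarray) -> tuple[np.ndarray, int, int]:
    rows, cols = np.nonzero(mask)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    return mask[r0:r1, c0:c1], r0, c0


def _place(
    occupied: np.ndarray,
    local: np.ndarray,
    rng: np.random.Generator,
    allow_overlap: bool,
    margin: int = 2,
) -> tuple[int, int] | None:
    """Find a top-left position for a local mask; rejection sampling."""
    H, W = occupied.shape
    h, w = local.shape
    if h > H or w > W:
        return None
    # prefer a clear margin around the shape, then fall back to strict
    # mask-disjointness when the slide gets dense
    for _ in range(200):
        r = int(rng.integers(0, H - h + 1))
        c = int(rng.integers(0, W - w + 1))
        if allow_overlap:
            return r, c
        rl, cl = max(r - margin, 0), max(c - margin, 0)
        if not occupied[rl : r + h + margin, cl : c + w + margin].any():
            return r, c
    for _ in range(200):
        r = int(rng.integers(0, H - h + 1))
        c = int(rng.integers(0, W - w + 1))
        if not (occupied[r : r + h, c : c + w] & local).any():
            return r, c
    return None


def generate_slide(config: SyntheticConfig) -> tuple[SlideImage, GroundTruth]:
    """Generate a synthetic slide raster and its instance ground truth.

    Returns the 8-bit grayscale slide and a :class:`GroundTruth` with exactly
    ``config.n_objects`` instances (distractors are image-only).  Each
    instance carries a provenance record (shape kind, length, width, angle,
    gray level) for use as a test oracle.

    Raises :class:`ConfigError` for invalid configs, or a RuntimeError when
    the requested shapes cannot be placed disjointly (slide too crowded).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    H, W = config.height, config.width

    image = np.full((H, W), float(config.background_level))
    if config.illumination_gradient:
        gy = np.linspace(-8, 8, H)[:, None]
        gx = np.linspace(-8, 8, W)[None, :]
        image += gy + gx
    occupied = np.zeros((H, W), dtype=bool)
    instances: list[Instance] = []

    def paint(local: np.ndarray, r: int, c: int, level: float,
              striation: tuple[float, float] | None, angle: float) -> None:
        h, w = local.shape
        region = image[r : r + h, c : c + w]
        vals = np.full(local.shape, level)
        if striation is not None:
            yy, xx = np.mgrid[0:h, 0:w].astype(float)
            u = np.cos(angle) * xx + np.sin(angle) * yy
            vals = _striate(vals, u, *striation)
        region[local] = vals[local]
        occupied[r : r + h, c : c + w] |= local

    def draw_shape(length_range, aspect_range):
        length = rng.uniform(*length_range)
        aspect = rng.uniform(*aspect_range)
        width_px = max(length / aspect, 4.0)
        angle = rng.uniform(0, np.pi)
        kind = "ellipse" if rng.random() < 0.5 else "capsule"
        mask = _shape_mask(length, width_px, angle, kind)
        level = rng.uniform(*config.object_level_range)
        striation = None
        if rng.random() < config.striation_prob:
            striation = (rng.uniform(6, 14), rng.uniform(0.05, 0.15))
        return mask, dict(kind=kind, length=length, width=width_px,
                          angle=angle, level=level), striation

    # Intact relevant objects: the only annotated instances.
    for k in range(config.n_objects):
        mask, prov, striation = draw_shape(
            config.object_length_range, config.object_aspect_range
        )
        local, _, _ = _tight(mask)
        pos = _place(occupied, local, rng, config.allow_overlap)
        if pos is None:
            raise RuntimeError(
                f"could not place object {k + 1}/{config.n_objects}; "
                "slide too crowded for disjoint instances"
            )
        r, c = pos
        paint(local, r, c, prov["level"], striation, prov["angle"])
        instances.append(
            Instance(
                instance_id=k + 1,
                bbox=Rect(r, c, r + local.shape[0], c + local.shape[1]),
                mask=local.copy(),
                provenance=prov,
            )
        )

    # Fragment distractors: full shapes cut by a chord to < 75% area.
    frag_range = (config.object_length_range[0] * 0.4,
                  config.object_length_range[1] * 0.8)
    for _ in range(config.n_fragments):
        mask, prov, striation = draw_shape(frag_range,
                                           config.object_aspect_range)
        frag = _clip_to_fragment(mask, rng)
        if not frag.any():
            continue
        local, _, _ = _tight(frag)
        pos = _place(occupied, local, rng, config.allow_overlap)
        if pos is None:
            continue  # distractor counts are best-effort on crowded slides
        paint(local, *pos, prov["level"], striation, prov["angle"])

    # Debris: small irregular dark blobs (silt/clay stand-ins).
    for _ in range(config.n_debris):
        n_lobes = int(rng.integers(2, 5))
        size = rng.uniform(10, 40)
        pad = int(size) + 4
        canvas = np.zeros((2 * pad + 1, 2 * pad + 1), dtype=bool)
        for _ in range(n_lobes):
            mask = _shape_mask(rng.uniform(size * 0.4, size),
                               rng.uniform(size * 0.3, size * 0.8),
                               rng.uniform(0, np.pi), "ellipse")
            m, _, _ = _tight(mask)
            r = int(rng.integers(0, canvas.shape[0] - m.shape[0] + 1))
            c = int(rng.integers(0, canvas.shape[1] - m.shape[1] + 1))
            canvas[r : r + m.shape[0], c : c + m.shape[1]] |= m
        if not canvas.any():
            continue
        local, _, _ = _tight(canvas)
        level = rng.uniform(config.object_level_range[0],
                            config.background_level - 30)
        pos = _place(occupied, local, rng, config.allow_overlap)
        if pos is None:
            continue
        paint(local, *pos, level, None, 0.0)

    # Girdle-band distractors: thin arc segments.
    for _ in range(config.n_bands):
        radius = rng.uniform(40, 140)
        thickness = rng.uniform(2.5, 6.0)
        theta0 = rng.uniform(0, 2 * np.pi)
        span = rng.uniform(0.6 * np.pi, 1.4 * np.pi)
        pad = int(radius + thickness) + 2
        yy, xx = np.mgrid[-pad : pad + 1, -pad : pad + 1].astype(float)
        rad = np.hypot(xx, yy)
        ang = np.mod(np.arctan2(yy, xx) - theta0, 2 * np.pi)
        band = (np.abs(rad - radius) <= thickness / 2) & (ang <= span)
        if not band.any():
            continue
        local, _, _ = _tight(band)
        level = rng.uniform(*config.object_level_range)
        pos = _place(occupied, local, rng, config.allow_overlap)
        if pos is None:
            continue
        paint(local, *pos, level, None, 0.0)

    if config.noise_sd > 0:
        image += rng.normal(0.0, config.noise_sd, size=image.shape)
    slide = SlideImage(np.clip(np.rint(image), 0, 255).astype(np.uint8))
    return slide, GroundTruth(shape=(H, W), instances=instances)
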