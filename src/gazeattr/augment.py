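"""Scanpath augmentation: duration rescaling, replication with jitter, fixation maps.

Short scanpaths (sometimes only two fixations) carry little signal for a
sequence model.  The augmentation densifies them: per-scanpath durations are
linearly rescaled to the integer range [1, 100], each fixation is replicated
as many times as its scaled duration, and every replica receives an
independent uniform integer shift in [-jitter_radius, +jitter_radius] on both
axes (then clipped to the image bounds).  Fixation maps mark every pixel
within a fixed radius of an original (pre-jitter) fixation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import Fixation, Scanpath


@dataclass
class AugmentationParams:
    scale_min: int = 1
    scale_max: int = 100
    jitter_radius: int = 10
    fixmap_radius: float = 10.0
    count_map: bool = False  # if True, fixation maps count overlapping disks

    def __post_init__(self) -> None:
        if self.scale_min >= self.scale_max:
            raise ValueError("scale_min must be < scale_max")
        if self.jitter_radius < 0 or self.fixmap_radius < 0:
            raise ValueError("radii must be non-negative")


def rescale_durations(scanpath: Scanpath, params: AugmentationParams | None = None) -> np.ndarray:
    """Rescale a scanpath's millisecond durations to integers in [scale_min, scale_max].

    The map is linear over the scanpath's own duration range:
    d' = round(lo + (hi - lo) * (d - d_min) / (d_max - d_min)), with
    round-half-away-from-zero so the midpoint of the range lands on the upper
    integer.  When all durations are equal the map is undefined; every
    duration is then set to the midpoint of the output range.
    """
    params = params or AugmentationParams()
    d = scanpath.durations()
    if d.size == 0:
        raise ValueError("empty scanpath")
    lo, hi = params.scale_min, params.scale_max
    d_min, d_max = d.min(), d.max()
    if d_max == d_min:
        mid = (lo + hi) // 2
        return np.full(d.shape, mid, dtype=int)
    scaled = lo + (hi - lo) * (d - d_min) / (d_max - d_min)
    return np.floor(scaled + 0.5).astype(int)


def replicate_and_jitter(
    scanpath: Scanpath,
    image_shape: tuple[int, int] | None,
    params: AugmentationParams,
    rng: np.random.Generator,
) -> Scanpath:
    """Densify a scanpath by duration-proportional replication with spatial jitter.

    Fixation i yields d'_i replicas (d' from :func:`rescale_durations`); each
    replica is shifted by an independent integer offset uniform in
    [-jitter_radius, +jitter_radius] per axis and clipped to the image bounds.
    Replica order follows fixation order, so the output length is sum(d').
    """
    if image_shape is None:
        raise ValueError("image_shape is required to clip jittered fixations")
    h, w = image_shape
    scaled = rescale_durations(scanpath, params)
    r = params.jitter_radius
    out: list[Fixation] = []
    for fix, n_rep in zip(scanpath.fixations, scaled):
        if r > 0:
            dx = rng.integers(-r, r + 1, size=n_rep)
            dy = rng.integers(-r, r + 1, size=n_rep)
        else:
            dx = dy = np.zeros(n_rep, dtype=int)
        xs = np.clip(fix.x + dx, 0, w - 1)
        ys = np.clip(fix.y + dy, 0, h - 1)
        out.extend(Fixation(float(x), float(y), fix.duration) for x, y in zip(xs, ys))
    return Scanpath(out, scanpath.participant_index, scanpath.image_id, scanpath.group_label)


def render_fixation_map(
    scanpath: Scanpath,
    image_shape: tuple[int, int],
    radius: float = 10.0,
    count: bool = False,
) -> np.ndarray:
    """Rasterize a scanpath into an H x W fixation map.

    Pixel (u, v) is set iff some fixation (x, y) satisfies
    (u - x)^2 + (v - y)^2 <= radius^2 (Euclidean disk, original fixations).
    With ``count=True`` the map counts covering disks instead of being binary.
    The result is invariant to fixation order and idempotent in the binary case.
    """
    h, w = int(image_shape[0]), int(image_shape[1])
    if h < 1 or w < 1:
        raise ValueError(f"invalid image shape {image_shape}")
    out = np.zeros((h, w), dtype=np.int32 if count else np.uint8)
    r = float(radius)
    for fix in scanpath.fixations:
        x0, y0 = float(fix.x), float(fix.y)
        # bounding box of the disk, clipped to the raster
        u_lo = max(0, int(np.floor(x0 - r)))
        u_hi = min(w - 1, int(np.ceil(x0 + r)))
        v_lo = max(0, int(np.floor(y0 - r)))
        v_hi = min(h - 1, int(np.ceil(y0 + r)))
        if u_lo > u_hi or v_lo > v_hi:
            continue
        us = np.arange(u_lo, u_hi + 1)
        vs = np.arange(v_lo, v_hi + 1)
        disk = (us[None, :] - x0) ** 2 + (vs[:, None] - y0) ** 2 <= r * r
        if count:
            out[v_lo : v_hi + 1, u_lo : u_hi + 1] += disk.astype(np.int32)
        else:
            out[v_lo : v_hi + 1, u_lo : u_hi + 1] |= disk.astype(np.uint8)
    return out


def augment_records(records, params: AugmentationParams, rng: np.random.Generator) -> None:
    """Attach a replicated-and-jittered scanpath to each record, in place.

    Fixation maps are left untouched: they are rendered from the original
    fixations, not from augmented replicas.
    """
    for rec in records:
        rec.augmented_scanpath = replicate_and_jitter(rec.scanpath, rec.image.shape, params, rng)


def save_fixation_map_png(fixmap: np.ndarray, path) -> None:
    """Write a binary fixation map as an 8-bit PNG (0/255)."""
    from PIL import Image

    Image.fromarray((fixmap > 0).astype(np.uint8) * 255).save(path)
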