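"""Synthetic desk-scale gaze data with a planted, recoverable class signal.

The generator emulates the structure of aggregated child eye-tracking data:
per-image, per-group scanpath files in the four-column dialect, stimulus
rasters in three categories (people / objects / landscapes), variable-length
fixation sequences (as short as two fixations) with log-normal millisecond
durations, and optional label noise.

The class signal mirrors the clinical finding the classifier is meant to
exploit: on "people" images each stimulus carries a *social region* (a
high-contrast disk), and TD viewers fixate inside it with higher probability
(default 0.7) than ASD-like viewers (default 0.3).  On non-people images both
groups follow the same spatial law, so only people images carry signal — which
gives category-level attribution a ground truth to recover.

Everything is written to disk (PNG stimuli, scanpath text files, manifest
CSV) and read back through the package's own readers, so the file round-trip
is exercised, not bypassed.
"""

from __future__ import annotations

import json
import math
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image

from . import io as gio
from .augment import AugmentationParams, augment_records
from .types import SampleRecord, Scanpath, StimulusImage


@dataclass
class SyntheticSpec:
    """Generator parameters; defaults define the standard desk-scale corpus."""

    n_images: int = 30
    n_participants_per_group: int = 5
    image_size: tuple[int, int] = (64, 64)  # (H, W)
    category_mix: dict = field(
        default_factory=lambda: {"people": 1 / 3, "objects": 1 / 3, "landscapes": 1 / 3}
    )
    p_social_td: float = 0.7
    p_social_asd: float = 0.3
    fixations_min: int = 2
    fixations_max: int = 20
    duration_mu: float = math.log(250.0)  # log-normal location, ms
    duration_sigma: float = 0.5
    label_noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_social_asd <= 1.0 and 0.0 <= self.p_social_td <= 1.0):
            raise ValueError("social-region probabilities must be in [0, 1]")
        if self.p_social_td <= self.p_social_asd:
            raise ValueError("the planted effect requires p_social_td > p_social_asd")
        if self.fixations_min < 2 or self.fixations_max < self.fixations_min:
            raise ValueError("invalid fixation-count range")
        if not 0.0 <= self.label_noise_rate < 1.0:
            raise ValueError("label_noise_rate must be in [0, 1)")
        total = sum(self.category_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError("category mix must sum to 1")


@dataclass
class SocialRegion:
    """Disk marking the socially relevant area of a people image."""

    cx: float
    cy: float
    radius: float

    def contains(self, x: float, y: float) -> bool:
        return (x - self.cx) ** 2 + (y - self.cy) ** 2 <= self.radius**2


def _image_rng(spec: SyntheticSpec, image_index: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, 1, image_index])


def category_allocation(spec: SyntheticSpec) -> list[str]:
    """Category of every image index, fixed by (spec, seed).

    Like a curated stimulus set, the corpus holds an exact number of images
    per category — the largest-remainder apportionment of ``category_mix``
    over ``n_images`` — and the assignment of categories to image indices is
    a seed-determined permutation.
    """
    cats = sorted(spec.category_mix)
    quotas = np.array([spec.category_mix[c] * spec.n_images for c in cats])
    counts = np.floor(quotas).astype(int)
    remainder = np.argsort(-(quotas - counts))
    for i in range(spec.n_images - counts.sum()):
        counts[remainder[i % len(cats)]] += 1
    assignment = [c for c, n in zip(cats, counts) for _ in range(n)]
    perm = np.random.default_rng([spec.seed, 0]).permutation(spec.n_images)
    return [assignment[i] for i in np.argsort(perm)]


def generate_stimulus(
    spec: SyntheticSpec, image_index: int, rng: Optional[np.random.Generator] = None
) -> tuple[StimulusImage, Optional[SocialRegion]]:
    """Deterministic-by-(seed, index) stimulus with a category-specific texture.

    People images carry a bright social-region disk over a textured body hint;
    objects are scattered rectangles; landscapes a smooth gradient.  Only
    people images return a social region.
    """
    rng = rng if rng is not None else _image_rng(spec, image_index)
    h, w = spec.image_size
    category = category_allocation(spec)[image_index]
    img = rng.normal(0.45, 0.05, size=(h, w))
    region: Optional[SocialRegion] = None
    yy, xx = np.mgrid[0:h, 0:w]
    if category == "landscapes":
        img += 0.35 * (yy / max(h - 1, 1)) - 0.15
        img += 0.08 * np.sin(2 * np.pi * xx / w * rng.integers(1, 4))
    elif category == "objects":
        for _ in range(int(rng.integers(3, 7))):
            rw, rh = rng.integers(w // 8, w // 3), rng.integers(h // 8, h // 3)
            x0, y0 = rng.integers(0, w - rw), rng.integers(0, h - rh)
            img[y0 : y0 + rh, x0 : x0 + rw] = rng.uniform(0.1, 0.9)
    else:  # people
        # photographer bias: faces cluster near the frame center in photo sets
        cx = rng.uniform(0.35 * w, 0.65 * w)
        cy = rng.uniform(0.35 * h, 0.65 * h)
        radius = min(h, w) / 8.0
        region = SocialRegion(cx, cy, radius)
        body = (xx - cx) ** 2 / (0.2 * w) ** 2 + (yy - (cy + 2 * radius)) ** 2 / (0.35 * h) ** 2 <= 1.0
        img[body] = 0.25
        face = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
        img[face] = 0.95
    img = np.clip(img, 0.0, 1.0)
    stimulus = StimulusImage(
        pixels=(img * 255).astype(np.uint8), image_id=f"img_{image_index:03d}", category=category
    )
    return stimulus, region


def _uniform_in_disk(rng: np.random.Generator, region: SocialRegion) -> tuple[float, float]:
    r = region.radius * np.sqrt(rng.random())
    theta = rng.uniform(0, 2 * np.pi)
    return region.cx + r * np.cos(theta), region.cy + r * np.sin(theta)


def generate_scanpath(
    spec: SyntheticSpec,
    image: StimulusImage,
    region: Optional[SocialRegion],
    group_label: str,
    participant_index: int,
    rng: np.random.Generator,
) -> Scanpath:
    """One participant's fixation sequence on one stimulus.

    Fixation count is uniform over [fixations_min, fixations_max].  On people
    images each fixation lands inside the social region with the group's
    probability (uniform within the disk), else uniform over the image;
    non-people images use the uniform law for both groups.  Durations are
    i.i.d. log-normal milliseconds.
    """
    h, w = image.shape
    n_fix = int(rng.integers(spec.fixations_min, spec.fixations_max + 1))
    p_social = {"TD": spec.p_social_td, "ASD": spec.p_social_asd}[group_label]
    from .types import Fixation

    fixations = []
    for _ in range(n_fix):
        if region is not None and rng.random() < p_social:
            x, y = _uniform_in_disk(rng, region)
            x, y = float(np.clip(x, 0, w - 1)), float(np.clip(y, 0, h - 1))
        else:
            # uniform over the image *outside* the region, so the in-region
            # rate equals the group's p_social exactly
            while True:
                x, y = float(rng.uniform(0, w - 1)), float(rng.uniform(0, h - 1))
                if region is None or not region.contains(x, y):
                    break
        duration = float(rng.lognormal(spec.duration_mu, spec.duration_sigma))
        # one decimal: eye trackers report sub-pixel gaze positions
        fixations.append(Fixation(round(x, 1), round(y, 1), round(duration, 1)))
    return Scanpath(fixations, participant_index, image.image_id, group_label)


def write_corpus(spec: SyntheticSpec, out_dir) -> Path:
    """Generate and write the full corpus (stimuli, scanpath files, manifests).

    Layout: ``stimuli/<image_id>.png``, ``scanpaths/<image_id>_<GROUP>.txt``,
    ``manifest.csv``, ``ground_truth.json``.  Returns the manifest path.
    """
    out_dir = Path(out_dir)
    (out_dir / "stimuli").mkdir(parents=True, exist_ok=True)
    (out_dir / "scanpaths").mkdir(parents=True, exist_ok=True)

    manifest_rows = []
    truth: dict = {
        "spec": {**asdict(spec), "image_size": list(spec.image_size)},
        "categories": {},
        "social_regions": {},
        "true_labels": {},
        "flipped_sample_ids": [],
    }
    for j in range(spec.n_images):
        stimulus, region = generate_stimulus(spec, j)
        img_path = f"stimuli/{stimulus.image_id}.png"
        Image.fromarray(stimulus.pixels).save(out_dir / img_path)
        truth["categories"][stimulus.image_id] = stimulus.category
        if region is not None:
            truth["social_regions"][stimulus.image_id] = asdict(region)
        row = {"image_id": stimulus.image_id, "image_path": img_path, "category": stimulus.category}
        for group in ("ASD", "TD"):
            sps = []
            for p in range(spec.n_participants_per_group):
                rng = np.random.default_rng([spec.seed, 2, j, p, 0 if group == "ASD" else 1])
                sps.append(generate_scanpath(spec, stimulus, region, group, p, rng))
            sp_path = f"scanpaths/{stimulus.image_id}_{group}.txt"
            gio.write_aggregated_scanpaths(sps, out_dir / sp_path)
            row[f"{group.lower()}_scanpaths"] = sp_path
            for sp in sps:
                sid = f"{stimulus.image_id}:{group}:p{sp.participant_index}"
                truth["true_labels"][sid] = sp.label
        manifest_rows.append(row)

    import pandas as pd

    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)

    # label noise: flip exactly round(rate * N) uniformly chosen records
    all_ids = sorted(truth["true_labels"])
    n_flips = int(math.floor(spec.label_noise_rate * len(all_ids) + 0.5))
    if n_flips:
        flip_rng = np.random.default_rng([spec.seed, 3])
        flipped = flip_rng.choice(len(all_ids), size=n_flips, replace=False)
        truth["flipped_sample_ids"] = sorted(all_ids[i] for i in flipped)
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return manifest_path


def build_dataset(
    spec: SyntheticSpec,
    out_dir=None,
    augment: bool = False,
    augmentation_params: AugmentationParams | None = None,
) -> tuple[list[SampleRecord], dict]:
    """Generate the corpus, load it back through the file readers, apply noise.

    Returns (records, ground_truth).  Label flips listed in the ground truth
    are applied to the returned records' labels (the scanpath keeps its true
    viewing group).  With ``augment=True`` each record also gets its
    replicated-and-jittered scanpath.
    """
    tmp = None
    if out_dir is None:
        tmp = tempfile.TemporaryDirectory(prefix="gazeattr_synth_")
        out_dir = tmp.name
    try:
        manifest_path = write_corpus(spec, out_dir)
        records, _reports = gio.load_dataset(manifest_path)
        truth = json.loads((Path(out_dir) / "ground_truth.json").read_text())
        flipped = set(truth["flipped_sample_ids"])
        for rec in records:
            if rec.sample_id in flipped:
                rec.label = 1 - rec.label
        if augment:
            params = augmentation_params or AugmentationParams()
            augment_records(records, params, np.random.default_rng([spec.seed, 4]))
        return records, truth
    finally:
        if tmp is not None:
            tmp.cleanup()
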