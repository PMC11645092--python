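"""Core domain containers for gaze-based classification.

A *scanpath* is the time-ordered fixation sequence one participant produced on
one stimulus image; an aggregated scanpath file concatenates the scanpaths of
every participant in one diagnostic group (ASD or TD) for one image, with a
per-participant fixation index that restarts at 0 for each new participant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Class label convention: ASD = 1 (positive class), TD = 0.
ASD, TD = 1, 0

GROUP_TO_LABEL = {"ASD": ASD, "TD": TD}
LABEL_TO_GROUP = {ASD: "ASD", TD: "TD"}

#: Closed stimulus-category vocabulary; unknown tags map to "other".
CATEGORIES = ("people", "objects", "landscapes", "other")


@dataclass(frozen=True)
class Fixation:
    """One fixation: pixel position (origin top-left, y down) and duration in ms."""

    x: float
    y: float
    duration: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite fixation coordinates ({self.x}, {self.y})")
        if not (math.isfinite(self.duration) and self.duration > 0):
            raise ValueError(f"fixation duration must be positive, got {self.duration}")


@dataclass
class Scanpath:
    """Ordered fixation sequence of one participant on one image."""

    fixations: list[Fixation]
    participant_index: int
    image_id: str
    group_label: str  # "ASD" | "TD"

    def __post_init__(self) -> None:
        if len(self.fixations) < 1:
            raise ValueError("a scanpath needs at least one fixation")
        if self.group_label not in GROUP_TO_LABEL:
            raise ValueError(f"unknown group label {self.group_label!r}")

    def __len__(self) -> int:
        return len(self.fixations)

    @property
    def label(self) -> int:
        return GROUP_TO_LABEL[self.group_label]

    def xy(self) -> np.ndarray:
        """Fixation coordinates as an (n, 2) float array, columns (x, y)."""
        return np.array([[f.x, f.y] for f in self.fixations], dtype=float)

    def durations(self) -> np.ndarray:
        return np.array([f.duration for f in self.fixations], dtype=float)


@dataclass
class StimulusImage:
    """A stimulus raster with an identifier and optional category tag."""

    pixels: np.ndarray  # H x W or H x W x C, values in [0, 1] or uint8
    image_id: str
    category: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pixels.ndim not in (2, 3):
            raise ValueError("stimulus pixels must be HxW or HxWxC")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("stimulus must have positive height and width")
        if self.category is not None and self.category not in CATEGORIES:
            self.category = "other"

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class SampleRecord:
    """One classification unit: stimulus + fixation map + scanpath + label."""

    image: StimulusImage
    fixation_map: np.ndarray  # H x W, binary {0, 1}
    scanpath: Scanpath
    label: int  # ASD=1, TD=0
    participant_index: int
    image_id: str
    sample_id: str = field(default="")
    augmented_scanpath: Optional[Scanpath] = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (TD) or 1 (ASD)")
        if self.fixation_map.shape != self.image.shape:
            raise ValueError(
                f"fixation map shape {self.fixation_map.shape} does not match "
                f"image shape {self.image.shape}"
            )
        if not self.sample_id:
            group = LABEL_TO_GROUP[self.label]
            self.sample_id = f"{self.image_id}:{group}:p{self.participant_index}"
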