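"""Reading and writing aggregated scanpath files and dataset manifests.

The aggregated dialect has four columns per row — within-participant fixation
index, x, y, duration (ms) — and a new participant's scanpath starts at every
row whose index is 0.  The delimiter (comma, tab, or whitespace) is
auto-detected and recorded in the parse report.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from PIL import Image

from .types import GROUP_TO_LABEL, Fixation, SampleRecord, Scanpath, StimulusImage

PathLike = Union[str, Path]


class ScanpathIOError(Exception):
    """Base class for scanpath file errors."""


class MalformedFileError(ScanpathIOError):
    """The file does not follow the aggregated dialect (e.g. first index != 0)."""


class ScanpathParseError(ScanpathIOError):
    """A cell failed to parse; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class EmptyInputError(ScanpathIOError):
    """The file contains no data rows."""


@dataclass
class ParseReport:
    """Bookkeeping from one aggregated-file read."""

    path: str
    delimiter: str  # "comma" | "tab" | "whitespace"
    n_rows: int = 0
    n_scanpaths: int = 0
    out_of_bounds: list[tuple[int, float, float]] = field(default_factory=list)
    # (row number, x, y) for fixations outside the image bounds; kept, not dropped


def _detect_delimiter(first_line: str) -> str:
    if "," in first_line:
        return "comma"
    if "\t" in first_line:
        return "tab"
    return "whitespace"


_SPLITTERS = {"comma": re.compile(r"\s*,\s*"), "tab": re.compile(r"\t"), "whitespace": re.compile(r"\s+")}


def read_aggregated_scanpaths(
    path: PathLike,
    group_label: str,
    image_id: str,
    image_shape: Optional[tuple[int, int]] = None,
) -> tuple[list[Scanpath], ParseReport]:
    """Decompose one aggregated scanpath file into per-participant scanpaths.

    Rows are split into maximal runs starting at each index-0 row; the number
    of scanpaths returned equals the number of index-0 rows, and concatenating
    the returned scanpaths reproduces the file's rows in order.

    Parameters
    ----------
    path
        Aggregated four-column file (index, x, y, duration).
    group_label
        "ASD" or "TD"; copied onto every returned scanpath.
    image_id
        Stimulus identifier the file belongs to.
    image_shape
        Optional (H, W); fixations outside the bounds are flagged in the parse
        report but kept.

    Returns
    -------
    (scanpaths, report)
    """
    if group_label not in GROUP_TO_LABEL:
        raise ValueError(f"unknown group label {group_label!r}")
    path = Path(path)
    lines = path.read_text().splitlines()
    data_lines = [(i + 1, ln.strip()) for i, ln in enumerate(lines) if ln.strip()]
    if not data_lines:
        raise EmptyInputError(f"{path} contains no data rows")

    delimiter = _detect_delimiter(data_lines[0][1])
    splitter = _SPLITTERS[delimiter]
    report = ParseReport(path=str(path), delimiter=delimiter)

    rows: list[tuple[int, float, float, float]] = []
    for lineno, line in data_lines:
        parts = [p for p in splitter.split(line) if p != ""]
        if len(parts) != 4:
            raise ScanpathParseError(
                f"expected 4 columns (index, x, y, duration), got {len(parts)}", lineno
            )
        try:
            idx = int(float(parts[0]))
            x, y, dur = float(parts[1]), float(parts[2]), float(parts[3])
        except ValueError as exc:
            raise ScanpathParseError(f"non-numeric cell in {parts!r}", lineno) from exc
        if idx < 0:
            raise ScanpathParseError(f"negative fixation index {idx}", lineno)
        rows.append((idx, x, y, dur))
        if image_shape is not None:
            h, w = image_shape
            if not (0 <= x < w and 0 <= y < h):
                report.out_of_bounds.append((lineno, x, y))

    if rows[0][0] != 0:
        raise MalformedFileError(
            f"{path}: first row has index {rows[0][0]}, expected 0"
        )

    scanpaths: list[Scanpath] = []
    current: list[Fixation] = []
    participant = -1
    for idx, x, y, dur in rows:
        if idx == 0:
            if current:
                scanpaths.append(
                    Scanpath(current, participant, image_id, group_label)
                )
            participant += 1
            current = []
        current.append(Fixation(x, y, dur))
    scanpaths.append(Scanpath(current, participant, image_id, group_label))

    report.n_rows = len(rows)
    report.n_scanpaths = len(scanpaths)
    return scanpaths, report


def write_aggregated_scanpaths(scanpaths: Sequence[Scanpath], path: PathLike) -> None:
    """Write scanpaths back to the aggregated four-column dialect (comma)."""
    path = Path(path)
    lines = []
    for sp in scanpaths:
        for i, f in enumerate(sp.fixations):
            lines.append(f"{i},{_fmt(f.x)},{_fmt(f.y)},{_fmt(f.duration)}")
    path.write_text("\n".join(lines) + "\n")


def write_individual_scanpath(record_or_scanpath, path: PathLike) -> None:
    """Write a single scanpath as a three-column (x, y, duration) file.

    ``read_individual_scanpath`` round-trips it; reading the same data through
    ``read_aggregated_scanpaths`` after prepending indexes yields one scanpath.
    """
    sp = record_or_scanpath.scanpath if isinstance(record_or_scanpath, SampleRecord) else record_or_scanpath
    path = Path(path)
    lines = [f"{_fmt(f.x)},{_fmt(f.y)},{_fmt(f.duration)}" for f in sp.fixations]
    path.write_text("\n".join(lines) + "\n")


def read_individual_scanpath(
    path: PathLike, group_label: str, image_id: str, participant_index: int = 0
) -> Scanpath:
    """Read a three-column (x, y, duration) file written by ``write_individual_scanpath``."""
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise EmptyInputError(f"{path} contains no data rows")
    fixations = []
    for lineno, line in enumerate(lines, start=1):
        parts = [p for p in _SPLITTERS[_detect_delimiter(line)].split(line) if p]
        if len(parts) != 3:
            raise ScanpathParseError(f"expected 3 columns, got {len(parts)}", lineno)
        try:
            fixations.append(Fixation(float(parts[0]), float(parts[1]), float(parts[2])))
        except ValueError as exc:
            raise ScanpathParseError(f"non-numeric cell in {parts!r}", lineno) from exc
    return Scanpath(fixations, participant_index, image_id, group_label)


def _fmt(v: float) -> str:
    """Render numbers compactly and stably (integers without a trailing .0)."""
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def pair_with_stimuli(
    scanpaths: Sequence[Scanpath],
    images: Mapping[str, StimulusImage],
    fixmap_radius: float = 10.0,
) -> list[SampleRecord]:
    """Attach each scanpath to its stimulus and render its fixation map.

    One SampleRecord is produced per scanpath; fixation content is never
    modified.  The fixation map marks pixels within ``fixmap_radius`` of any
    original fixation.
    """
    from .augment import render_fixation_map  # local import avoids a cycle

    records = []
    for sp in scanpaths:
        if sp.image_id not in images:
            raise KeyError(f"no stimulus image for image_id {sp.image_id!r}")
        img = images[sp.image_id]
        fixmap = render_fixation_map(sp, img.shape, radius=fixmap_radius)
        records.append(
            SampleRecord(
                image=img,
                fixation_map=fixmap,
                scanpath=sp,
                label=sp.label,
                participant_index=sp.participant_index,
                image_id=sp.image_id,
            )
        )
    return records


def load_stimulus_image(path: PathLike, image_id: str, category: Optional[str] = None) -> StimulusImage:
    """Load a PNG/JPEG stimulus as a float raster in [0, 1]."""
    arr = np.asarray(Image.open(path), dtype=np.float64) / 255.0
    return StimulusImage(pixels=arr, image_id=image_id, category=category)


MANIFEST_COLUMNS = ["image_id", "image_path", "category", "asd_scanpaths", "td_scanpaths"]


def load_dataset(manifest_path: PathLike, fixmap_radius: float = 10.0) -> tuple[list[SampleRecord], list[ParseReport]]:
    """Load a full dataset from a manifest CSV.

    The manifest maps image_id -> image path, category, and the per-group
    aggregated scanpath files (paths relative to the manifest's directory).
    """
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest is missing columns {sorted(missing)}")

    records: list[SampleRecord] = []
    reports: list[ParseReport] = []
    for row in manifest.itertuples(index=False):
        image = load_stimulus_image(root / row.image_path, str(row.image_id), row.category)
        for group, col in (("ASD", row.asd_scanpaths), ("TD", row.td_scanpaths)):
            if pd.isna(col):
                continue
            sps, report = read_aggregated_scanpaths(
                root / col, group, str(row.image_id), image_shape=image.shape
            )
            reports.append(report)
            records.extend(pair_with_stimuli(sps, {image.image_id: image}, fixmap_radius))
    return records, reports
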