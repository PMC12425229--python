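"""Data model and readers/writers for annotated tandem-reporter time-lapse data.

The on-disk layout mirrors the public CELLULAR-style convention: one
single-channel TIFF per fluorescence/transmitted-light channel per time
point, one binary mask file per cell, a bounding-box table (absolute-pixel
CSV or YOLO-normalized txt), and a per-cell class-label CSV.  Boxes use
0-based half-open pixel coordinates ``[x0, x1) x [y0, y1)`` internally.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

import numpy as np
import tifffile

CHANNELS = ("green", "red", "transmitted")
LABELS = ("basal", "activated", "unidentified")
CONDITIONS = ("fed", "starved")

#: numeric class index used in YOLO-dialect box files, fixed class order
LABEL_TO_CLASS = {"basal": 0, "activated": 1, "unidentified": 2}
CLASS_TO_LABEL = {v: k for k, v in LABEL_TO_CLASS.items()}


class CellularIOError(ValueError):
    """Raised on malformed annotation inputs (bad labels, count mismatches...)."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, 0-based, half-open: pixels with x0 <= x < x1, y0 <= y < y1."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self):
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise CellularIOError(f"degenerate box {self!r}: need x0<x1 and y0<y1")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x0, self.y0, self.x1, self.y1)


@dataclass
class ChannelImage:
    """One channel's 2-D intensity image; intensities finite and >= 0."""

    pixels: np.ndarray
    channel: str

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise CellularIOError("channel image must be 2-D with both dims >= 1")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise CellularIOError("channel intensities must be finite and >= 0")
        if self.channel not in CHANNELS:
            raise CellularIOError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")


@dataclass
class CellRecord:
    """One annotated cell: full-frame binary mask, box, and autophagy class."""

    cell_id: int
    mask: np.ndarray
    box: BoundingBox
    label: str

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.sum() < 1:
            raise CellularIOError(f"cell {self.cell_id}: mask has no foreground pixels")
        if self.label not in LABELS:
            raise CellularIOError(
                f"cell {self.cell_id}: invalid label {self.label!r}; expected one of {LABELS}"
            )


@dataclass
class AnnotatedFrame:
    """One time point: the three channel images plus per-cell annotations."""

    timepoint: int
    channels: dict[str, ChannelImage]
    cells: list[CellRecord] = field(default_factory=list)

    def __post_init__(self):
        if set(self.channels) != set(CHANNELS):
            raise CellularIOError(f"frame needs exactly channels {CHANNELS}")
        shapes = {c.pixels.shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise CellularIOError("all channels must share one shape")
        ids = [c.cell_id for c in self.cells]
        if len(ids) != len(set(ids)):
            raise CellularIOError("cell_ids must be unique within a frame")
        h, w = self.shape
        for c in self.cells:
            if c.mask.shape != (h, w):
                raise CellularIOError(f"cell {c.cell_id}: mask shape differs from frame shape")
            if not (0 <= c.box.x0 and c.box.x1 <= w and 0 <= c.box.y0 and c.box.y1 <= h):
                raise CellularIOError(f"cell {c.cell_id}: box {c.box} outside frame bounds")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).pixels.shape

    def merged_rgb(self) -> np.ndarray:
        """(H, W, 3) float image with red/green fluorescence in R/G planes."""
        h, w = self.shape
        rgb = np.zeros((h, w, 3), dtype=np.float64)
        rgb[..., 0] = self.channels["red"].pixels
        rgb[..., 1] = self.channels["green"].pixels
        return rgb


@dataclass
class Sequence:
    """Five frames of one sample under one condition."""

    frames: list[AnnotatedFrame]
    condition: str
    replicate_id: str = "rep0"

    def __post_init__(self):
        if [f.timepoint for f in self.frames] != [0, 1, 2, 3, 4]:
            raise CellularIOError("sequence must have timepoints 0..4 in order, no gaps")
        if self.condition not in CONDITIONS:
            raise CellularIOError(f"condition must be one of {CONDITIONS}")
        if len({f.shape for f in self.frames}) != 1:
            raise CellularIOError("all frames of a sequence must share one image shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape


# ---------------------------------------------------------------------------
# box dialect conversion


def mask_tight_box(mask: np.ndarray) -> BoundingBox:
    """Tight half-open bounding box of a nonempty binary mask."""
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise CellularIOError("cannot bound an empty mask")
    return BoundingBox(int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)


def box_to_yolo(box: BoundingBox, shape: tuple[int, int]) -> tuple[float, float, float, float]:
    """Absolute half-open box -> YOLO (cx, cy, w, h), all normalized to [0, 1]."""
    h, w = shape
    return (
        (box.x0 + box.x1) / 2.0 / w,
        (box.y0 + box.y1) / 2.0 / h,
        box.width / w,
        box.height / h,
    )


def yolo_to_box(cx: float, cy: float, bw: float, bh: float, shape: tuple[int, int]) -> BoundingBox:
    """YOLO normalized center box -> absolute pixels, rounding ties toward +inf."""
    h, w = shape
    x0 = np.floor(cx * w - bw * w / 2.0 + 0.5)
    y0 = np.floor(cy * h - bh * h / 2.0 + 0.5)
    x1 = np.floor(cx * w + bw * w / 2.0 + 0.5)
    y1 = np.floor(cy * h + bh * h / 2.0 + 0.5)
    return BoundingBox(int(x0), int(y0), int(x1), int(y1))


# ---------------------------------------------------------------------------
# readers


def _read_boxes_csv(path: Path) -> dict[int, BoundingBox]:
    boxes: dict[int, BoundingBox] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            boxes[int(row["cell_id"])] = BoundingBox(
                int(row["x0"]), int(row["y0"]), int(row["x1"]), int(row["y1"])
            )
    return boxes


def _read_boxes_yolo(path: Path, shape: tuple[int, int]) -> dict[int, BoundingBox]:
    # YOLO txt has no cell ids; lines are assigned ids 0..n-1 in file order
    boxes: dict[int, BoundingBox] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.split()
            if not parts:
                continue
            _, cx, cy, bw, bh = parts[:5]
            boxes[i] = yolo_to_box(float(cx), float(cy), float(bw), float(bh), shape)
    return boxes


def read_annotated_frame(
    channel_paths: dict[str, str | Path],
    mask_dir: str | Path,
    boxes_path: str | Path,
    labels_path: str | Path,
    timepoint: int = 0,
) -> AnnotatedFrame:
    """Read one annotated time point from its on-disk files.

    ``channel_paths`` maps each of green/red/transmitted to a single-channel
    TIFF.  ``mask_dir`` holds one binary mask image per cell, named
    ``cell_<id>.tif``.  ``boxes_path`` may be either the CSV dialect
    (``cell_id,x0,y0,x1,y1``, absolute half-open pixels) or the YOLO dialect
    (``class cx cy w h`` per line, normalized); the dialect is chosen by file
    extension (``.txt`` = YOLO).  Missing files are fatal; a stored box that
    is not tight to its mask is kept with a warning.
    """
    channels = {}
    for name in CHANNELS:
        p = Path(channel_paths[name])
        if not p.exists():
            raise CellularIOError(f"missing channel file for {name!r}: {p}")
        channels[name] = ChannelImage(tifffile.imread(p).astype(np.float64), name)
    shape = channels["green"].pixels.shape

    boxes_path = Path(boxes_path)
    if boxes_path.suffix == ".txt":
        boxes = _read_boxes_yolo(boxes_path, shape)
    else:
        boxes = _read_boxes_csv(boxes_path)

    labels: dict[int, str] = {}
    with open(labels_path, newline="") as fh:
        for row in csv.DictReader(fh):
            lbl = row["label"].strip()
            if lbl not in LABELS:
                raise CellularIOError(f"invalid label {lbl!r} for cell {row['cell_id']}")
            labels[int(row["cell_id"])] = lbl

    mask_dir = Path(mask_dir)
    mask_files = {
        int(p.stem.split("_")[-1]): p for p in sorted(mask_dir.glob("cell_*.tif"))
    }
    all_ids = sorted(set(mask_files) | set(boxes) | set(labels))
    cells = []
    for cid in all_ids:
        if cid not in mask_files or cid not in boxes or cid not in labels:
            raise CellularIOError(
                f"cell {cid}: mask/box/label count mismatch "
                f"(mask={cid in mask_files}, box={cid in boxes}, label={cid in labels})"
            )
        mask = tifffile.imread(mask_files[cid]) > 0
        box = boxes[cid]
        tight = mask_tight_box(mask)
        if box != tight and not (
            box.x0 <= tight.x0 and box.y0 <= tight.y0 and box.x1 >= tight.x1 and box.y1 >= tight.y1
        ):
            warnings.warn(
                f"cell {cid}: stored box {box.as_tuple()} does not enclose mask "
                f"tight box {tight.as_tuple()}; keeping stored box",
                stacklevel=2,
            )
        cells.append(CellRecord(cid, mask, box, labels[cid]))
    return AnnotatedFrame(timepoint=timepoint, channels=channels, cells=cells)


def write_annotated_frame(frame: AnnotatedFrame, out_dir: str | Path) -> dict[str, Path]:
    """Write a frame as channel TIFFs, per-cell mask TIFFs, box tables (CSV +
    YOLO txt), and a labels CSV.  ``read_annotated_frame`` on the result
    reproduces the frame exactly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name in CHANNELS:
        p = out / f"{name}.tif"
        tifffile.imwrite(p, frame.channels[name].pixels.astype(np.float32))
        paths[name] = p
    mask_dir = out / "masks"
    mask_dir.mkdir(exist_ok=True)
    for c in frame.cells:
        tifffile.imwrite(mask_dir / f"cell_{c.cell_id}.tif", c.mask.astype(np.uint8) * 255)
    paths["mask_dir"] = mask_dir

    boxes_csv = out / "boxes.csv"
    with open(boxes_csv, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["cell_id", "x0", "y0", "x1", "y1"])
        for c in frame.cells:
            w.writerow([c.cell_id, *c.box.as_tuple()])
    paths["boxes"] = boxes_csv

    yolo_txt = out / "boxes.txt"
    with open(yolo_txt, "w") as fh:
        for c in frame.cells:
            cx, cy, bw, bh = box_to_yolo(c.box, frame.shape)
            fh.write(f"{LABEL_TO_CLASS[c.label]} {cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f}\n")
    paths["boxes_yolo"] = yolo_txt

    labels_csv = out / "labels.csv"
    with open(labels_csv, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["cell_id", "label"])
        for c in frame.cells:
            w.writerow([c.cell_id, c.label])
    paths["labels"] = labels_csv
    return paths


def write_label_image(frame: AnnotatedFrame, path: str | Path) -> None:
    """Optional compact mask writer: one image whose pixel value is cell_id+1."""
    h, w = frame.shape
    lbl = np.zeros((h, w), dtype=np.uint16)
    for c in frame.cells:
        lbl[c.mask] = c.cell_id + 1
    tifffile.imwrite(Path(path), lbl)


def load_split_list(list_path: str | Path) -> tuple[list[str], list[str], list[str]]:
    """Parse a ``filename<TAB>partition`` list into (train, validation, test).

    Every filename must appear exactly once; partition tags outside
    {train, validation, test} are fatal.
    """
    parts: dict[str, list[str]] = {"train": [], "validation": [], "test": []}
    seen: set[str] = set()
    with open(list_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                name, tag = line.split("\t")
            except ValueError as e:
                raise CellularIOError(f"line {lineno}: expected 'filename<TAB>partition'") from e
            if tag not in parts:
                raise CellularIOError(f"line {lineno}: unknown partition tag {tag!r}")
            if name in seen:
                raise CellularIOError(f"filename {name!r} assigned to more than one partition")
            seen.add(name)
            parts[tag].append(name)
    return parts["train"], parts["validation"], parts["test"]
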