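"""Seeded generator of synthetic tandem-reporter time-lapse sequences.

Emulates the statistical structure of annotated mRFP-EGFP-Atg8a microscopy
data: five hourly frames per sample, three channels (green, red,
transmitted light), cells as compact smoothed blobs that drift and
occasionally divide, and the reporter logic that distinguishes the two
autophagy states —

* **basal** cells carry few, small autophagosome puncta rendered in BOTH
  the green and red channels (yellow in a merge);
* **activated** cells carry more, larger autolysosome puncta rendered in
  the red channel ONLY (EGFP is quenched in the acidic lumen).

Under the fed condition no cell ever transitions; under starvation each
cell's basal-to-activated transition frame is drawn from a clamped normal
distribution.  Complete ground truth (masks, boxes, labels, track
identities, division lineage, transition schedule, planted punctum rasters)
accompanies every sequence, so every downstream stage has an exact oracle.
All randomness flows from a single seeded generator: identical configs
reproduce output bit-for-bit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon
from skimage.morphology import closing as binary_closing, erosion as binary_erosion, disk as disk_selem
from skimage.segmentation import find_boundaries

from .io_cellular import (
    AnnotatedFrame,
    CellRecord,
    ChannelImage,
    Sequence,
    mask_tight_box,
)

N_FRAMES = 5


@dataclass(frozen=True)
class SynthConfig:
    """All knobs of the generator; defaults give a clean, separable world.

    Radii and distances are in pixels, times in frames (1 frame = 1 hour).
    ``basal_area_scale`` plants the basal-vs-activated morphology contrast
    (basal cells larger in expected area); ``basal_perturb_extra`` makes
    basal outlines rougher, hence less circular.
    """

    image_size: int = 256
    n_cells: int = 8
    condition: str = "starved"
    cell_radius_mean: float = 12.0
    cell_radius_sd: float = 1.5
    motion_sd: float = 2.0
    division_prob: float = 0.02
    transition_time_mean: float = 2.0
    transition_time_sd: float = 1.0
    basal_puncta_count_range: tuple[int, int] = (2, 4)
    activated_puncta_count_range: tuple[int, int] = (5, 9)
    puncta_radius_range: tuple[float, float] = (1.5, 2.5)
    activated_puncta_radius_scale: float = 2.0
    background_level: float = 10.0
    noise_sd: float = 2.0
    seed: int = 0
    # morphology contrast (design option, not biology)
    basal_area_scale: float = 1.13
    basal_perturb_extra: float = 0.05
    perturb_sd: float = 0.12
    unidentified_fraction: float = 0.0
    cell_intensity: float = 40.0
    punctum_intensity: float = 150.0

    def __post_init__(self):
        if not 0.0 <= self.division_prob <= 1.0:
            raise ValueError("division_prob must be in [0, 1]")
        if not 0.0 <= self.unidentified_fraction <= 1.0:
            raise ValueError("unidentified_fraction must be in [0, 1]")
        if self.cell_radius_mean <= 0 or self.puncta_radius_range[0] <= 0:
            raise ValueError("radii must be > 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.activated_puncta_radius_scale <= 1.0:
            raise ValueError("activated_puncta_radius_scale must be > 1")


@dataclass
class PunctumTruth:
    """One rendered punctum: center (row, col), radius, rasterized in-mask area."""

    center: tuple[int, int]
    radius: float
    area: int
    channels: tuple[str, ...]


@dataclass
class GroundTruth:
    """Complete per-sequence truth keyed by (timepoint, cell_id)."""

    track_of: dict[tuple[int, int], int] = field(default_factory=dict)
    labels: dict[tuple[int, int], str] = field(default_factory=dict)
    parent: dict[int, int] = field(default_factory=dict)
    transition_frame: dict[int, Optional[int]] = field(default_factory=dict)
    puncta: dict[tuple[int, int], list[PunctumTruth]] = field(default_factory=dict)
    divisions: list[dict] = field(default_factory=list)

    def tracks_at(self, t: int) -> set[int]:
        return {tid for (tp, _), tid in self.track_of.items() if tp == t}


@dataclass
class _SimCell:
    track_id: int
    centroid: np.ndarray  # (row, col) float
    radius: float
    perturb: np.ndarray  # per-vertex radial perturbation
    phase: float
    state: str  # basal / activated / unidentified
    transition_frame: Optional[int]
    parent: Optional[int] = None


def _basal_radius_scale(cfg: SynthConfig) -> float:
    """Radius multiplier planting the basal/activated expected-area ratio.

    The expected area of a radial-perturbation polygon is proportional to
    the squared base radius and, to first order, independent of the
    perturbation sd (adjacent vertex radii are independent), so scaling the
    radius by sqrt(basal_area_scale) plants the area contrast directly.
    """
    return math.sqrt(cfg.basal_area_scale)


def _render_blob(
    centroid: np.ndarray,
    radius: float,
    perturb: np.ndarray,
    phase: float,
    shape: tuple[int, int],
) -> np.ndarray:
    n = perturb.size
    ang = 2 * np.pi * np.arange(n) / n + phase
    radii = radius * np.clip(1.0 + perturb, 0.3, 2.0)
    rows = centroid[0] + radii * np.sin(ang)
    cols = centroid[1] + radii * np.cos(ang)
    rr, cc = draw_polygon(rows, cols, shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return binary_closing(mask, disk_selem(2))


def _cell_mask(cell: _SimCell, cfg: SynthConfig, shape: tuple[int, int]) -> np.ndarray:
    r = cell.radius * (_basal_radius_scale(cfg) if cell.state == "basal" else 1.0)
    return _render_blob(cell.centroid, r, cell.perturb, cell.phase, shape)


def _new_perturb(rng: np.random.Generator, cfg: SynthConfig, state: str) -> np.ndarray:
    sd = cfg.perturb_sd + (cfg.basal_perturb_extra if state == "basal" else 0.0)
    n_vert = int(rng.integers(10, 17))
    return rng.normal(0.0, sd, n_vert)


def _draw_transition(rng: np.random.Generator, cfg: SynthConfig) -> Optional[int]:
    t = int(round(rng.normal(cfg.transition_time_mean, cfg.transition_time_sd)))
    t = max(0, min(N_FRAMES, t))
    return None if t >= N_FRAMES else t


def _place_centroids(
    rng: np.random.Generator, cfg: SynthConfig, n: int
) -> list[np.ndarray]:
    """Sample n centroids with pairwise separation; reduce n if space runs out."""
    margin = 2.2 * cfg.cell_radius_mean
    min_sep = 2.6 * cfg.cell_radius_mean
    lo, hi = margin, cfg.image_size - margin
    if hi <= lo:
        raise ValueError("image_size too small for cell_radius_mean")
    placed: list[np.ndarray] = []
    for _ in range(n):
        ok = False
        for _ in range(200):
            c = rng.uniform(lo, hi, 2)
            if all(np.linalg.norm(c - p) >= min_sep for p in placed):
                placed.append(c)
                ok = True
                break
        if not ok:
            warnings.warn(
                f"could not place {n} cells without overlap; reduced to {len(placed)}",
                stacklevel=3,
            )
            break
    return placed


def _label_at(cell: _SimCell, t: int) -> str:
    if cell.state == "unidentified":
        return "unidentified"
    if cell.transition_frame is not None and t >= cell.transition_frame:
        return "activated"
    return "basal"


def generate_sequence(config: SynthConfig) -> tuple[Sequence, GroundTruth]:
    """Simulate one five-frame sequence with full ground truth.

    Cells are radial-perturbation polygons rasterized and morphologically
    smoothed, drifting by Gaussian steps and reflected at the borders.  A
    division replaces the parent blob with two daughters displaced by one
    parent radius along a random axis; daughters inherit the parent's state
    and transition schedule and get fresh track ids with
    ``parent_track_id`` recorded.  Masks within a frame are kept pairwise
    disjoint (later-rendered cells are clipped against claimed pixels).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.image_size, cfg.image_size)

    centroids = _place_centroids(rng, cfg, cfg.n_cells)
    cells: list[_SimCell] = []
    next_track = 0
    gt = GroundTruth()
    for c in centroids:
        if cfg.unidentified_fraction > 0 and rng.random() < cfg.unidentified_fraction:
            state = "unidentified"
            trans = None
        else:
            state = "basal"
            trans = _draw_transition(rng, cfg) if cfg.condition == "starved" else None
        radius = max(3.0, rng.normal(cfg.cell_radius_mean, cfg.cell_radius_sd))
        cells.append(
            _SimCell(
                track_id=next_track,
                centroid=c,
                radius=radius,
                perturb=_new_perturb(rng, cfg, state),
                phase=rng.uniform(0, 2 * np.pi),
                state=state,
                transition_frame=trans,
            )
        )
        gt.transition_frame[next_track] = trans
        next_track += 1

    frames: list[AnnotatedFrame] = []
    margin = 1.2 * cfg.cell_radius_mean
    for t in range(N_FRAMES):
        if t > 0:
            # motion, shape morphing, divisions
            for cell in cells:
                step = rng.normal(0.0, cfg.motion_sd, 2)
                c = cell.centroid + step
                c = np.clip(c, margin, cfg.image_size - margin)
                cell.centroid = c
                cell.perturb = np.clip(cell.perturb + rng.normal(0, 0.02, cell.perturb.size), -0.4, 0.4)
            divided: list[_SimCell] = []
            survivors: list[_SimCell] = []
            for cell in cells:
                if rng.random() < cfg.division_prob:
                    axis = rng.uniform(0, 2 * np.pi)
                    offset = cell.radius * np.array([np.sin(axis), np.cos(axis)])
                    children = []
                    for sign in (+1, -1):
                        child = _SimCell(
                            track_id=next_track,
                            centroid=np.clip(cell.centroid + sign * offset, margin, cfg.image_size - margin),
                            radius=cell.radius / math.sqrt(2),
                            perturb=_new_perturb(rng, cfg, cell.state),
                            phase=rng.uniform(0, 2 * np.pi),
                            state=cell.state,
                            transition_frame=cell.transition_frame,
                            parent=cell.track_id,
                        )
                        gt.parent[next_track] = cell.track_id
                        gt.transition_frame[next_track] = cell.transition_frame
                        children.append(child)
                        next_track += 1
                    divided.append(cell)
                    survivors.extend(children)
                    gt.divisions.append(
                        {"frame": t, "parent": cell.track_id, "children": [ch.track_id for ch in children]}
                    )
                else:
                    survivors.append(cell)
            cells = survivors

        frames.append(_render_frame(t, cells, cfg, rng, gt, shape))

    seq = Sequence(frames=frames, condition=cfg.condition, replicate_id=f"sim{cfg.seed}")
    return seq, gt


def _render_frame(
    t: int,
    cells: list[_SimCell],
    cfg: SynthConfig,
    rng: np.random.Generator,
    gt: GroundTruth,
    shape: tuple[int, int],
) -> AnnotatedFrame:
    green = np.full(shape, cfg.background_level, dtype=np.float64)
    red = np.full(shape, cfg.background_level, dtype=np.float64)
    trans_ch = np.full(shape, 10 * cfg.background_level, dtype=np.float64)

    occupied = np.zeros(shape, dtype=bool)
    records: list[CellRecord] = []
    for cell in cells:
        mask = _cell_mask(cell, cfg, shape) & ~occupied
        if mask.sum() < 9:  # clipped away or degenerate; skip this cell this frame
            continue
        occupied |= mask
        label = _label_at(cell, t)
        body = cfg.cell_intensity if label != "unidentified" else 0.35 * cfg.cell_intensity
        green[mask] += body
        red[mask] += body
        trans_ch[find_boundaries(mask, mode="inner")] += 3 * cfg.cell_intensity

        cell_id = cell.track_id  # unique per frame; doubles as the truth link
        key = (t, cell_id)
        gt.track_of[key] = cell.track_id
        gt.labels[key] = label
        gt.puncta[key] = []
        if label != "unidentified":
            _render_puncta(cell, mask, label, cfg, rng, green, red, gt.puncta[key])

        records.append(CellRecord(cell_id=cell_id, mask=mask, box=mask_tight_box(mask), label=label))

    for img in (green, red, trans_ch):
        img += rng.normal(0.0, cfg.noise_sd, shape)
        np.clip(img, 0.0, None, out=img)

    records.sort(key=lambda r: r.cell_id)
    return AnnotatedFrame(
        timepoint=t,
        channels={
            "green": ChannelImage(green, "green"),
            "red": ChannelImage(red, "red"),
            "transmitted": ChannelImage(trans_ch, "transmitted"),
        },
        cells=records,
    )


def _render_puncta(
    cell: _SimCell,
    mask: np.ndarray,
    label: str,
    cfg: SynthConfig,
    rng: np.random.Generator,
    green: np.ndarray,
    red: np.ndarray,
    out: list[PunctumTruth],
) -> None:
    if label == "basal":
        lo, hi = cfg.basal_puncta_count_range
        r_scale = 1.0
        channels = ("green", "red")
    else:
        lo, hi = cfg.activated_puncta_count_range
        r_scale = cfg.activated_puncta_radius_scale
        channels = ("red",)
    count = int(rng.integers(lo, hi + 1))
    # sample centers from the eroded mask so puncta sit inside the cell
    interior = binary_erosion(mask, disk_selem(int(math.ceil(cfg.puncta_radius_range[1] * r_scale))))
    if not interior.any():
        interior = mask
    rows, cols = np.nonzero(interior)
    for _ in range(count):
        i = int(rng.integers(rows.size))
        center = (int(rows[i]), int(cols[i]))
        radius = rng.uniform(*cfg.puncta_radius_range) * r_scale
        rr, cc = draw_disk(center, radius, shape=mask.shape)
        keep = mask[rr, cc]
        rr, cc = rr[keep], cc[keep]
        red[rr, cc] += cfg.punctum_intensity
        if "green" in channels:
            green[rr, cc] += cfg.punctum_intensity
        out.append(PunctumTruth(center=center, radius=radius, area=int(rr.size), channels=channels))


def planted_spot_truth(gt: GroundTruth) -> pd.DataFrame:
    """Per-cell, per-frame red-channel punctum truth (count, exact raster areas).

    This is the oracle for spot segmentation: areas are the noiseless
    rasterized pixel counts of each planted punctum clipped to its cell mask.
    """
    rows = []
    for (t, cid), plist in sorted(gt.puncta.items()):
        red = [p for p in plist if "red" in p.channels]
        rows.append(
            {
                "timepoint": t,
                "cell_id": cid,
                "spot_count": len(red),
                "total_area": int(sum(p.area for p in red)),
                "max_area": int(max((p.area for p in red), default=0)),
            }
        )
    return pd.DataFrame(rows, columns=["timepoint", "cell_id", "spot_count", "total_area", "max_area"])


def generate_morphology_population(
    n_basal: int,
    n_activated: int,
    config: SynthConfig | None = None,
    seed: int | None = None,
) -> tuple[list[np.ndarray], list[str]]:
    """Rasterize standalone cell masks with the planted morphology contrast.

    Returns (masks, labels) for population-level morphology studies without
    paying for full frame rendering; each mask sits in its own small canvas.
    """
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    side = int(6 * cfg.cell_radius_mean)
    center = np.array([side / 2, side / 2])
    masks, labels = [], []
    for label, n in (("basal", n_basal), ("activated", n_activated)):
        scale = _basal_radius_scale(cfg) if label == "basal" else 1.0
        for _ in range(n):
            radius = max(3.0, rng.normal(cfg.cell_radius_mean, cfg.cell_radius_sd)) * scale
            perturb = _new_perturb(rng, cfg, label)
            phase = rng.uniform(0, 2 * np.pi)
            masks.append(_render_blob(center, radius, perturb, phase, (side, side)))
            labels.append(label)
    return masks, labels
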