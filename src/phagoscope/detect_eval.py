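"""Reference classical cell detector and detection/segmentation metrology.

The detector is a deliberately simple classical stand-in for a fine-tuned
neural detector: fluorescence sum -> Gaussian smoothing -> Otsu threshold ->
connected components -> minimum-area filter -> distance-transform watershed
to split touching cells.  It exists so the rest of the pipeline can be
exercised without a GPU; its parameters are tuned on the synthetic
generator's defaults and are not claimed to transfer to real microscopy.

The metrology half implements the standard detection vocabulary: box IoU on
half-open pixel boxes, greedy confidence-ordered matching, COCO-style
101-point interpolated average precision (mAP50, mAP50-95), and pixel-level
segmentation metrics (IoU, F1, precision, recall, accuracy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence as TypingSequence

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

from .io_cellular import AnnotatedFrame, BoundingBox, mask_tight_box


@dataclass
class Detection:
    """A candidate cell from any detector: box, confidence, optional mask."""

    box: BoundingBox
    confidence: float
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass
class DetectionMatch:
    """One-to-one matching between detections and ground-truth boxes."""

    pairs: list[tuple[int, int, float]]  # (det index, gt index, IoU)
    unmatched_detections: list[int]
    unmatched_ground_truths: list[int]


def box_iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two half-open pixel boxes, in [0, 1]."""
    ix = max(0, min(a.x1, b.x1) - max(a.x0, b.x0))
    iy = max(0, min(a.y1, b.y1) - max(a.y0, b.y0))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def match_detections(
    dets: TypingSequence[Detection],
    gts: TypingSequence[BoundingBox],
    iou_thresh: float,
) -> DetectionMatch:
    """Greedy confidence-ordered one-to-one matching (AP-style).

    Detections are visited in descending confidence (ties broken by lower
    index); each takes the still-unmatched ground truth of maximal IoU if
    that IoU reaches ``iou_thresh``.
    """
    if not 0.0 < iou_thresh <= 1.0:
        raise ValueError("iou_thresh must be in (0, 1]")
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    taken = [False] * len(gts)
    pairs: list[tuple[int, int, float]] = []
    unmatched_d: list[int] = []
    for i in order:
        best_j, best_iou = -1, 0.0
        for j, g in enumerate(gts):
            if taken[j]:
                continue
            iou = box_iou(dets[i].box, g)
            if iou > best_iou:
                best_j, best_iou = j, iou
        if best_j >= 0 and best_iou >= iou_thresh:
            taken[best_j] = True
            pairs.append((i, best_j, best_iou))
        else:
            unmatched_d.append(i)
    unmatched_g = [j for j, t in enumerate(taken) if not t]
    return DetectionMatch(pairs=pairs, unmatched_detections=unmatched_d, unmatched_ground_truths=unmatched_g)


_RECALL_GRID = np.linspace(0.0, 1.0, 101)


def average_precision(
    dets: TypingSequence[TypingSequence[Detection]],
    gts: TypingSequence[TypingSequence[BoundingBox]],
    iou_thresh: float,
) -> float:
    """COCO-style 101-point interpolated AP pooled over images.

    Per image, detections are matched greedily in confidence order; the
    pooled detection list is then ranked by confidence and the
    precision-recall curve evaluated with the precision envelope
    (max precision at recall >= r) on the 101-point recall grid.
    Raises if there are no ground truths (AP is undefined, not 0).
    """
    if len(dets) != len(gts):
        raise ValueError("detections and ground truths must align per image")
    n_gt = sum(len(g) for g in gts)
    if n_gt == 0:
        raise ValueError("average precision undefined with zero ground truths")
    scored: list[tuple[float, bool]] = []  # (confidence, is true positive)
    for img_dets, img_gts in zip(dets, gts):
        m = match_detections(img_dets, img_gts, iou_thresh)
        tp_idx = {i for i, _, _ in m.pairs}
        for i, d in enumerate(img_dets):
            scored.append((d.confidence, i in tp_idx))
    if not scored:
        return 0.0
    scored.sort(key=lambda s: -s[0])
    tps = np.cumsum([1 if tp else 0 for _, tp in scored])
    fps = np.cumsum([0 if tp else 1 for _, tp in scored])
    recall = tps / n_gt
    precision = tps / np.maximum(tps + fps, 1)
    # precision envelope: p_interp(r) = max precision at recall >= r
    ap = 0.0
    for r in _RECALL_GRID:
        mask = recall >= r
        ap += float(precision[mask].max()) if mask.any() else 0.0
    return ap / _RECALL_GRID.size


def mean_average_precision(
    dets: TypingSequence[TypingSequence[Detection]],
    gts: TypingSequence[TypingSequence[BoundingBox]],
    thresholds: TypingSequence[float] = tuple(np.arange(0.50, 0.96, 0.05)),
) -> float:
    """mAP over an IoU threshold range (default 0.50:0.05:0.95)."""
    return float(np.mean([average_precision(dets, gts, float(t)) for t in thresholds]))


def pixel_metrics(pred: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """Foreground-pixel confusion-matrix metrics for a binary segmentation.

    Empty truth and empty prediction agree perfectly: IoU/F1/precision/
    recall are defined as 1 in that degenerate case.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must share a shape")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    if tp + fp + fn == 0:
        iou = f1 = precision = recall = 1.0
    else:
        iou = tp / (tp + fp + fn)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    accuracy = (tp + tn) / (tp + tn + fp + fn)
    return {"IoU": iou, "F1": f1, "precision": precision, "recall": recall, "accuracy": accuracy}


@dataclass(frozen=True)
class DetectorParams:
    """Classical detector knobs, tuned on the generator's default config."""

    smooth_sigma: float = 2.0
    min_area: int = 60
    watershed_min_distance: int = 10


def reference_detect(
    frame: AnnotatedFrame | dict[str, np.ndarray],
    params: DetectorParams = DetectorParams(),
) -> list[Detection]:
    """Classical detector: smooth(green+red) -> Otsu -> components -> watershed.

    Confidence is the component's mean smoothed intensity normalized by the
    frame maximum, clipped to [0, 1].  Returns tight boxes with masks; a
    blank image yields an empty list.
    """
    if isinstance(frame, AnnotatedFrame):
        green = frame.channels["green"].pixels
        red = frame.channels["red"].pixels
    else:
        green, red = frame["green"], frame["red"]
    total = gaussian(green + red, sigma=params.smooth_sigma, preserve_range=True)
    if total.max() <= total.min():
        return []
    # threshold on a log-compressed image: bright puncta would otherwise pull
    # the Otsu threshold above the cell-body level and fragment cells
    log_total = np.log1p(total)
    thr = threshold_otsu(log_total)
    fg = log_total > thr
    # Otsu always splits something: on a background-only image the two
    # "classes" are just noise halves. Require real foreground contrast.
    if fg.any() and not fg.all():
        if total[fg].mean() < 1.5 * total[~fg].mean():
            return []
    fg = remove_small_objects(fg, max_size=params.min_area - 1)
    if not fg.any():
        return []
    # split touching cells on the distance transform
    dist = ndi.distance_transform_edt(fg)
    coords = peak_local_max(
        dist, min_distance=params.watershed_min_distance, labels=fg, exclude_border=False
    )
    markers = np.zeros_like(fg, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    if markers.max() == 0:
        labels = cc_label(fg)
    else:
        labels = watershed(-dist, markers, mask=fg)
    dets: list[Detection] = []
    fg_mean = float(total[fg].mean())
    for lab in range(1, labels.max() + 1):
        mask = labels == lab
        area = int(mask.sum())
        if area < params.min_area:
            continue
        # normalized component mean: ~1 for a typically bright cell, low for
        # dim (unidentified-looking) components, so the 0.65 filter bites
        conf = float(np.clip(total[mask].mean() / fg_mean, 0.0, 1.0))
        dets.append(Detection(box=mask_tight_box(mask), confidence=conf, mask=mask))
    dets.sort(key=lambda d: (d.box.y0, d.box.x0))
    return dets


def crop_cell(frame: AnnotatedFrame, box: BoundingBox, pad: int = 0) -> np.ndarray:
    """Padded box crop of the merged (H, W, 3) color image; pad clips at borders."""
    h, w = frame.shape
    if not (0 <= box.x0 < box.x1 <= w and 0 <= box.y0 < box.y1 <= h):
        raise ValueError(f"box {box} outside frame of shape {(h, w)}")
    x0, y0 = max(0, box.x0 - pad), max(0, box.y0 - pad)
    x1, y1 = min(w, box.x1 + pad), min(h, box.y1 + pad)
    return frame.merged_rgb()[y0:y1, x0:x1]


def apply_mask(cell_image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero every pixel outside the mask (cells isolated on black background)."""
    if mask.shape != cell_image.shape[:2]:
        raise ValueError("mask shape must match the image's spatial shape")
    out = cell_image.copy()
    out[~np.asarray(mask, dtype=bool)] = 0
    return out


def filter_by_confidence(dets: TypingSequence[Detection], threshold: float) -> list[Detection]:
    """Keep detections with confidence >= threshold, preserving order."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    return [d for d in dets if d.confidence >= threshold]
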