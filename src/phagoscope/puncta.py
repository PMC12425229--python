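"""Red-channel punctum quantification and threshold-based autophagy calling.

Reimplements the traditional (non-deep-learning) analysis route natively:
RFP spots are segmented within each ground-truth cell mask (white-top-hat
background removal, a robust per-cell median + k*MAD intensity threshold,
connected components, minimum-area filter), per-cell spot features are
normalized within experiment replicates and log10-transformed, and a cell
is called *activated* when its spot-area feature exceeds the 95th
percentile of fed cells at timepoint 1.  Cells with no segmentable spots
are excluded from thresholding and reported, mirroring the original
analysis where roughly a tenth of cells had no RFP spots.

Also provides the morphology statistics (area, Crofton perimeter,
circularity 4*pi*A/P^2) and the classification metrology (confusion matrix,
accuracy, macro precision/recall/F1, multiclass MCC).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence as TypingSequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage.measure import label as cc_label
from skimage.measure import perimeter_crofton
from skimage.morphology import disk as disk_selem
from skimage.morphology import white_tophat

from .io_cellular import ChannelImage


@dataclass
class SpotRecord:
    """Per-cell red-punctum measurements."""

    cell_id: int
    spot_areas: list[int]
    no_spots: bool = False
    feature: Optional[float] = None  # transformed feature used for thresholding

    @property
    def spot_count(self) -> int:
        return len(self.spot_areas)

    @property
    def total_area(self) -> int:
        return int(sum(self.spot_areas))

    @property
    def max_area(self) -> int:
        return int(max(self.spot_areas, default=0))


@dataclass
class MorphologyRecord:
    cell_id: int
    area: int
    perimeter: float
    circularity: float


@dataclass
class ConfusionMatrix:
    """K x K count matrix, rows = truth, columns = prediction, fixed class order."""

    counts: np.ndarray
    classes: tuple[str, ...] = ("basal", "activated")

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k) or (self.counts < 0).any():
            raise ValueError("confusion matrix must be KxK with non-negative counts")

    @classmethod
    def from_labels(
        cls,
        truth: TypingSequence[str],
        pred: TypingSequence[str],
        classes: tuple[str, ...] = ("basal", "activated"),
    ) -> "ConfusionMatrix":
        idx = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
        for t, p in zip(truth, pred, strict=True):
            counts[idx[t], idx[p]] += 1
        return cls(counts, classes)


@dataclass(frozen=True)
class SpotParams:
    """Spot segmentation knobs: top-hat radius, threshold rule, min area."""

    tophat_radius: int = 4
    mad_k: float = 5.0
    min_spot_area: int = 3


def segment_spots(
    red: ChannelImage | np.ndarray,
    cell_mask: np.ndarray,
    params: SpotParams = SpotParams(),
    cell_id: int = 0,
) -> SpotRecord:
    """Segment red puncta inside one cell mask and return their areas.

    Within the mask only: white-top-hat background removal with a disk of
    ``tophat_radius``, then a robust threshold median + mad_k * MAD of the
    top-hat response over the mask, connected components, and a minimum
    spot area filter.  A cell whose mask survives no component is flagged
    ``no_spots`` (such cells are excluded from threshold classification).
    """
    img = red.pixels if isinstance(red, ChannelImage) else np.asarray(red, dtype=np.float64)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("segment_spots: empty cell mask")
    th = white_tophat(img, disk_selem(params.tophat_radius))
    vals = th[cell_mask]
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    thr = med + params.mad_k * max(mad, 1e-9)
    spots = (th > thr) & cell_mask
    labels = cc_label(spots, connectivity=2)
    areas = [
        int(n)
        for n in np.bincount(labels.ravel())[1:]
        if n >= params.min_spot_area
    ]
    areas.sort(reverse=True)
    return SpotRecord(cell_id=cell_id, spot_areas=areas, no_spots=(len(areas) == 0))


def normalize_and_log(
    values: TypingSequence[float], replicate_ids: TypingSequence[str]
) -> np.ndarray:
    """Divide each value by its replicate's median, then log10.

    Scale-free within a replicate: multiplying one replicate's raw values by
    any positive constant leaves its output unchanged.  Zeros are not
    representable after the log and must be excluded upstream.
    """
    values = np.asarray(values, dtype=np.float64)
    reps = np.asarray(replicate_ids)
    if values.shape != reps.shape:
        raise ValueError("values and replicate_ids must align")
    out = np.empty_like(values)
    for rep in np.unique(reps):
        sel = reps == rep
        med = np.median(values[sel])
        if med <= 0:
            raise ValueError(f"replicate {rep!r}: non-positive median, cannot normalize")
        if np.any(values[sel] <= 0):
            raise ValueError(f"replicate {rep!r}: non-positive values cannot be log-transformed")
        out[sel] = np.log10(values[sel] / med)
    return out


def activation_threshold(fed_t1_values: TypingSequence[float], percentile: float = 95.0) -> float:
    """Linear-interpolation (type 7) percentile of the fed calibration values.

    The calibration population is the transformed spot-area feature of fed
    cells at timepoint 1; the default 95th percentile defines the activated
    autophagy threshold.
    """
    vals = np.asarray(fed_t1_values, dtype=np.float64)
    if vals.size < 2:
        raise ValueError("need at least 2 calibration values")
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must be in (0, 100)")
    return float(np.percentile(vals, percentile, method="linear"))


def classify_by_threshold(
    records: TypingSequence[SpotRecord], threshold: float, feature: str = "max_area"
) -> dict[int, str]:
    """Call each cell activated iff its transformed feature exceeds the threshold.

    Records must carry ``feature`` (the transformed value); ``no_spots``
    cells are excluded from the result (the caller reports them).  Returns
    ``{cell_id: "basal" | "activated"}``.
    """
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    out: dict[int, str] = {}
    for r in records:
        if r.no_spots:
            continue
        if r.feature is None:
            raise ValueError(f"cell {r.cell_id}: record lacks a transformed feature")
        out[r.cell_id] = "activated" if r.feature > threshold else "basal"
    return out


def cell_morphology(mask: np.ndarray, cell_id: int = 0) -> MorphologyRecord:
    """Area (pixel count), Crofton 4-direction perimeter, circularity 4*pi*A/P^2.

    Multi-component masks keep the largest component with a warning;
    circularity is clipped at 1 (the Crofton estimator can slightly
    overshoot on small discs).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cell_morphology: empty mask")
    labels = cc_label(mask, connectivity=2)
    if labels.max() > 1:
        warnings.warn(f"cell {cell_id}: mask has {labels.max()} components; keeping largest", stacklevel=2)
        sizes = np.bincount(labels.ravel())[1:]
        mask = labels == (int(np.argmax(sizes)) + 1)
    area = int(mask.sum())
    perim = float(perimeter_crofton(mask, directions=4))
    circ = 4 * math.pi * area / perim**2 if perim > 0 else 1.0
    return MorphologyRecord(cell_id=cell_id, area=area, perimeter=perim, circularity=min(circ, 1.0))


def compare_classes(
    records: TypingSequence[MorphologyRecord], labels: TypingSequence[str]
) -> dict[str, float]:
    """Basal-vs-activated morphology contrast with Welch t-tests.

    ``percent_diff_area`` = (mean_basal - mean_activated) / mean_activated * 100,
    positive when basal cells are larger; ``percent_diff_circularity``
    analogous, negative when basal cells are less circular.  Swapping the
    class labels negates the t statistics and maps each percent difference
    to its reciprocal-form counterpart.
    """
    areas = {"basal": [], "activated": []}
    circs = {"basal": [], "activated": []}
    for r, lbl in zip(records, labels, strict=True):
        if lbl in areas:
            areas[lbl].append(r.area)
            circs[lbl].append(r.circularity)
    for cls in ("basal", "activated"):
        if len(areas[cls]) < 2:
            raise ValueError(f"class {cls!r} needs >= 2 members, got {len(areas[cls])}")
    out: dict[str, float] = {}
    for name, data in (("area", areas), ("circularity", circs)):
        b = np.asarray(data["basal"], dtype=np.float64)
        a = np.asarray(data["activated"], dtype=np.float64)
        out[f"percent_diff_{name}"] = float((b.mean() - a.mean()) / a.mean() * 100.0)
        if np.var(b) == 0 and np.var(a) == 0 and b.mean() == a.mean():
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(b, a, equal_var=False)
        out[f"t_{name}"] = float(t)
        out[f"p_{name}"] = float(p)
    return out


def classification_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, macro precision/recall/F1, and multiclass MCC from a confusion matrix.

    MCC uses the covariance (Gorodkin) form, which reduces to the familiar
    binary formula for two classes.  Classes absent from both truth and
    prediction are excluded from the macro averages with a warning.
    """
    c = cm.counts.astype(np.float64)
    total = c.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    accuracy = float(np.trace(c) / total)

    precisions, recalls, f1s = [], [], []
    for k in range(len(cm.classes)):
        tp = c[k, k]
        col = c[:, k].sum()
        row = c[k, :].sum()
        if col == 0 and row == 0:
            warnings.warn(
                f"class {cm.classes[k]!r} absent from truth and prediction; excluded from macro averages",
                stacklevel=2,
            )
            continue
        p = tp / col if col else 0.0
        r = tp / row if row else 0.0
        precisions.append(p)
        recalls.append(r)
        f1s.append(2 * p * r / (p + r) if p + r else 0.0)

    # Gorodkin multiclass MCC: cov(truth, pred) / sqrt(cov(t,t) cov(p,p))
    t_k = c.sum(axis=1)
    p_k = c.sum(axis=0)
    cov_tp = np.trace(c) * total - float(t_k @ p_k)
    cov_tt = total**2 - float(t_k @ t_k)
    cov_pp = total**2 - float(p_k @ p_k)
    denom = math.sqrt(cov_tt * cov_pp)
    mcc = cov_tp / denom if denom > 0 else 0.0

    return {
        "accuracy": accuracy,
        "precision": float(np.mean(precisions)),
        "recall": float(np.mean(recalls)),
        "F1": float(np.mean(f1s)),
        "MCC": float(mcc),
    }
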