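"""Multi-object cell tracker: Hungarian association without motion filtering.

Five-frame sequences are too short for a Kalman-style motion model, so the
tracker predicts each cell at its last observed position and associates
tracks to detections by solving a minimum-cost bipartite assignment with
the Hungarian algorithm.  The cost mixes spatial distance, appearance
(cosine distance between feature embeddings), and box overlap:

    cost(i, j) = w_spatial * d_ij / D
               + w_feature * (1 - cos(f_i, f_j)) / 2
               + w_overlap * (1 - IoU(box_i, box_j))

with pairs beyond the gate radius D forbidden outright.  Tracks that miss a
detection become *inactive* but keep their full history and stay in the
candidate pool with a fixed re-identification surcharge, so a cell that
reappears resumes its original identity.  An unmatched detection whose box
overlaps a matched track's previous box is registered as a division
daughter (its ``parent_track_id`` records the lineage); otherwise it starts
a new track.

The feature embedding is a contract — any function mapping a masked cell
crop to a fixed-length vector plugs in.  The shipped reference embedding is
deterministic and hand-crafted (per-channel intensity histograms plus shape
summaries), which keeps the suite GPU-free; a neural encoder attaches
through the same contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence as TypingSequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detect_eval import Detection, box_iou
from .io_cellular import BoundingBox
from .puncta import cell_morphology
from .synthgen import GroundTruth

SENTINEL = np.inf  # forbidden-pair marker in cost matrices


@dataclass
class FeatureVector:
    """Fixed-length appearance embedding with the id of its extractor."""

    values: np.ndarray
    extractor_id: str = "histogram-v1"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector entries must be finite")


def embed_cell(cell_image: np.ndarray, mask: Optional[np.ndarray] = None) -> FeatureVector:
    """Deterministic reference embedding of a masked color cell crop.

    Concatenates, over the mask's pixels, a 16-bin intensity histogram per
    channel (each channel min-max normalized within the mask first, so the
    histograms are invariant to uniform gain), the mask area and
    circularity, the per-channel mean intensities, and a reporter-aware
    punctum block: the bright-pixel fraction per channel (pixels above the
    channel's in-mask median + 5 MAD) and the Jaccard overlap of the red
    and green bright sets.  The overlap separates cells whose red puncta
    are also green (autophagosomes, yellow) from cells with red-only
    puncta (autolysosomes); without it the body pixels dominate the
    histograms and appearance barely discriminates.  The result is
    unit-normalized.
    """
    img = np.asarray(cell_image, dtype=np.float64)
    if img.ndim == 2:
        img = img[..., None]
    if mask is None:
        mask = img.sum(axis=-1) > 0
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("embed_cell: empty mask")
    feats: list[np.ndarray] = []
    bright_sets: dict[int, np.ndarray] = {}
    for c in range(img.shape[-1]):
        vals = img[..., c][mask]
        lo, hi = np.percentile(vals, [1, 99])
        span = hi - lo
        norm = (vals - lo) / span if span > 0 else np.zeros_like(vals)
        hist, _ = np.histogram(np.clip(norm, 0, 1), bins=16, range=(0.0, 1.0))
        feats.append(hist / max(hist.sum(), 1))
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        bright_sets[c] = vals > med + 5 * max(mad, 1e-9)
    morph = cell_morphology(mask)
    feats.append(np.array([morph.area / 1000.0, morph.circularity]))
    feats.append(np.array([img[..., c][mask].mean() / 255.0 for c in range(img.shape[-1])]))
    punctum = [bright_sets[c].mean() for c in sorted(bright_sets)]
    if len(bright_sets) >= 2:
        union = np.logical_or(bright_sets[0], bright_sets[1]).sum()
        inter = np.logical_and(bright_sets[0], bright_sets[1]).sum()
        punctum.append(inter / union if union else 0.0)
    feats.append(2.0 * np.array(punctum))  # weighted up against the histogram mass
    v = np.concatenate(feats)
    n = np.linalg.norm(v)
    return FeatureVector(v / n if n > 0 else v)


def cosine_similarity(a: FeatureVector, b: FeatureVector) -> float:
    na, nb = np.linalg.norm(a.values), np.linalg.norm(b.values)
    if na == 0 or nb == 0:
        return 0.0
    return float(a.values @ b.values / (na * nb))


@dataclass
class Track:
    """One cell's identity through time; inactive tracks keep their history."""

    track_id: int
    links: list[tuple[int, int]] = field(default_factory=list)  # (timepoint, detection ref)
    status: str = "active"
    last_feature: Optional[FeatureVector] = None
    last_centroid: Optional[np.ndarray] = None
    last_box: Optional[BoundingBox] = None
    parent_track_id: Optional[int] = None

    def add_link(self, t: int, ref: int) -> None:
        if self.links and t <= self.links[-1][0]:
            raise ValueError("track timepoints must strictly increase")
        self.links.append((t, ref))


@dataclass(frozen=True)
class TrackerConfig:
    """Association weights and gates; weights must sum to 1."""

    w_spatial: float = 0.4
    w_feature: float = 0.4
    w_overlap: float = 0.2
    gate_radius: Optional[float] = None  # None -> 3x median cell diameter, per frame
    inactive_surcharge: float = 0.1
    theta_div: float = 0.15

    def __post_init__(self):
        s = self.w_spatial + self.w_feature + self.w_overlap
        if any(w < 0 for w in (self.w_spatial, self.w_feature, self.w_overlap)):
            raise ValueError("weights must be >= 0")
        if not math.isclose(s, 1.0, abs_tol=1e-9):
            raise ValueError(f"weights must sum to 1, got {s}")


def _det_centroid(det: Detection) -> np.ndarray:
    if det.mask is not None:
        ys, xs = np.nonzero(det.mask)
        return np.array([ys.mean(), xs.mean()])
    b = det.box
    return np.array([(b.y0 + b.y1) / 2.0, (b.x0 + b.x1) / 2.0])


def _auto_gate(dets: TypingSequence[Detection]) -> float:
    if not dets:
        return 100.0
    diams = [max(d.box.width, d.box.height) for d in dets]
    return 3.0 * float(np.median(diams))


def build_cost_matrix(
    candidates: TypingSequence[Track],
    detections: TypingSequence[Detection],
    features: TypingSequence[FeatureVector],
    config: TrackerConfig = TrackerConfig(),
) -> np.ndarray:
    """Association costs, rows = candidate tracks (active first), cols = detections.

    Pairs whose centroid distance exceeds the gate radius get the forbidden
    sentinel; inactive candidates pay a fixed re-identification surcharge.
    """
    if len(detections) != len(features):
        raise ValueError("detections and features must align")
    D = config.gate_radius if config.gate_radius is not None else _auto_gate(detections)
    cost = np.full((len(candidates), len(detections)), SENTINEL)
    for i, tr in enumerate(candidates):
        for j, (det, feat) in enumerate(zip(detections, features)):
            d = float(np.linalg.norm(tr.last_centroid - _det_centroid(det)))
            if d > D:
                continue
            c = config.w_spatial * d / D
            c += config.w_feature * (1.0 - cosine_similarity(tr.last_feature, feat)) / 2.0
            c += config.w_overlap * (1.0 - box_iou(tr.last_box, det.box))
            if tr.status == "inactive":
                c += config.inactive_surcharge
            cost[i, j] = c
    return cost


def hungarian(cost: np.ndarray) -> list[tuple[int, int]]:
    """Minimum-cost maximal assignment avoiding sentinel entries.

    Wraps scipy's Hungarian solver; sentinel (infinite) entries are replaced
    by a finite penalty larger than any feasible total so they are used only
    when unavoidable, then stripped from the returned matching.  Returns
    sorted (row, col) pairs.
    """
    cost = np.asarray(cost, dtype=np.float64)
    if cost.size == 0:
        return []
    finite = cost[np.isfinite(cost)]
    if finite.size == 0:
        return []
    big = float(finite.sum()) + float(np.abs(finite).max()) + 1.0
    filled = np.where(np.isfinite(cost), cost, big)
    rows, cols = linear_sum_assignment(filled)
    return sorted((int(r), int(c)) for r, c in zip(rows, cols) if np.isfinite(cost[r, c]))


@dataclass
class TrackerState:
    tracks: list[Track] = field(default_factory=list)
    next_id: int = 0
    t: int = -1


def step(
    state: TrackerState,
    detections: TypingSequence[Detection],
    features: TypingSequence[FeatureVector],
    t: int,
    refs: Optional[TypingSequence[int]] = None,
    config: TrackerConfig = TrackerConfig(),
) -> TrackerState:
    """Advance the tracker by one frame.

    Active and inactive tracks compete jointly for the frame's detections
    (inactive ones pay the surcharge).  Matched tracks extend and are
    active; unmatched tracks turn inactive but are never dropped; each
    unmatched detection becomes a division daughter if its box overlaps a
    matched track's previous box by at least ``theta_div`` IoU, else a new
    track.  ``refs`` names each detection (defaults to its index).
    """
    if refs is None:
        refs = list(range(len(detections)))
    if len(set(refs)) != len(refs):
        raise ValueError("duplicate detection references")
    candidates = [tr for tr in state.tracks if tr.status == "active"] + [
        tr for tr in state.tracks if tr.status == "inactive"
    ]
    prev_boxes = {tr.track_id: tr.last_box for tr in candidates}

    matched_tracks: dict[int, int] = {}  # candidate row -> detection col
    if candidates and detections:
        cost = build_cost_matrix(candidates, detections, features, config)
        matched_tracks = dict(hungarian(cost))

    matched_det_cols = set(matched_tracks.values())
    matched_track_objs: list[Track] = []
    for i, tr in enumerate(candidates):
        if i in matched_tracks:
            j = matched_tracks[i]
            tr.add_link(t, refs[j])
            tr.status = "active"
            tr.last_feature = features[j]
            tr.last_centroid = _det_centroid(detections[j])
            tr.last_box = detections[j].box
            matched_track_objs.append(tr)
        else:
            tr.status = "inactive"

    for j, (det, feat) in enumerate(zip(detections, features)):
        if j in matched_det_cols:
            continue
        parent_id = None
        best = 0.0
        for tr in matched_track_objs:
            pb = prev_boxes.get(tr.track_id)
            if pb is None:
                continue
            iou = box_iou(det.box, pb)
            if iou >= config.theta_div and iou > best:
                parent_id, best = tr.track_id, iou
        new = Track(
            track_id=state.next_id,
            status="active",
            last_feature=feat,
            last_centroid=_det_centroid(det),
            last_box=det.box,
            parent_track_id=parent_id,
        )
        new.add_link(t, refs[j])
        state.tracks.append(new)
        state.next_id += 1

    state.t = t
    return state


def track_sequence(
    seq_detections: TypingSequence[TypingSequence[Detection]],
    seq_features: TypingSequence[TypingSequence[FeatureVector]],
    seq_refs: Optional[TypingSequence[TypingSequence[int]]] = None,
    config: TrackerConfig = TrackerConfig(),
) -> list[Track]:
    """Track one sequence's per-frame detections; returns all tracks with history."""
    if not seq_detections:
        raise ValueError("empty frame list")
    state = TrackerState()
    for t, dets in enumerate(seq_detections):
        feats = seq_features[t]
        refs = seq_refs[t] if seq_refs is not None else None
        state = step(state, dets, feats, t, refs=refs, config=config)
    return state.tracks


def tracking_metrics(tracks: TypingSequence[Track], gt: GroundTruth) -> dict[str, float]:
    """Identity switches, fragmentation, and purity against generator truth.

    Predicted links are (timepoint, cell_id) pairs resolved to true track
    ids through the ground truth.  Fragmentation counts, per true track,
    the number of extra predicted tracks covering it.  An identity switch
    is an adjacent-link pair within one predicted track whose true id
    changes — except when the change follows a recorded division (parent to
    daughter), which is lineage, not error.  Purity is the mean fraction of
    links in each predicted track belonging to its most frequent true id.
    """
    frag_cover: dict[int, set[int]] = {}
    switches = 0
    purities: list[float] = []
    for tr in tracks:
        true_ids = []
        for (t, ref) in tr.links:
            key = (t, ref)
            if key not in gt.track_of:
                raise ValueError(f"predicted link {key} absent from ground truth")
            true_ids.append(gt.track_of[key])
        for tid in true_ids:
            frag_cover.setdefault(tid, set()).add(tr.track_id)
        for a, b in zip(true_ids, true_ids[1:]):
            if b != a and gt.parent.get(b) != a:
                switches += 1
        if true_ids:
            majority = max(set(true_ids), key=true_ids.count)
            purities.append(true_ids.count(majority) / len(true_ids))
    fragmentation = sum(len(s) - 1 for s in frag_cover.values())
    return {
        "identity_switches": switches,
        "fragmentation": fragmentation,
        "track_purity": float(np.mean(purities)) if purities else 1.0,
    }


def truth_detections(frame_cells) -> tuple[list[Detection], list[int]]:
    """Build oracle detections (confidence 1) from a frame's annotated cells."""
    dets, refs = [], []
    for c in frame_cells:
        dets.append(Detection(box=c.box, confidence=1.0, mask=c.mask))
        refs.append(c.cell_id)
    return dets, refs
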