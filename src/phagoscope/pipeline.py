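"""End-to-end orchestration: detect -> segment -> classify -> track -> summarize.

Also hosts the transition summaries (per-timepoint class counts and
percent-activated curves), the model-agnostic occlusion-saliency surrogate
for explainability, and the dataset-statistics entry point (class
proportions, cells-per-image range, morphology contrast) that can be
pointed at real annotated data.

Every run is reproducible: all stage parameters live in one serializable
config, randomness flows from one seed, and the output bundle is
byte-deterministic except for the wall-clock timings, which are isolated in
their own ``timing.json`` sidecar.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence as TypingSequence

import numpy as np
import pandas as pd
import yaml

from . import detect_eval, puncta, tracker
from .detect_eval import DetectorParams
from .io_cellular import Sequence
from .puncta import SpotParams
from .tracker import TrackerConfig


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters of one pipeline run."""

    confidence_threshold: float = 0.65
    percentile: float = 95.0
    feature: str = "max_area"
    activation_threshold: float | str = "auto"  # number, or "auto" to calibrate
    detector: DetectorParams = field(default_factory=DetectorParams)
    spots: SpotParams = field(default_factory=SpotParams)
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (("detector", DetectorParams), ("spots", SpotParams), ("tracker", TrackerConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text) or {})

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class TransitionSummary:
    """Per-timepoint class counts, per-track label sequences, percent activated."""

    counts: dict[int, dict[str, int]]
    track_sequences: dict[int, list[tuple[int, str]]]
    percent_activated: dict[int, float]
    condition: str

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "counts": {str(t): c for t, c in sorted(self.counts.items())},
            "percent_activated": {str(t): v for t, v in sorted(self.percent_activated.items())},
            "track_sequences": {
                str(tid): [[t, lbl] for t, lbl in seq]
                for tid, seq in sorted(self.track_sequences.items())
            },
        }


def summarize_transitions(
    tracks: TypingSequence[tracker.Track],
    labels: dict[tuple[int, int], str],
    condition: str,
) -> TransitionSummary:
    """Aggregate per-(track, timepoint) labels into the transition summary.

    ``labels`` maps (track_id, timepoint) to a class label; every labelled
    pair must correspond to an existing track link.  Percent activated at a
    timepoint is activated / (basal + activated) * 100 — unidentified cells
    are excluded from the denominator.
    """
    links = {(tr.track_id, t) for tr in tracks for (t, _) in tr.links}
    for key in labels:
        if key not in links:
            raise ValueError(f"label attached to nonexistent track link {key}")
    counts: dict[int, dict[str, int]] = {}
    seqs: dict[int, list[tuple[int, str]]] = {}
    for (tid, t), lbl in sorted(labels.items(), key=lambda kv: (kv[0][0], kv[0][1])):
        counts.setdefault(t, {"basal": 0, "activated": 0, "unidentified": 0})
        counts[t][lbl] = counts[t].get(lbl, 0) + 1
        seqs.setdefault(tid, []).append((t, lbl))
    pct = {}
    for t, c in counts.items():
        denom = c.get("basal", 0) + c.get("activated", 0)
        pct[t] = 100.0 * c.get("activated", 0) / denom if denom else 0.0
    return TransitionSummary(counts=counts, track_sequences=seqs, percent_activated=pct, condition=condition)


@dataclass
class SaliencyResult:
    """Occlusion saliency: per-position drop grid and its image-size heatmap."""

    grid: np.ndarray
    heatmap: np.ndarray


def occlusion_saliency(
    classifier: Callable[[np.ndarray], np.ndarray],
    cell_image: np.ndarray,
    patch: int,
    stride: int,
    fill: Optional[float] = None,
) -> SaliencyResult:
    """Model-agnostic input-space saliency by patch occlusion.

    Each patch on the stride grid is replaced by ``fill`` (default: the
    image background median) and the drop in the predicted class score is
    recorded; drops are clipped at 0.  The heatmap paints each grid cell's
    drop over its patch footprint (overlaps averaged) at image size.
    """
    img = np.asarray(cell_image, dtype=np.float64)
    h, w = img.shape[:2]
    if patch > min(h, w):
        raise ValueError("patch must not exceed the image size")
    base = np.asarray(classifier(img), dtype=np.float64)
    if not np.all(np.isfinite(base)):
        raise ValueError("classifier returned non-finite scores")
    pred = int(np.argmax(base))
    if fill is None:
        fill = float(np.median(img))
    ys = list(range(0, h, stride))
    xs = list(range(0, w, stride))
    grid = np.zeros((len(ys), len(xs)))
    heat = np.zeros((h, w))
    norm = np.zeros((h, w))
    for gi, y in enumerate(ys):
        for gj, x in enumerate(xs):
            y1, x1 = min(y + patch, h), min(x + patch, w)
            occluded = img.copy()
            occluded[y:y1, x:x1] = fill
            scores = np.asarray(classifier(occluded), dtype=np.float64)
            if not np.all(np.isfinite(scores)):
                raise ValueError("classifier returned non-finite scores")
            drop = max(float(base[pred] - scores[pred]), 0.0)
            grid[gi, gj] = drop
            heat[y:y1, x:x1] += drop
            norm[y:y1, x:x1] += 1.0
    heat = np.divide(heat, norm, out=heat, where=norm > 0)
    return SaliencyResult(grid=grid, heatmap=heat)


def replicate_dataset_statistics(frames: TypingSequence) -> dict:
    """Pooled class percentages, cells-per-image range, morphology contrast.

    Point this at annotated frames (real or synthetic) to reproduce
    dataset-level statistics: the basal/activated/unidentified class mix,
    the min/max cell count per image, and the basal-vs-activated area and
    circularity contrast with Welch t-tests.
    """
    if not frames:
        raise ValueError("need at least one annotated frame")
    n_per_frame = [len(f.cells) for f in frames]
    all_cells = [c for f in frames for c in f.cells]
    if not all_cells:
        raise ValueError("zero cells across all frames")
    n = len(all_cells)
    pct = {
        lbl: 100.0 * sum(1 for c in all_cells if c.label == lbl) / n
        for lbl in ("unidentified", "basal", "activated")
    }
    report: dict = {
        "n_cells": n,
        "n_images": len(frames),
        "class_percentages": pct,
        "cells_per_image": {"min": int(min(n_per_frame)), "max": int(max(n_per_frame))},
    }
    ba = [c for c in all_cells if c.label in ("basal", "activated")]
    if sum(c.label == "basal" for c in ba) >= 2 and sum(c.label == "activated" for c in ba) >= 2:
        morphs = [puncta.cell_morphology(c.mask, c.cell_id) for c in ba]
        report["morphology"] = puncta.compare_classes(morphs, [c.label for c in ba])
    return report


class PipelineError(RuntimeError):
    def __init__(self, stage: str, timepoint: Optional[int], cause: Exception):
        where = f"stage {stage!r}" + (f" at frame {timepoint}" if timepoint is not None else "")
        super().__init__(f"pipeline failed in {where}: {cause}")
        self.stage = stage
        self.timepoint = timepoint


def run_pipeline(seq: Sequence, config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run detect -> filter -> spots -> classify -> track -> summarize on one sequence.

    Writes the full bundle (detections.csv, spots.csv, tracks.csv,
    summary.json, run.json, timing.json) under ``out_dir`` and returns the
    summary dict.  Any stage error removes partial outputs and raises
    :class:`PipelineError` naming the stage and frame.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    timings: dict[str, float] = {}
    stage, tp = "setup", None
    try:
        # --- detection -----------------------------------------------------
        stage = "detect"
        t0 = time.perf_counter()
        frame_dets = []
        for tp, frame in enumerate(seq.frames):
            dets = detect_eval.reference_detect(frame, config.detector)
            dets = detect_eval.filter_by_confidence(dets, config.confidence_threshold)
            frame_dets.append(dets)
        tp = None
        timings["detect"] = time.perf_counter() - t0

        det_rows = [
            {"timepoint": t, "det_index": j, **dict(zip(("x0", "y0", "x1", "y1"), d.box.as_tuple())),
             "confidence": round(d.confidence, 6)}
            for t, dets in enumerate(frame_dets)
            for j, d in enumerate(dets)
        ]

        # --- spot segmentation --------------------------------------------
        stage = "spots"
        t0 = time.perf_counter()
        spot_rows = []
        records_by_frame: list[list[puncta.SpotRecord]] = []
        for tp, (frame, dets) in enumerate(zip(seq.frames, frame_dets)):
            recs = []
            for j, d in enumerate(dets):
                rec = puncta.segment_spots(frame.channels["red"], d.mask, config.spots, cell_id=j)
                recs.append(rec)
            records_by_frame.append(recs)
        tp = None
        timings["spots"] = time.perf_counter() - t0

        # --- classification ------------------------------------------------
        stage = "classify"
        t0 = time.perf_counter()
        feat_of = {"max_area": lambda r: r.max_area, "total_area": lambda r: r.total_area}[config.feature]
        usable = [
            (t, r) for t, recs in enumerate(records_by_frame) for r in recs if not r.no_spots
        ]
        if usable:
            raw = [feat_of(r) for _, r in usable]
            transformed = puncta.normalize_and_log(raw, [seq.replicate_id] * len(raw))
            for (_, r), v in zip(usable, transformed):
                r.feature = float(v)
        if isinstance(config.activation_threshold, (int, float)):
            threshold = float(config.activation_threshold)
        else:
            calib_t = 1 if seq.condition == "fed" else 0
            calib = [r.feature for t, r in usable if t == calib_t]
            threshold = puncta.activation_threshold(calib, config.percentile) if len(calib) >= 2 else float("inf")
        labels_by_frame: list[dict[int, str]] = []
        for recs in records_by_frame:
            with_spots = [r for r in recs if not r.no_spots]
            if np.isfinite(threshold):
                labels_by_frame.append(
                    puncta.classify_by_threshold(with_spots, threshold, config.feature))
            else:  # no calibration population (e.g. empty input): nothing classified
                labels_by_frame.append({})
        for t, recs in enumerate(records_by_frame):
            for r in recs:
                spot_rows.append({
                    "timepoint": t, "det_index": r.cell_id, "spot_count": r.spot_count,
                    "total_area": r.total_area, "max_area": r.max_area,
                    "feature": round(r.feature, 6) if r.feature is not None else "",
                    "label": labels_by_frame[t].get(r.cell_id, "no_spots"),
                })
        timings["classify"] = time.perf_counter() - t0

        # --- tracking ------------------------------------------------------
        stage = "track"
        t0 = time.perf_counter()
        seq_feats = []
        for frame, dets in zip(seq.frames, frame_dets):
            rgb = frame.merged_rgb()
            feats = []
            for d in dets:
                crop = rgb[d.box.y0:d.box.y1, d.box.x0:d.box.x1]
                m = d.mask[d.box.y0:d.box.y1, d.box.x0:d.box.x1] if d.mask is not None else None
                feats.append(tracker.embed_cell(detect_eval.apply_mask(crop, m) if m is not None else crop, m))
            seq_feats.append(feats)
        tracks = tracker.track_sequence(frame_dets, seq_feats, config=config.tracker) if any(
            frame_dets) else []
        timings["track"] = time.perf_counter() - t0

        # --- summary -------------------------------------------------------
        stage = "summarize"
        t0 = time.perf_counter()
        track_labels: dict[tuple[int, int], str] = {}
        for tr in tracks:
            for (t, ref) in tr.links:
                lbl = labels_by_frame[t].get(ref)
                if lbl is not None:
                    track_labels[(tr.track_id, t)] = lbl
        summary = summarize_transitions(tracks, track_labels, seq.condition)
        timings["summarize"] = time.perf_counter() - t0

        # --- outputs -------------------------------------------------------
        stage = "write"
        det_cols = ["timepoint", "det_index", "x0", "y0", "x1", "y1", "confidence"]
        spot_cols = ["timepoint", "det_index", "spot_count", "total_area", "max_area", "feature", "label"]
        p = out / "detections.csv"
        pd.DataFrame(det_rows, columns=det_cols).to_csv(p, index=False)
        written.append(p)
        p = out / "spots.csv"
        pd.DataFrame(spot_rows, columns=spot_cols).to_csv(p, index=False)
        written.append(p)
        p = out / "tracks.csv"
        track_rows = [
            {"track_id": tr.track_id, "timepoint": t, "det_index": ref,
             "status": tr.status, "parent_track_id": tr.parent_track_id if tr.parent_track_id is not None else ""}
            for tr in tracks for (t, ref) in tr.links
        ]
        pd.DataFrame(track_rows, columns=["track_id", "timepoint", "det_index", "status", "parent_track_id"]).to_csv(p, index=False)
        written.append(p)
        p = out / "summary.json"
        bundle_summary = {
            "threshold": threshold if np.isfinite(threshold) else None,
            "n_detections": sum(len(d) for d in frame_dets),
            "n_tracks": len(tracks),
            "n_no_spot_cells": sum(r.no_spots for recs in records_by_frame for r in recs),
            "transitions": summary.to_dict(),
        }
        p.write_text(json.dumps(bundle_summary, indent=2, sort_keys=True))
        written.append(p)
        p = out / "run.json"
        p.write_text(json.dumps(
            {"config": config.to_dict(), "config_hash": config.digest(), "seed": config.seed,
             "condition": seq.condition, "replicate_id": seq.replicate_id},
            indent=2, sort_keys=True, default=str))
        written.append(p)
        # wall-clock timings are the one non-deterministic artifact; they live
        # in their own sidecar so the rest of the bundle is byte-stable
        (out / "timing.json").write_text(json.dumps({k: round(v, 4) for k, v in timings.items()}, indent=2))
        return bundle_summary
    except Exception as e:  # noqa: BLE001 - abort cleanly naming the stage
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(e, PipelineError):
            raise
        raise PipelineError(stage, tp, e) from e
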