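# Methods

## The synthetic world

The generator (`phagoscope.synthgen`) emulates the *statistical structure*
of annotated tandem-reporter time-lapse data, not microscope physics: no
point-spread function, photobleaching, or pH kinetics. Each sample is five
hourly frames of three channels (green, red, transmitted light).

**Cells** are radial-perturbation polygons: 10–16 vertices at radius
`r·(1+ε)`, ε ~ N(0, 0.12), rasterized and morphologically closed with a
2-px disk. Base radius is N(12, 1.5) px on a 256-px frame (defaults).
Centroids drift by N(0, 2 px) per frame, reflected at a border margin.
Within a frame, later-rendered cells are clipped against already-claimed
pixels, so masks are pairwise disjoint by construction.

**Reporter rule.** Basal cells carry 2–4 puncta of radius 1.5–2.5 px
rendered into *both* green and red channels (autophagosomes, yellow);
activated cells carry 5–9 puncta at 2× radius rendered into red *only*
(autolysosomes). Cell bodies render at intensity 40 in both fluorescence
channels over background 10, puncta add 150, and N(0, 2) read noise is
added per channel and clipped at zero. Every rendered punctum's center,
radius, and exact in-mask rasterized area is recorded as ground truth, so
spot segmentation has a pixel-exact oracle.

**Transitions.** Under the fed condition no cell ever transitions. Under
starvation each lineage draws a transition frame from round(N(2, 1))
clamped to [0, 5], values ≥ 5 meaning "never"; the label is activated from
that frame on and never reverts. Daughters inherit the parent's schedule.

**Divisions** occur per cell per frame with probability 0.02: the parent
track retires and two daughters of radius r/√2 appear at ±1 parent radius
along a random axis, each with a fresh track id and `parent_track_id`
recorded.

**Morphology contrast.** As a config option (not asserted biology), basal
cells are drawn larger and rougher: radius scaled by √1.13 (the expected
polygon area is proportional to the squared base radius and, to first
order, independent of the perturbation sd, so this plants a +13 % area
contrast directly) and perturbation sd raised by 0.05 (lower circularity).
`generate_morphology_population` rasterizes standalone masks with the same
plant for population-level studies.

All randomness flows from one `numpy` generator seeded by the config;
identical configs reproduce sequences bit for bit.

**What a green test does not establish.** Synthetic cells are compact,
well-separated, high-contrast blobs with stationary noise. Real microscopy
has uneven illumination, debris, out-of-focus cells, dense clusters, and
annotation noise; none of the fixture-calibrated defaults (detector
smoothing/area, spot threshold, tracker gates) are claimed to transfer.

## Reference detector

`reference_detect` is a classical stand-in for a trained detector:
Gaussian smoothing (σ = 2) of green + red, Otsu threshold on the
log1p-compressed image (bright puncta otherwise pull the threshold above
the cell-body level and fragment activated cells), a foreground-contrast
guard (mean fg < 1.5× mean bg ⇒ no detections, since Otsu will happily
split pure noise), minimum area 60 px, and a distance-transform watershed
(peak separation 10 px) to split touching cells. Confidence is the
component's mean smoothed intensity normalized by the global foreground
mean, clipped to [0, 1] — a typically bright cell scores near 1 and dim
low-contrast components fall under the default 0.65 confidence filter.

## Detection and segmentation metrology

Average precision is COCO-style: greedy confidence-ordered one-to-one
matching per image, pooled ranking, 101-point interpolation with the
precision envelope (max precision at recall ≥ r). mAP50-95 averages AP
over IoU 0.50:0.05:0.95. Zero ground truths make AP undefined (an error,
not 0). Pixel metrics come from the foreground confusion matrix; the
empty-vs-empty case defines IoU = F1 = precision = recall = 1 (both agree
there is nothing).

## Punctum quantification and threshold classification

Within each cell mask: white top-hat (4-px disk) background removal, a
robust per-cell threshold (median + 5·MAD of the top-hat response over the
mask), 8-connected components, minimum spot area 3 px. Cells with no
surviving spot are flagged and excluded from thresholding rather than
imputed (log of zero area is undefined).

The per-cell activation feature is the **maximum** spot area (a single
large autolysosome is the biologist's cue; total area is available via
config). Features are divided by the within-replicate median and
log10-transformed — in that order; the transform is invariant to scaling
any replicate's raw values. The activation threshold is the
linear-interpolation (type 7) 95th percentile of fed cells at timepoint 1.

A caveat the synthetic world makes vivid: median normalization assumes
replicates have comparable class composition. Normalizing a
starved-only, mostly-activated population by its own median recenters the
activated cells at zero and the fed-calibrated threshold misclassifies
nearly everything. Fed and starved sequences belonging to one experiment
replicate must be normalized in one pool; the pipeline treats one input
sequence as one replicate and the "auto" threshold calibrates on fed cells
at timepoint 1 when present, else on the input's timepoint-0 cells.

Morphology: area is the foreground pixel count, perimeter the Crofton
4-direction estimate, circularity 4πA/P² clipped at 1 (the estimator can
slightly overshoot on small discs). Class comparison uses Welch's
(unequal-variance) two-sided t-test; percent differences are
(basal − activated)/activated × 100. Classification metrics are computed
from the confusion matrix: accuracy, macro-averaged precision/recall/F1,
and MCC in the covariance (Gorodkin) form, which reduces to the binary
formula for two classes.

## Tracker

Costs mix spatial distance (normalized by the gate radius D, default 3×
the median detected cell diameter), appearance cosine distance, and box
overlap with weights 0.4/0.4/0.2; pairs beyond D are forbidden. Active and
inactive tracks compete jointly each frame, inactive ones paying a 0.1
surcharge; assignment is solved with `scipy.optimize.linear_sum_assignment`
(forbidden entries replaced by a penalty larger than any feasible total and
stripped afterwards, yielding the minimum-cost maximal sentinel-free
matching). Among equal-cost optima the solver's deterministic internal
tie-break is used; same input always gives the same output. There is no
motion model: five frames are too few to estimate velocities, so the last
observed position is the prediction. Inactive tracks never expire within a
sequence.

The reference appearance embedding concatenates per-channel 16-bin
intensity histograms (each channel min-max normalized within the mask, so
histograms are gain-invariant), mask area and circularity, per-channel
means, and a reporter-aware punctum block — per-channel bright-pixel
fraction (above in-mask median + 5·MAD) and the Jaccard overlap of the red
and green bright sets, weighted ×2. The punctum block is essential: body
pixels dominate the histograms, and without it two cells with completely
different punctum patterns embed at cosine ≈ 0.999, leaving the appearance
term inert. With it, same-cell adjacent-frame similarity stays ≥ ~0.87
while basal-vs-activated pairs fall to ~0.55. Any function mapping a
masked crop to a fixed-length vector (e.g. a neural encoder) plugs in
through the same contract.

Division: an unmatched detection whose box overlaps a matched track's
previous box by IoU ≥ 0.15 becomes a daughter with lineage recorded.
(A daughter displaced by one parent radius overlaps the parent's former
box by only ~0.2 IoU, so a noticeably higher threshold would never fire on
a geometrically plain division.)

Tracking metrics are lineage-aware: an adjacent-link change of true
identity inside a predicted track counts as an identity switch *unless*
the new true track is a recorded daughter of the old one — a tracker that
carries the parent track into one daughter is following lineage, not
erring. Fragmentation is, per true track, the number of distinct predicted
tracks covering it minus one, summed; purity is the mean majority-identity
fraction per predicted track.

## Pipeline and saliency

The stage order is fixed: detect → confidence filter (0.65) → per-cell
spot segmentation → threshold classification → tracking → transition
summary. Percent activated per timepoint is activated/(basal + activated)
× 100; unidentified cells are excluded from the denominator (configurable).
The bundle is byte-deterministic for a given config and input; wall-clock
timings are isolated in `timing.json` so the rest can be compared
byte-for-byte. A stage failure removes partial outputs and raises an error
naming the stage and frame.

Occlusion saliency is the model-agnostic input-space analogue of
feature-ablation explanations: each patch on the stride grid is replaced
by the image background median (not zero, to avoid out-of-distribution
artifacts; configurable) and the drop in the predicted class score is
recorded, clipped at 0. For an additive classifier and stride = patch the
grid equals the per-patch contributions exactly.

## Numerical choices and degenerate inputs

- Percentiles: linear interpolation between order statistics (type 7).
- Box dialect conversion (absolute half-open ↔ YOLO normalized center)
  rounds to nearest integer with ties toward +∞ and is exact on boxes
  representable on the normalization grid.
- Empty masks, empty calibration sets, zero ground truths, and non-finite
  scores are errors, not silent zeros; an empty input sequence runs the
  pipeline to completion with empty tables.
- A stored bounding box that does not enclose its mask is kept with a
  machine-readable warning (annotation inconsistencies exist in real
  data); tightness is advisory.

## Known limitations

- The detector and all fixture-calibrated defaults target the generator's
  default config only; they are not a general microscopy segmenter.
- The threshold classifier inherits the composition sensitivity of median
  normalization described above.
- Tracking quality is only assessable against synthetic truth here; no
  claim is made about crowded real-data scenes with >100 cells/frame.
- The saliency surrogate explains whatever classifier it is handed; it
  says nothing about the internals of CNN/transformer models.
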