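# Methods

This note documents the models and procedures implemented in
`mothtrap`, the parameters that matter, the numerical conventions, and
what the synthetic data does and does not establish.

## Imaging model and segmentation

The trap images insects resting on a uniformly illuminated white sheet
from a fixed camera (native 3840×2160). Because the background is
static and bright, detection reduces to background subtraction: frames
are converted to grayscale with BT.601 luma weights and the absolute
difference from a fixed empty-sheet reference is taken. The absolute
value is deliberate — most moths are darker than the sheet, but pale
species and specular wing reflections can be brighter.

The difference image is binarised with Otsu's threshold, which
maximises the between-class variance of the gray histogram. Foreground
is the above-threshold side. A constant difference image (no insects,
no noise) has no two-class structure; by convention it yields an
all-background mask rather than an error. For 8-bit input the
threshold is computed on the integer histogram, so it agrees exactly
with an exhaustive sweep over all gray levels (this is property-tested).

Binarisation is followed by a morphological opening (square side 5 px,
removes noise specks) and closing (square side 7 px, fuses small gaps
inside one insect). Neither size is prescribed by the trap's imaging
geometry; both are configurable. Connected components with area
≥ `min_blob_area` (default 2500 px, about the area of the smallest
insects of interest at this working distance, and the same magnitude
as the capture software's 1500-changed-pixel trigger) become
detections. The reported centroid is the bounding-box centre, which is
what the tracker matches on. Coordinates are 0-based, origin top-left,
boxes half-open.

Known failure mode, reproduced faithfully: two insects sitting closer
than the closing kernel merge into a single blob and cannot be
separated at this stage.

The optional motion gate accepts a frame when strictly more than
`motion_gate_pixels` (default 1500) pixels changed by more than
`motion_gate_delta` gray levels (default 25) since the previous frame.
The per-pixel delta of the original capture software is not public;
it is exposed as configuration.

## Tracking by assignment

Insects are near-stationary between captures (0.5–2 s apart), so
frame-to-frame association is solved as a linear assignment between
the previous and current detections. The pairing cost combines the
centroid distance, normalised by the image diagonal so it lies in
[0, 1], with the bounding-box area dissimilarity
1 − min(A₁,A₂)/max(A₁,A₂):

    cost = (dist / diagonal) · Wdist + (1 − areacost) · Warea

Defaults are Wdist = 0.8, Warea = 0.2: distance dominates because a
resting moth rarely moves, while the area term disambiguates
similar-position pairs of different size. The matrix is padded to
square with dummy rows/columns at cost 2·(Wdist + Warea), strictly
above any achievable real cost and scale-free in the weights; a real
detection assigned to a dummy is an entry (new track) or exit (track
closed). The optimal assignment is computed with the Hungarian method
(scipy's `linear_sum_assignment`); tests verify optimality against
brute-force enumeration of all permutations up to 7×7.

Design choices made where the design was open:

- Tracks matched to a dummy close immediately; there is no coasting,
  occlusion memory, or re-identification. An insect that leaves and
  returns is a new individual — this matches the field protocol, which
  accepts double-counting of returning individuals.
- Ties between equal-cost assignments may resolve either way; tests
  assert the optimal total cost, not a particular matching, when ties
  exist.
- Track IDs are unique within a run and never reused.

## The classifier family

The classifier is a deliberately small CNN for 10 classes (eight
noctuid moth taxa — one of them, the *Hoplodrina* complex, pooling
three visually inseparable species — plus the wasp *Vespula vulgaris*
and a background class). Small matters: the training sets obtainable
from a single trap are tiny (hundreds of images per class), and the
model must run on embedded hardware.

The family is parameterised by the first/last convolution's kernel
size k ∈ {1,3,5} and depth d ∈ {32,64,128} and the hidden dense width
fc ∈ {256,512}; the two middle convolutions are fixed at 64 kernels of
3×3. Every convolution is 'same'-padded with ReLU and followed by 2×2
stride-2 max pooling, so a 128×128×3 input leaves an 8×8 map after the
fourth pool and the flatten width is 64·d_last (4096 for the chosen
member). One hidden dense layer of width fc with dropout 0.3 after it
feeds the 10-way softmax. This is the only layer layout under which
the closed-form parameter accounting

    conv: (k²·c_in + 1)·c_out        dense: (n_in + 1)·n_out

reproduces all published totals of the 64-architecture search grid
exactly (e.g. 2,197,578 for {5,3,32,64,512}); in particular the
"4096-neuron hidden layer" is the flatten output, not an extra dense
layer, and the output width is 10. The accounting is property-tested
against the number of weights the instantiated network allocates over
the whole default grid. One printed grid total ({5,3,32,32,512} at
2,164,810) is not reproducible under any consistent reading of the
layout — the closed form gives 1,130,538 — and the implementation
reports the computed value.

The printed option sets generate more than 64 combinations, so the
exact trained subset is not recoverable; `enumerate_grid` defaults to
the full Cartesian product (which contains every published row) and
accepts arbitrary subsets.

Detections are cropped with 10% padding per side, expanded to a square
(so the aspect ratio survives), clipped to the frame, and bilinearly
resized to 128×128 — about a 2.9× reduction for the average 368×353
annotation. Pixel values are scaled to [0, 1]; augmentation draws
horizontal/vertical flips, rotations up to ±30°, centre zoom up to
1.25×, and illumination gain in [0.7, 1.3] from a seeded generator,
exactly `factor` crops per input with the original always included.

Training uses a stratified 80/20 train/validation split, Adam
(learning rate 10⁻³) or SGD (0.01, momentum 0.9), batch size 32,
softmax cross-entropy. Epoch count is workload-dependent: the
separable synthetic dataset converges within one epoch; real imagery
needs more. The validation report carries the confusion matrix,
per-class precision/recall/F1 and macro F1.

### The numpy engine

The network runs on an in-package engine written against float32
numpy: convolutions are lowered to BLAS matrix products via im2col,
and the data gradient is computed as a full convolution with the
spatially flipped, channel-transposed kernels, so the backward pass is
also pure gemm (no scatter). The first convolution skips its input
gradient. Max-pool backward routes gradients through the stored
argmax; dropout is inverted (identity at inference). Gradients are
verified against central differences in a kink-free linear setting
(ReLU/max-pool kinks make naive whole-network numeric checks
unreliable at float32). Adam and SGD follow the standard update rules
with bias correction.

## Counting

Per-frame predictions along a track are aggregated by majority vote;
ties break toward the label of the earliest frame (deterministic and
order-stable). A track whose winning label is the background class, or
whose winning label's mean softmax confidence is below
`unknown_threshold` (default 0.5 — the unknown category is described
without a published rule, so a neutral majority-confidence cut is
used), is counted as *unknown*. A track enters the counts only if its
longest run of consecutive processed frames is at least
`min_consecutive` (default 3; the source material states the rule
once as "more than three" and once as "at least three" — resolved as
≥ 3 and configurable). Short-lived near-lens fliers fail this filter,
which is what keeps them out of the totals.

## Evaluation

TDR = TP/GT and FAR = FP/(TP+FP), where GT is the number of unique
individuals in the ground truth, TP the number of individuals covered
by exactly one track over their whole presence, and FP every other
produced track (splits, duplicates, spurious blobs). Matching a track
to an individual is an artifact decision (the original evaluation was
by manual video review): each track frame is attributed to the
individual whose ground-truth box contains the track centroid (nearest
centroid within 50 px as fallback when no boxes are given), a track is
owned by the individual winning a strict majority of its frames, and a
TP requires the single owning track to span the individual's full
first-to-last frame interval.

Per-class precision TP/(TP+FP), recall TP/(TP+FN) and
F1 = 2TP/(2TP+FP+FN) are reported with undefined denominators as
absent, not zero. Report rounding is half-up to two decimals. On the
published three-night totals (TP 357, FP 168, FN 128) the computed
precision is 357/525 = 0.68, which differs from the printed 0.69 in
the source table; the implementation reports the computed value.

## Synthetic data

`generate_scene` renders the imaging situation the trap creates —
near-white sheet (intensity 235, Gaussian noise σ 3), dark striped
elliptical insects with bounding boxes drawn from the trap's annotated
size statistics (mean 368×353 px, sd 110, truncated below at 120 px),
mostly stationary motion (stationary probability 0.9, jitter σ 2 px,
optional jumps), per-insect entry/exit spans, optional touching pairs
and large near-lens transients — with an exact per-frame ground-truth
table. The default frame is 1920×1080 rather than the native
3840×2160; rendering and segmenting the full resolution works but is
four times slower, and every pipeline operator is resolution-agnostic,
so the reduced default is used for the test scenes. Generation is a
pure function of the configuration (including its seed): identical
configurations give byte-identical frames.

`generate_crop_dataset` produces 128×128×3 crops whose classes own
distinct stripe orientations, spatial frequencies and base colors, so
they are separable by construction.

What passing on synthetic data shows — and does not. The scenes
exercise the pipeline's geometry and logic: contrast-based
segmentation, assignment under near-stationary motion, entry/exit
handling, transient filtering, count bookkeeping. They do not contain
shadows, dew, wing-posture variation, partial visibility at frame
edges, or photo-realistic insect appearance, and the procedural crop
classes are far more separable than real congeneric moths. A classifier
at 0.9+ macro F1 on the synthetic crops therefore validates the
training machinery, not field-level species accuracy; real deployments
must be validated against annotated trap imagery.

## Degenerate inputs and numerical conventions

- Constant images binarise to all-background; empty frames produce
  empty detection lists; an empty detection list is a valid tracker
  update (all tracks close).
- Zero or negative blob areas, degenerate boxes, and centroids outside
  their box are rejected at construction.
- The assignment matrix must be finite and square; both-empty frames
  produce an empty matrix and a no-op.
- Augmentation, initialisation, dropout, splits and scene generation
  all draw from explicitly passed seeded generators; there is no
  hidden global random state.

## Known limitations

- Touching insects merge into one detection (inherent to blob
  segmentation); the tracker then sees one object.
- No occlusion handling or track revival; brief detection dropouts
  split tracks and inflate FAR.
- The classifier trains on CPU via BLAS; a full-size training run at
  realistic dataset scale takes minutes per epoch, and GPU execution
  is out of scope.
- Per-track filters beyond the consecutive-frame rule and the minimum
  blob area (the source material alludes to further adjusted noise
  filters without specifying them) are not implemented.
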