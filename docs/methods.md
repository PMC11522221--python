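# Methods

## Problem and model

`skelseg` segments the skeleton (cortical bone plus marrow) from axial CT
slices.  The core is a standard 2D U-Net classified per pixel, but most of
the engineering lives in the deterministic geometry and bookkeeping around
it: couch removal, Hounsfield-unit conditioning, randomized dataset
construction, and pixel-wise evaluation.  This note records the model,
its assumptions, the tunable parameters, and the design choices made where
the design was genuinely open.

## Stretcher (couch) removal

The couch is a high-attenuation curved shell near one image edge.  The
algorithm assumes a frame in which the couch faces the **left** edge; the
`orientation` load flag (`as-is`, `rotate90/180/270`, `flip-lr`) brings
arbitrary exports into that frame, since on-disk orientation varies by
scanner and export path.

Steps, all 0-based with rows top-to-bottom and half-open band intervals:

1. Binarize at **98 HU, inclusive** (≥).  Inclusivity keeps boundary
   voxels of thin couch shells; the alternative (strict >) differs only on
   exact-98 voxels.
2. The couch candidate is the 8-connected foreground component whose
   leftmost pixel is closest to the left margin, restricted to components
   starting in the left third of the image.  No candidate raises a named
   error so callers can skip removal per slice.
3. For each of three row-band groups — central (R4–R5), inclined (R3,
   R6), extreme (R2, R7) — the couch's inner edge is its rightmost column
   within those rows and the body limit is the leftmost non-couch
   foreground column more than `gap` (default 5 px) to its right; the
   separating line (`i1`, `i2`, `i3` respectively) is the **integer
   midpoint** of the two.  The midpoint is symmetric and robust; any
   monotone interpolant between the limits would satisfy the same
   sandwich property.  Ordering `i3 ≤ i2 ≤ i1` is enforced by a min
   cascade; on couch-shaped geometry it holds without clamping.
4. The image height is cut into eight near-equal bands (`⌊kH/8⌋`
   boundaries, heights differing by at most one pixel).  The margin
   column follows the band schedule i3, i3, i2, i1, i1, i2, i3, i3; at a
   boundary where the column changes the polyline passes through the
   larger of the two adjacent columns (one vertex per boundary), and the
   line extends vertically on i3 to the top and bottom rows.  Taking the
   max at boundaries keeps the margin on the body side of both adjacent
   bands' couch edges.  When the three lines are distinct the eight
   vertical/horizontal intersection points are labelled Pe1, Pi1, Pi3,
   Pe3, Pe4, Pi4, Pi2, Pe2 in top-to-bottom traversal order.
5. The couch mask is every pixel left of (or on) the margin — row-wise a
   left-anchored run.
6. Per-slice adaptation: the reference mask (reference slice `auto` =
   largest couch cross-section, the safest template) is dilated with a
   **square** structuring element of radius 3 px (default), and any
   8-connected component of the slice's binarization whose overlap with
   the dilated mask exceeds the accessory fraction (default 0.5) is
   absorbed — this captures couch accessories and per-slice couch
   variation.  Masked voxels are set to 0 HU; all others are
   bit-untouched.  A volume with no couch anywhere is returned unchanged
   with a logged warning rather than an error.

## HU conditioning

Thresholding clamps to [0, 300] HU: at or below 0 lies air, lung and fat,
at or near/above 300 only skeleton, so the band isolates soft tissue,
marrow and cortical bone.  The operation is idempotent and runs **after**
couch removal, so zeroed couch pixels stay at the lower bound.

Normalization maps [minGL, maxGL] linearly to integer gray levels
[0, 255].  The anchors are taken to be the thresholding bounds (after
clamping they coincide with the volume minimum/maximum whenever both
extremes occur, which any body-containing CT satisfies); using the fixed
bounds makes the two experiment arms exactly equivalent in the
one-patient/one-set limit and avoids anchor drift on degenerate sets.
Integer conversion **rounds half away from zero** (127.5 → 128); the
rounding rule is otherwise unconstrained, and this matches common image
tooling.  Experiment A applies the normalization when a training set
(random slices of random patients) is assembled; Experiment B per patient
during preprocessing.

Clipping indices (first femur slice, first head slice) are caller-
supplied.  Automatic anatomical detection is out of scope; a naive
optional heuristic (`suggest_femur_start`: first slice whose ≥300 HU area
exceeds a pixel count) exists but is off by default.

## Dataset construction

Shuffling draws a **uniformly random patient among those with remaining
slices**, then a uniformly random remaining slice of that patient, until
none remain.  Uniform-over-patients (rather than weighted by remaining
slices) is the simplest reading of "a patient is randomly selected"; the
choice is isolated in one function and can be switched.  Partition: first
n−1 sets of size ⌈N/n⌉, last the remainder (N = 21,304, n = 5 gives
4261×4 + 4260); when the remainder would be non-positive (e.g. N = 11,
n = 5) the split falls back to balanced sizes and logs it.  Training
orders are pairwise-distinct uniform permutations (error if more than n!
are requested).  The cohort split takes ⌊fraction·N⌋ whole patients for
training (77 at 0.85 → 65/12).  All randomized operations are
reproducible bit-for-bit given their seed; the CLI derives per-stage
seeds from one global seed as `(seed·1000003 + stage_offset) mod 2^31`.

## Network and training

Five levels with channels F, 2F, 4F, 8F, 16F; two 3×3 convolutions +
ReLU per level; 2×2 max-pool down, 2×2 transposed-convolution up with
skip concatenation; 1×1 sigmoid head; probability cut **0.5, inclusive**.
Convolutions are "same"-padded so input and output resolutions match
(input divisible by 16).  Batch normalization is off.  Unstated training
hyper-parameters were fixed once as conventional choices and surfaced in
config: pixel-wise binary cross-entropy, Adam, learning rate 3e-3, batch
size 4, He initialization.  Inputs enter the network as normalized gray
levels rescaled to [0, 1]; this is an internal contract invisible to file
formats.

The network is implemented directly in numpy (im2col convolutions,
hand-written backward passes verified against central differences at
1e-4 relative tolerance, float64 throughout).  Training is therefore
bit-deterministic on a given platform; identical results across BLAS
builds are not promised.  Each epoch visits the five sets in the given
training order; batches traverse each set in its stored sequence, so the
order is the only stochastic schedule element.

Evaluation aggregates TP/TN/FP/FN globally over the test volume (not
per-slice averages).  Zero-denominator metrics are defined as 1.0
(vacuous agreement of two empty sets); an empty truth with a non-empty
prediction yields 0 through the ordinary formula.  Dice ≥ IoU holds
componentwise by the identity Dice = 2·IoU/(1+IoU).  A model predicting
all background on the test set is non-convergent and excluded from
best-cell selection (best = max Dice, then Dice(mask), then TP).

## Phantoms: what they emulate and what they do not

Each phantom slice has air (−1000 HU), an elliptical soft-tissue body
(40 HU), cortical annuli (700 HU) with marrow cores (100 HU), a couch
band (250 HU) whose inner edge follows the three-zone profile, optional
couch accessories (150 HU), and additive Gaussian noise (default
σ = 5 HU — low-dose CT soft-tissue noise is of this order, and it keeps
every tissue ≥ 6σ from the binarization and bone thresholds so truth
masks stay exact).  Labels and masks come from the same rasterization, so
ground truth is pixel-exact: at σ = 0, thresholding at 300 HU recovers
the cortical label set exactly.

Deliberately absent: beam hardening, reconstruction artifacts, partial-
volume edges, anatomic variety (vertebrae, ribs, metal), couch motion
between slices.  Passing phantom tests therefore demonstrates the
correctness of the geometry, bookkeeping and learning machinery — not
clinical-grade segmentation accuracy, which requires the clinical cohort
and full-scale training.

## Problem sizes

Default phantom resolution is 64×64 (a spec field, not a constant) with
8–16 slices per patient, chosen so the full pipeline including U-Net
training runs in CPU minutes.  The learning check trains F=2 for ten
epochs on ≥ 200 slices from a 27-patient cohort (five ordered sets) and
evaluates ≥ 50 held-out slices, requiring Dice(mask) ≥ 0.8 in at least
two of three fixed seeds; observed values are typically ≥ 0.94.  The
bookkeeping quantities (set sizes, cohort split, normalization anchors,
sample totals) are computed at the full clinical sizes, since they are
scale-independent arithmetic.

## Known limitations

- The couch must face one image edge and be the leftmost high-attenuation
  structure after reorientation; exotic couch geometries (e.g. lateral
  supports inboard of the body) would defeat the left-attached-component
  heuristic.
- Margin estimation uses one reference slice per patient; a couch that
  shifts grossly between slices is handled only through dilation and
  accessory absorption.
- The numpy engine is single-threaded beyond BLAS and intended for
  desk-scale inputs; clinical 512×512 training is out of its envelope by
  design.
- Patient-uniform shuffling, the midpoint margin rule, fixed normalization
  anchors and the half-away rounding are documented choices among several
  defensible ones; each is isolated behind one function.
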