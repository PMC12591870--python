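# Methods

This note records the models, conventions and design choices behind the
package, in the order a reader needs them: the activation decision
procedures, the detector family and its complexity accounting, the
training objective, the evaluation metrics, and what the synthetic data
does and does not establish.

## Activation decision procedures

The decision engine consumes per-frame detections (axis-aligned boxes
with class and confidence) and decides when the cutter slot is in
activation position relative to the tumor. The rules are pure geometry
(see README for the inequalities); configuration lives in
`DecisionConfig` with the clinical defaults: 20 px size margin, 0.2
horizontal slack factor, 1.1 vertical overlap factor, 1.2 similar-size
extension, 500 cumulative overlap frames. Choices made where the
published description is silent:

* **Boundary ties.** The size comparisons use strict inequalities
  (">20 px"), leaving |L1 − L2| = 20 unassigned; it is mapped to the
  similar-size regime, whose extension rule is the natural fallback, so
  the regime partition is total.
* **Real-valued geometry.** Detector outputs are sub-pixel; no rounding
  happens inside any predicate.
* **Multiple detections per class.** One box per class enters the rules:
  highest confidence, ties to larger area, then smaller x — the same
  deterministic choice a tracker-free post-processing stage would make.
* **Prompt uniqueness.** The prompt is an absorbing event: once emitted,
  a session never re-emits. Both procedures behave identically here.
* **Lateral-approach slot memory.** "Analyzing multi-frame images" is
  operationalized as requiring 5 consecutive slot sightings before the
  slot position is recorded; a later confirmed sighting replaces the
  memory. No motion compensation is applied to the remembered box — the
  workflow assumes the patient and cutter stay still while the probe
  moves.
* **Cumulative counter.** Overlap frames accumulate without reset
  (non-overlapping frames are neutral). `reset_on_miss=True` exposes the
  stricter consecutive reading but is off by default, matching the
  "cumulative number of frames" wording.
* **Known asymmetry.** In the slot-larger regime the horizontal rule
  `x1 − 0.2·L1 < x2` is satisfied by any tumor far to the slot's right;
  it is implemented exactly as specified, and users should treat the
  vertical rule as the effective gate in that regime.

Step functions are pure (state in, state out), so a recorded detection
stream replays to identical events; this is asserted by tests and used
by the session log's `replay()`.

## Detector family and layer plans

Four architectures are registered: the stock small baselines
(`yolov11n`, `yolov11s`, plus `yolov8s` as a comparison row) and the
lightweight variants (`yolov11n_plus`, `yolov11s_plus`). Every model is
declared as a YAML layer plan (`src/rotoloc/plans/`): nominal channels,
scaled at build time by `make_divisible(min(c, max_channels) * width, 8)`
with width 0.25 (n scale) or 0.5 (s scale) — the family-standard scaling.
Plans expand into a flat DAG of primitives (convolution + batch norm +
SiLU, max-pool, nearest upsample, concat, channel-chunk, attention)
executed by a small numpy engine with explicit backward passes.

The lightweight variants replace the backbone with
inverted-residual blocks (MIRB: 1x1 expand, depthwise 3x3/5x5, 1x1
project, residual when shapes allow) for low-level stages and universal
inverted-bottleneck blocks (MUIB: optional leading depthwise, expand,
optional mid depthwise, project) for mid/high-level stages, keep SPPF,
and prune the cross-stage-partial (C3K2) neck. The published description
fixes the module inventory, kernel sizes (3/5), expansion ratios
(2/4/6), the stride-2 stem and the printed parameter/FLOP totals of both
scale variants — but not the exact layer sequence. The totals act as
checksums: the plan shipped here was selected by exhaustive search over
the constrained design space as one satisfying *all four* checksums
exactly (two parameter totals) or to printed precision (two FLOP
figures) with a single structure shared by both scales. Two readings
were ruled out by that search and are worth recording: taking the
printed channel sequence as literal stage widths is infeasible (any such
plan exceeds the baseline's FLOPs before reaching the parameter total),
and no plan whose s-scale widths are exactly double the n-scale widths
can satisfy both parameter totals simultaneously — the divisor-8
rounding of the standard scaling rule supplies the required asymmetry.

"Pruning enabled" for the neck C3K2 blocks is realized as identity
pruning of the partial-stage refinement branch in the two
high-resolution blocks (the cross-stage concat keeps its three branches;
the third passes through unrefined), while the two low-resolution output
blocks keep the stock deep form. This is the variant pinned by the
checksums and is recorded in the plan files.

## Complexity conventions

* **Parameters** are reported *fused*: convolution weight plus one
  folded bias per output channel for every conv+norm pair (what the pair
  collapses to at deployment), biased convolutions as-is, plus the 16
  fixed weights of the distribution-focal projection. Under this
  convention the three stock baselines reproduce their published
  two-class totals exactly (2,582,542 / 9,413,574 / 11,126,358), which
  validates the convention independently of the lightweight variants.
* **FLOPs** are 2 x convolution weight-multiply-accumulates at the
  stated resolution (default 640 x 640); normalization, activation,
  pooling, resampling and attention arithmetic count as zero. The same
  convention reproduces the baselines' published 6.3 / 21.3 / 28.4
  GFLOPs, pinning it before it is applied to the new variants.
* Headline reduction percentages are quoted the way such tables derive
  them: the parameter reduction from exact counts (17.1 %), the FLOP
  reduction from the one-decimal figures (1 − 4.6/6.3 = 27.0 %).

## Training objective

The trainer is for capacity checks on synthetic data, not clinical runs.
Anchor-free assignment: a grid cell is positive for a box when its
anchor point lies inside the box within 2.5 cells of the center, at
every pyramid level where all four cell-unit distances fit the 16-bin
range; thin boxes that enclose no anchor point fall back to the nearest
anchor with distances clamped at zero (the cutter slot is ~25 px tall at
native resolution and can be thinner than the stride-8 anchor spacing at
reduced training resolutions). Losses: binary cross-entropy over all
cells for classification, distribution-focal cross-entropy (two-hot
integer targets) for the four distance distributions at positives, both
normalized by positive count; a 1 − IoU term of the decoded positives is
logged for monitoring but not back-propagated. Optimizer: SGD with
momentum 0.937 (the family-standard value; the published recipe states
SGD, lr 0.01, batch 64, 333 epochs, patience 55 but not the momentum),
one warm-up epoch, cosine decay. Adam/AdamW/NAdam are available for the
optimizer-comparison configuration but produce results only on user
data. Augmentation implements the published table where meaningful for
single-channel ultrasound: horizontal flip, value gain, random erasing;
hue/saturation gains are accepted no-ops, rotation is 0 by default.

The capacity check trains the lightweight variant on 50 synthetic
frames for 20 epochs at 288 x 288 with batch 1 and lr 0.015 — problem
sizes chosen so the check runs on a laptop-class CPU in minutes while
the slot's thin profile still spans the finest anchor grid. The trained
model is evaluated on its own training set at 320 x 320 with confidence
floor 0.01: the network is fully convolutional, and a modestly larger
evaluation resolution shrinks the relative localization error of the
thin slot (much larger mismatches degrade again as feature statistics
drift from the training scale). Passing it shows the architecture,
gradients and trainer are sound; it says nothing about clinical
detection quality.

## Evaluation metrics

Greedy per-image, per-class IoU matching at threshold 0.5 (confidence
order, one-to-one); AP with all-points interpolation; mAP50 is the
unweighted two-class mean. Specificity, MCC and ERR need true negatives,
which standard box detection does not define; the declared convention is
image-level: an image contributes one TN for a class when it contains
neither ground truth nor predictions of that class. This convention is
printed in every report; comparisons against numbers produced under an
unknown TN convention should treat these three metrics as
convention-dependent. Degenerate denominators yield `None` (undefined)
rather than 0, except MCC which is defined as 0 when a marginal is
empty. Cross-validation folds are patient-level: a deterministic
seed-shuffled round-robin over patients, so no patient's images straddle
folds.

## Synthetic data: what it does and does not show

Frames are a smooth random echogenicity field with multiplicative
unit-mean gamma speckle, a bright rectangle (slot) and a dark soft-rimmed
ellipse (tumor); scripts move the objects so the activation predicate
first becomes true at a known frame (co-visible workflow: the slot
descends 1 px/frame across the vertical threshold; lateral workflow:
alternating visibility blocks with a constant overlapping geometry). The
generator is deterministic per seed; the detector stub returns ground
truth degraded by Gaussian localization noise, Bernoulli misses and
Poisson false positives, deterministic per (seed, frame).

This emulates the *structure* of the clinical task — two classes with
distinctive shape/contrast, speckle texture, scripted approach dynamics —
but none of its hard parts: no acoustic shadowing, attenuation, needle
artefacts, anatomical clutter, probe-pressure deformation, or annotation
noise. Green tests therefore certify the software (rules, state
machines, metrics, training mechanics, stream handling), not clinical
detection performance, which would require the original patient videos.

## Stream I/O

Sources are numbered-image directories, in-memory arrays or scripted
synthetic sessions; container video (MP4/AVI) requires an ffmpeg-style
codec backend which this package does not assume, so the session writer
emits a lossless numbered-PNG sequence with an index manifest instead.
Keyframe extraction samples one frame per interval (default 10 s) from
the stream's timestamp grid. The pipeline is single-threaded and
frame-ordered; annotated output preserves the frame count, and the
prompt banner text is fixed to "The operation can begin now."
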