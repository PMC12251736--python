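# Methods

`leafdet` is a self-contained study of a single-stage leaf-disease
detector family: a YOLOv8n-topology baseline and an improved variant
("YOLO-SSM") that replaces selected backbone downsampling convolutions
with a space-to-depth block (SSPDConv), the SPPF pyramid with a dilated
cross-stage pyramid (ESPPFCSPC), and the CIoU box-regression loss with
MPDIoU.  This note documents the models, the numerical choices, and what
the synthetic experiments do and do not demonstrate.

## Numerical backend

All network computation runs on a small reverse-mode autodiff engine
written on numpy (`leafdet.nn`): convolution is an im2col view plus one
BLAS `tensordot`, max-pooling stores argmax indices for its backward
scatter, and BatchNorm is composed from differentiable primitives.
Everything is float32.  Gradient correctness is verified against central
differences (per-element for cheap ops, directional for convolutions,
where float32 round-off would otherwise dominate a per-element probe).

## Box-regression losses

Boxes are corner-form `(x1, y1, x2, y2)`.  For a prediction `A` and
ground truth `B`:

* IoU = I/u with the intersection clamped to zero unless the candidate
  rectangle has positive extent on both axes;
* CIoU loss = `1 − IoU + ρ²/c² + αv`, where ρ² is the squared center
  distance, c² the squared diagonal of the smallest enclosing box,
  `v = (4/π²)(arctan(w_gt/h_gt) − arctan(w/h))²` and `α = v/(1−IoU+v)`;
* MPDIoU = `IoU − d₁²/(h²+w²) − d₂²/(h²+w²)` with d₁², d₂² the squared
  distances between the two top-left and the two bottom-right corners and
  (w, h) the image (network input) dimensions; the loss is `1 − MPDIoU`.

Numerical guards: `α`'s denominator and `c²` carry an epsilon of 1e-7
(identical boxes would otherwise form 0/0); aspect ratios are evaluated as
`arctan2(w, h)`, so degenerate zero-height boxes hit the π/2 limit instead
of overflowing.  Degenerate zero-area pairs yield IoU 0 in the batched
path (an exception would abort a training step); the scalar API can be
made strict.  MPDIoU normalizes by the size of the frame the boxes are
expressed in — during training that is the network input (square), a
documented choice since normalization by the original photograph's size is
equally defensible.

Bounds: for boxes inside the image each corner distance satisfies
`d² ≤ h²+w²`, so MPDIoU ∈ [−2, 1], loss ∈ [0, 3], and MPDIoU ≤ IoU with
equality iff both corner pairs coincide.  These are asserted as property
tests over >10⁴ random pairs, and the scalar implementation is checked
against a pixel-counting rasterization oracle on integer boxes.

## Network blocks

**SPD (space-to-depth)** moves 2×2 spatial blocks into channels:
`(S, S, C) → (S/2, S/2, 4C)`, lossless by construction, with sub-map
order fixed at (0,0), (1,0), (0,1), (1,1) over (row, col) offsets.  Any
fixed order is equivalent at initialization because the following 1×1
convolution is permutation-equivariant; the order is pinned for
reproducibility and the inverse is shipped and tested.

**SimAM** assigns each neuron a closed-form attention weight with zero
learnable parameters.  With per-sample, per-channel mean μ and biased
variance σ², a neuron t has energy `e = 4(σ²+λ)/((t−μ)² + 2σ² + 2λ)` and
is rescaled by `sigmoid(1/e)`.  λ = 1e-4 (the value used by the
originating attention work; this detector family does not pin it) guards
zero-variance channels, for which the weight degenerates to the uniform
`sigmoid(0.5) ≈ 0.6225`.  Weights increase monotonically with `(t−μ)²`.

**SSPDConv** = SPD → k×k convolution (4C₁ → C₂, stride 1, with BN+SiLU)
→ SimAM; a drop-in replacement for a stride-2 convolution.  The pointwise
k=1 form follows the block's textual description; k=3 is exposed because
the published parameter budget of the full model is only reachable with
the heavier form (see "Calibration").

**ESPPFCSPC** wraps the SPPF max-pool pyramid in a cross-stage-partial
structure.  Main branch: 1×1 → dilated 3×3 → 1×1, three serial max-pools
(k=5, stride 1, same padding — serial pools have receptive fields 5/9/13,
verified against parallel pools), concatenation, 1×1 fuse, dilated 3×3.
Shortcut branch: one 1×1.  Outputs concatenate and fuse to the requested
width.  The exact internal wiring of the published block is not
recoverable from its description; this topology is the standard SPPFCSPC
arrangement, with dilation 2 applied to the two 3×3 convolutions (a
dilated 1×1 would be a no-op, so "replace 1×1 with dilated convolution"
is read as upgrading the 3×3 stages).  `dilation_rate=1` recovers plain
SPPFCSPC at identical parameter count.

## Detector assembly and statistics

The baseline is the YOLOv8n topology (stem + four downsampling stages
with C2f blocks, SPPF, FPN/PAN neck, decoupled anchor-free head with
distribution-focal box regression, reg_max 16).  Its trainable-parameter
count at 80 classes matches the public reference implementation exactly
once the 16 frozen DFL projection weights are excluded (DFL is a fixed
softmax expectation here, not a module).  Statistics convention: params =
exact trainable total; GFLOPs = 2 × multiply-accumulates of convolution
layers, measured by tracing a real forward pass — identical across
models, so differences are convention-free.

**Calibration of the variant preset.**  The published ablation pins only
three architecture-level facts: 3.0 M baseline parameters, 4.0 M variant
parameters, and a +1.1 GFLOPs forward-cost increase at 640×640.  The
block placement is not printed.  Since a k=3 SSPDConv at any backbone
stage adds a fixed 0.708 GFLOPs (0.265 at the stem), while the pyramid
stage at 20×20 ties parameters to FLOPs at 1 : 8·10⁻⁷ (GF per weight),
the budget has essentially one solution: SSPDConv (k=3) at the stem and
the deepest downsample (128→256), plus ESPPFCSPC with hidden width 96.
That preset gives 4.046 M parameters and +1.09 GFLOPs and is shipped as
`YOLO_SSM`.  Placement, kernel and hidden width remain configuration.

## Training loss and toy schedule

Assignment is a deliberately plain center-prior + top-k scheme: candidate
anchors are those whose centers fall inside a ground-truth box; the top-10
by decoded-box IoU are taken, conflicts resolve to the higher IoU, and a
box smaller than one grid cell falls back to the nearest stride-8 anchor.
The composite loss is `7.5·box + 0.5·cls + 1.5·dfl` (YOLOv8 convention,
configurable): box is the mean MPDIoU (or CIoU) loss over assigned pairs,
delegating to the same formulas as the scalar API; cls is BCE over all
anchors with hard positive targets; dfl is the usual two-bin soft
cross-entropy on stride-normalized distances.  Class logits start at the
rare-positive prior (bias log(0.01/0.99)).

The toy preset scales the study to one CPU: width multiple 0.25, 160 px
inputs, 300 synthetic scenes, batch 16, SGD with momentum 0.937 and
weight decay 5e-4 (the reference field configuration), initial learning
rate 1e-2 with two warmup epochs and linear decay to 10%, 16 epochs.
On the "easy" synthetic condition this halves the smoothed loss within a
few epochs and reaches validation mAP@0.5 near 100% by the end of the
schedule; the shipped acceptance threshold (≥30%) is deliberately a loose
lower bound on a stochastic quantity.

## Background-complexity screening

Metrics over a 4×4×4-bin quantized RGB cube: histogram entropy (bits),
dominant-bin proportion, and Canny edge density (Gaussian σ=1; hysteresis
100/200 quoted in the OpenCV convention of unnormalized Sobel responses
on 8-bit images, i.e. 100/(255·4) and 200/(255·4) on skimage's normalized
gradient scale).  Decision rule: *simple* if dominant-color proportion
> 60% **or** edge proportion < 1.5%, else *complex* — the two published
conditions are each stated as sufficient for "simple", hence OR; entropy
is reported but not thresholded, since no cut-off is published for it.
Binning and the edge operator are documented choices; neither is printed
in the source description.

## Synthetic scenes

The generator produces stylized scenes — textured elliptical leaves with
venation, class-distinct lesion blobs (brown/grey/rust families with
darker rims; ragged outlines for odd classes), smooth near-uniform
backdrops for "simple" scenes and layered multi-color clutter for
"complex" ones.  Occlusion places leaves around an anchor at a distance
scaled by the requested overlap and resolves visibility in painter's
order, so occluded lesion pixels genuinely disappear (an annotation is
dropped when fewer than 4 pixels remain visible).  Illumination is a
multiplicative ramp along x with random sign.  Annotations are exact
bounding boxes of the visible lesion mask.  Challenge presets: occlusion
(target overlap 0.5), lowlight (ramp 0.7 plus post-hoc brightness 0.5–0.9
/ contrast 0.6–1.1 perturbation), small-lesion (area fractions 0.1–0.5%
of the image).  Datasets are written in YOLO layout with a 7:2:1 split
(val/test round to nearest, train takes the remainder).

Augmentations (rotation ±15°, translation ≤10%, mirror, sharpness,
Gaussian noise, ≤3 cutout patches of ≤10% area, HSV jitter ≤0.2) follow
the published operation list; the magnitudes are this package's defaults
since none are printed.  Geometric ops transform boxes with the pixels
(rotation keeps the axis-aligned bbox of rotated corners, which can only
grow); photometric ops and cutout leave labels untouched; a box pushed
out of frame is dropped with a logged count, never silently.

What passing these tests shows — and does not.  The generator reproduces
the *statistical* structure of the detection problem (scale range,
occlusion, illumination, background clutter, class balance), so green
tests demonstrate that the blocks, losses, training loop and metrics are
implemented correctly and can solve a detection task end-to-end.  They
say nothing about accuracy on real tea-leaf photographs: lesion
appearance here is far more separable than real disease, and no claim is
made that toy mAP transfers.

## Evaluation

Matching is the standard confidence-ranked greedy protocol (same class,
IoU ≥ 0.5, each ground truth used once).  AP is all-point
precision-envelope integration (checked against a brute-force rank-by-rank
oracle); mAP averages over classes present in the ground truth, and the
degenerate no-GT/no-prediction case is vacuously 100%.  Headline P/R are
reported both at the max-F1 confidence and over all predictions.  The
confusion matrix (class-agnostic IoU matching at a fixed confidence,
default 0.25) carries a background row/column.

Error decomposition (foreground threshold t_f = 0.5, background
threshold t_b = 0.1) buckets every false positive exactly once, in
priority order: duplicate (best same-class IoU ≥ t_f, ground truth
already claimed), classification (IoU ≥ t_f, wrong class), localization
(same class, t_b ≤ IoU < t_f), background (all the rest, including the
rare wrong-class medium-IoU case, folded in to keep
`EFP = Ecls + Eloc + Ebkg + Edup` exact).  `Emiss` counts ground truths
no prediction covered above t_b; `EFN` all unmatched ground truths.
Counts, per-prediction/per-GT rates, and a ΔmAP-style estimate (mAP
change when the offending predictions are removed) are all reported; the
estimate is labeled as such and is not the exact oracle of the published
error-analysis toolkit.

## Known limitations

* The variant's real-data accuracy claims are not reproduced — they
  require the original photographs and GPU-scale training.  Only the
  architecture statistics and behavioral contracts are.
* The assigner is a simplification of task-aligned assignment; it is
  adequate for the toy regime but not tuned for crowded scenes.
* The engine is CPU/float32 only; no mixed precision, no export formats.
* Exact internal wiring of the published pyramid block and the exact
  placement of the space-to-depth blocks are reconstructions constrained
  by the published parameter/FLOP budget, documented above, not asserted
  as the original authors' code.
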