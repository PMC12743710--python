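# Methods

## Pipeline model

`cxrseg` treats prompt-guided lung-field segmentation as a fixed chain of
stages: preprocess → build prompt → detect (raw or binarized pathway) →
refine boxes → segment → select candidate → evaluate. Detection and
segmentation are *contracts* (`Detector.detect_raw`,
`Segmenter.segment_raw`), not concrete models: any backend producing
scored, phrase-labeled boxes or scored candidate masks can fill the slot.
Two backends ship with the package — deterministic oracles driven by
phantom ground truth (used for all testing and calibration of the
surrounding machinery) and optional adapters for pre-trained grounded
detection / promptable segmentation models, loaded lazily so the core
package has no deep-learning dependencies.

## Synthetic phantoms

A phantom is two rotated ellipses of low intensity (default 60) on a
brighter background (default 180) with optional additive Gaussian noise,
clipped to [0, 255]. The geometry emulates what the pipeline actually
consumes from a frontal radiograph: two compact radiolucent regions of
unequal size and position (the left lung field is drawn ~15 % smaller,
standing in for the cardiac silhouette's encroachment). Layout follows
radiographic convention — the patient's right lung on the image's left.

The phantoms are deliberately *not* anatomically textured: no ribs,
mediastinum, tubes, or pathology. Every bespoke stage downstream consumes
boxes, masks and scalar scores, none of which depend on texture, and flat
interiors keep the ground truth and the oracle backends exact. Passing
tests therefore demonstrate the correctness of the pipeline machinery —
thresholding, box bookkeeping, search, metrics, calibration — not the
detection performance of any real model on real radiographs.

Ellipse rasterization uses the boundary-inclusive test
`(u/a)² + (v/b)² ≤ 1` in the rotated frame, implemented vectorized and
verified in tests against a per-pixel loop. Masks must be disjoint
(overlapping lobes are rejected) and ellipses must lie fully inside the
image. Noise is drawn from a generator seeded by the spec, so identical
specs give bit-identical phantoms.

### Oracle backends

*Detector*: parses side ("left"/"right") and anatomy ("lung"/"lobe")
tokens out of the prompt after stripping punctuation; a sided prompt
returns the named lobe's tight box, a side-less anatomical prompt returns
both lobes (matching the multi-detection behaviour grounded detectors
exhibit), anything else returns nothing. A jitter parameter displaces the
box by seeded integer offsets up to ±j per axis, with confidence
`exp(−‖offset‖ / scale)` (scale default 10 px) — zero jitter gives the
exact box at confidence 1. The paper-scale analogue of a confidence model
does not exist for synthetic data, so an exponential decay in
displacement was chosen as the simplest monotone model.

*Segmenter*: inside the (clipped) box, pixels below a box-local Otsu
threshold are foreground; the quality score is the captured fraction of
the dark connected components the box touches (components measured over
the whole image at the same threshold). The score is 1 exactly when every
touched component lies inside the box, so on a one-lobe box the score as
a function of box translation is unimodal with its maximum at
lobe-containing boxes — giving the refinement stage a landscape whose
global optimum is known. An `erosion` option degrades the output mask,
providing a controlled "worse backend" for comparison experiments.

## Preprocessing

Grayscale conversion uses Rec.601 luma weights. Resizing returns the
(sy, sx) scale factors so boxes map between spaces exactly; downscaling
defaults to local-mean (area) averaging, with nearest/linear options.
Binarization follows `B = 1 iff I ≥ T`; in Otsu mode `T` maximizes the
between-class variance `w₀w₁(μ₀−μ₁)²` over integer thresholds with
smallest-`T` tie break, computed from cumulative histograms and verified
in tests against both an exhaustive-search oracle and scikit-image
(which uses a strict `>` convention, so agreement is asserted at the mask
level). The canonical binary representation is boolean; the value 196
appears only when a mask is rendered back to a grayscale image for the
binary detection pathway — separating the math from the display encoding.
A constant image has no Otsu threshold and falls back to the fixed value
(127) with a warning. Boxes use 0-based, half-open
`[x_min, x_max) × [y_min, y_max)` coordinates; box mapping floors minima
and ceils maxima so coverage never shrinks.

Two resolutions of the pathway question are supported: segment on the
resized working image, or map boxes back and segment at original
resolution. The default is the latter (detection at working resolution,
segmentation at native resolution), since overlays and ground truth live
in native space. In the binary pathway with oracle backends the rendering
stays at native resolution, because oracle boxes are defined in
ground-truth space.

## Prompts

Word-level prompts are built in two styles: `plain` joins terms with
". ", `dot_separated` emits every whitespace token followed by " . "
(`"right . lung ."`). For multi-term dot-separated prompts the token
lists are flattened with a single trailing dot — the simplest convention
whose output parses back to the original token sequence by splitting on
" . ". Case transformation is applied last. Sentence-level prompts pass
through verbatim and carry a flag so reports can separate them.

## Box refinement

Greedy local search. The neighborhood is the cross product of per-axis
offsets {0, ±2, ±5, ±10} (defaults) and scale factors {1.0}; each sweep
evaluates the objective at every neighbor (clipped to image bounds,
duplicates skipped), adopts the argmax, and stops when the best
improvement is below `min_improvement` (1e-6) or after `max_iterations`
(10). Ties break toward the identity move, then smaller offset magnitude,
then x-axis moves before y — a total order that makes runs reproducible
and guarantees termination. Because the identity move is always
evaluated, the adopted objective sequence is non-decreasing and the final
box is never worse than the initial one; both properties are asserted on
every trace in the test suite.

The objective defaults to the segmenter's best candidate score; a
detector-confidence objective (for detectors exposing `box_confidence`)
and a BPIoU-against-reference objective are also implemented. All four
schedule ingredients (offsets, scales, stop rule, objective) are
config-exposed.

Known limitation: with the default coarse offsets, a residual
displacement of odd parity (e.g. 1 px) can be a greedy fixed point even
though finer boxes exist — no single move of ±2/±5/±10 improves on it.
Exhaustive-search agreement is therefore measured with a schedule that
includes unit offsets ({0, ±1, ±2, ±5, ±10}), under which greedy search
on a unimodal landscape reaches the lattice optimum; the coarse default
trades that last pixel for a ~3× smaller neighborhood.

## Metrics

IoU and BPIoU are set ratios on boolean masks; BPIoU binarizes a soft
prediction at a threshold (default 0.5, never stated more precisely by
users of this metric; config-exposed) before taking the IoU, and reduces
exactly to IoU for boolean predictions. Dice loss uses the squared-sum
soft form, which on booleans collapses to the classical count form
(`v² = v`); both identities are asserted on random masks, along with
`Dice = 2·IoU/(1+IoU)`. Conventions for degenerate input: two empty masks
agree perfectly (IoU 1, Dice loss 0 with warning), chosen so that perfect
agreement never scores worse than disagreement.

The stability score segments `n` perturbed versions of a prompt
(default: box translation jitter; alternatively image noise) and reports
the mean pairwise IoU of the selected masks. Box jitter is the default
because the prompt, not the image, is the pipeline's control variable;
the image-noise mode mirrors the perturbed-input formulation used
elsewhere.

## Calibration

Scores are min-max scaled to [0, 1] (identity scaling available for
scores already on that range; constant scores are degenerate and map to
1.0 with a warning). Success is `IoU ≥ cutoff` (default 0.5) — a
reproducible operationalization of a qualitative "good segmentation"
judgment. Binning uses 10 equal-width bins on [0, 1], right-closed at the
top so probability 1.0 lands in the last bin; empty bins keep count 0
with NaN means. A perfect predictor reproduces the diagonal exactly, and
Bernoulli-sampled outcomes stay within binomial sampling error of it —
both asserted in tests.

## Pipeline and determinism

Per-image seeds derive from the run seed and the image id (CRC32,
reduced below 2³¹), so batches are order-independent and two runs with
the same seed produce byte-identical CSVs. Batch failure policy is
skip-and-record: one bad image does not abort a batch, only a fully
failed batch raises. Artifacts follow the scheme
`<image_id>__<prompt_slug>__<backend>__<pathway>.<ext>` and are listed in
a YAML manifest with the seed, pathway and histogram bin edges (fixed 20
bins on [0, 1]).

## Problem sizes

Tests and the reproduction script run on phantoms of 64–128 px (96 px for
batch runs), 100 refinement runs for the monotonicity check, 20 phantoms
with a ±10 px exhaustive translation sweep for the optimality check, 200
random mask pairs for metric agreement, 50 images for Otsu agreement, and
10 000 Bernoulli draws for calibration — sizes at which the independent
oracles (per-pixel loops, exhaustive sweeps) are themselves exact and
fast, while every code path of the full-scale pipeline is exercised.

## Limitations

- Phantom results validate the pipeline machinery, not real-model
  performance on radiographs; the oracle confidence model is synthetic.
- The refinement neighborhood is a fixed schedule, not a learned or
  adaptive policy; see the parity note above.
- No histogram equalization or denoising is applied in preprocessing.
- Calibration is diagnostic only; no recalibration (Platt/isotonic) is
  performed.
- Hausdorff-type boundary metrics are not implemented.
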