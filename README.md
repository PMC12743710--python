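# cxrseg

Text-prompt-guided lung-field segmentation for chest radiographs.

Segmenting the lung fields on a frontal chest X-ray normally requires
models trained on large annotated datasets. An alternative is to chain two
zero-shot components: a text-grounded object detector that turns an
anatomical prompt such as `"right lung"` into a bounding box, and a
box-promptable segmenter that turns that box into a pixel mask. `cxrseg`
implements the full pipeline around those two components — the parts that
make the chain usable and measurable — for researchers evaluating
prompt-based segmentation on radiographs:

- **preprocessing** — grayscale conversion, resizing with exact coordinate
  bookkeeping, and binarization `B(x,y) = 1 if I(x,y) ≥ T` with `T` fixed
  (127) or chosen by Otsu's between-class-variance criterion; a rendered
  binary image (foreground 196) feeds the binary detection pathway;
- **prompt construction** — word-level prompt styles (`"right lung"`,
  `"right . lung ."`), case variants, sentence-level pass-through;
- **detection and segmentation contracts** — scored, phrase-labeled boxes
  filtered at a confidence threshold (default 0.25); multi-candidate masks
  with explicit selection policies. Real Grounding DINO / SAM checkpoints
  plug in behind these contracts as optional adapters;
- **iterative bounding-box refinement** — greedy hill climbing over a
  translation (and optional scaling) neighborhood, maximizing a
  segmentation-quality objective; the objective trace is provably
  non-decreasing and the final box is never worse than the initial one;
- **metrics** — IoU, BPIoU (IoU after binarizing the predicted mask),
  soft Dice loss `1 − 2Σ(g·p)/(Σg² + Σp²)`, and a stability score (mean
  pairwise IoU of masks under perturbed prompts);
- **calibration** — quality scores scaled to probabilities, binary
  success labels from an IoU cutoff, and reliability tables/diagrams;
- **synthetic chest phantoms** — two elliptical radiolucent lung fields on
  a noisy brighter background, with exact per-lobe ground-truth masks, and
  deterministic *oracle* detector/segmenter backends built on that ground
  truth. Every stage is testable end to end without any model weights.

## Worked example

Detect, refine and segment one lung field on a noisy synthetic phantom
with a deliberately displaced initial detection (jitter 12 px):

```python
from cxrseg import (PhantomSpec, generate_phantom, OracleDetector, OracleSegmenter,
                    detect, refine_box, segment, select_candidate, iou, dice_loss,
                    stability_score, DetectorConfig)

spec = PhantomSpec.default(224, 224, noise_sd=5.0, seed=42)
image, gt = generate_phantom(spec)

detector = OracleDetector(gt, jitter=12, seed=42)
segmenter = OracleSegmenter()

boxes = detect(detector, image, "right lung", DetectorConfig(box_threshold=0.0))
trace = refine_box(image, boxes[0], segmenter)
mask = select_candidate(segment(segmenter, image, trace.final_box))
```

This prints (formatting as in the example script):

```
detected 1 box(es); confidence 0.387
refinement: objective 0.927 -> 0.997 in 3 sweeps (converged=True)
IoU vs ground truth:  0.9971
Dice loss:            0.0015
stability score:      0.9820
```

The displaced box captures only 92.7 % of the lung field; three greedy
sweeps recover 99.7 % of it, and the selected mask overlaps the true lobe
at IoU 0.997. The stability score of 0.982 says the segmentation barely
changes when the box prompt is jittered by ±4 px.

The same flow is available from the shell:

```bash
cxrseg generate data/ --n 4 --noise-sd 5
cxrseg run out/ --images data/ --detector-jitter 8 --seed 1
cxrseg calibrate out/metrics.csv --out-prefix out/calibration
```

`run` writes per-image masks, box JSON, refinement traces (JSON lines),
a metrics CSV (IoU/BPIoU/Dice loss/stability per prompt and box), summary
statistics, fixed-edge score histograms, and a manifest that makes the run
exactly reproducible from its seed.

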