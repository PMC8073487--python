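# viadyn

Automatic cervical precancer detection from the **dynamics** of
acetowhitening in videos taken during visual inspection with acetic acid
(VIA).

VIA is the front-line cervical screening test in low-resource settings:
3–5% acetic acid is applied to the cervix and precancerous tissue
(CIN2+) turns transiently white. The diagnostic signal is *temporal* —
neoplastic epithelium whitens quickly and then fades, while benign
tissue stays nearly constant — but human readings of this effect are
subjective and unreliable. `viadyn` implements a pixel-wise classifier
of that temporal signature for 2-minute, 1 fps smartphone recordings,
intended for researchers reproducing or extending dynamic-VIA
classification.

## The method

For a stabilized recording of `T = 120` frames at `150 × 150` px:

1. **Stabilization** — every frame is registered to the last frame
   (where lesion annotations are drawn) by point-feature matching
   (Harris corners + BRIEF descriptors) and RANSAC fitting of a
   similarity transform.
2. **Projection** — channels are scaled to `[-0.5, 0.5]` and each RGB
   pixel is projected onto the mean whitening principal axis
   `d = [0.3609, 0.5941, 0.7074]` (unit-normalized), giving one scalar
   intensity per pixel per frame.
3. **Curve features** — the first 10 frames are discarded and each
   pixel's 110-point curve is downsampled to **11 time points** with a
   natural cubic spline. Pixels whose projected maximum exceeds 0.25 are
   flagged as specular reflections.
4. **Classification** — an `11 → 15 → 1` neural network (logistic
   activations, binary cross-entropy) maps each curve to a CIN2+
   probability. Training pixels come from eroded (positive) and
   dilated-and-centrally-masked (negative) annotation masks; positives
   are augmented by curve scaling in `[0.9, 1.15]` to exact class
   balance. Evaluation is leave-one-out cross-validation at the
   *patient* level.
5. **Postprocessing** — reflections are neutralized to probability 0.5,
   the map is multiplied by a radial distance map (1 at the center, 0.5
   at the farthest point), regions are grown from up to 5 seeds under a
   dual predicate (|seed − neighbor| < 0.27 and neighbor > 0.50), closed
   with a 7 × 7 kernel, and the recording is called **positive** iff any
   region reaches 450 px.

Because no public recordings of this kind exist, the package ships a
first-class phantom generator (`viadyn.synthetic`) that renders cervix
videos with known lesion masks, whitening kinetics, specular highlights,
camera jitter, and sensor noise, so the full pipeline is testable
end to end.

## Worked example

```python
from viadyn import PipelineConfig
from viadyn.pipeline import run_phantom_benchmark

patients, result = run_phantom_benchmark(n_positive=4, n_negative=4,
                                         rng_seed=42)
print("sensitivity:", result.sensitivity)
print("specificity:", result.specificity)
for pid, iou in result.lesion_ious.items():
    print(pid, "lesion IoU vs truth:", round(iou, 3))
```

prints

```
sensitivity: 1.0
specificity: 1.0
P000 lesion IoU vs truth: 0.998
P001 lesion IoU vs truth: 0.991
P002 lesion IoU vs truth: 0.999
P003 lesion IoU vs truth: 0.997
```

i.e. on an 8-phantom cohort every patient is diagnosed correctly under
patient-level LOO-CV, and the segmented lesions overlap the ground-truth
masks almost perfectly (IoU is intersection over union of the predicted
and true lesion masks).

The same flow works on real data through the CLI:

```sh
viadyn simulate --out cohort/ --seed 1 --n-positive 4 --n-negative 4
viadyn loocv --manifest cohort/manifest.json --seed 1 --out report.json
viadyn evaluate --predictions decisions.csv --out metrics.json
```

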