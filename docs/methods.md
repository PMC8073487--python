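# Methods

## Problem and model

Visual inspection with acetic acid (VIA) exploits a transient optical
effect: after 3–5% acetic acid is applied, CIN2+ epithelium whitens
within tens of seconds and then fades smoothly, while benign tissue
keeps a nearly constant appearance. `viadyn` treats each pixel of a
2-minute, 1 fps recording as an independent time series and classifies
its whitening curve. The spatial structure of disease enters only
afterwards, through postprocessing (a central-location prior and seeded
region growing with a minimum lesion size).

The per-pixel feature is an 11-point curve obtained by: scaling 8-bit
channels to [-0.5, 0.5]; projecting RGB onto the whitening principal
axis; discarding the first 10 frames (most affected by speculum and
camera adjustment); and natural-cubic-spline downsampling of the
remaining 110 samples onto 11 equally spaced abscissae spanning both
endpoints. Keeping the final point matters: the residual whiteness at
~2 min is part of what distinguishes fading neoplastic whitening from
constant benign brightness.

The classifier is deliberately minimal — one hidden layer of 15
logistic units and a logistic output trained with binary cross-entropy —
because each input is an 11-vector and the training set per fold is a
few thousand curves. Model capacity is not the bottleneck; label
quality and motion are.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| working resolution | 150 × 150 | px | square crop, bilinear resize |
| frame rate / length | 1 fps / 120 frames | | nearest-timestamp resampling |
| principal axis | [0.3609, 0.5941, 0.7074] | scaled-RGB | renormalized to unit length (raw norm 0.9918) before use |
| discarded frames | first 10 | frames | |
| curve length | 11 | points | network input size |
| reflection threshold | 0.25 | projected scalar | strict `>` on the temporal maximum |
| augmentation range | [0.9, 1.15] | scale factor | one factor per synthesized curve |
| hidden nodes / layers | 15 / 1 | | |
| training epochs | 200 | | full-epoch adam; see "calibration" below |
| homogeneity threshold | 0.27 | probability | vs the originating seed |
| minimum probability | 0.50 | probability | strict `>` |
| seeds | 5 | | first random in top 0.5%, then highest-remaining |
| closing kernel | 7 × 7 | px | square; infinite-plane padding |
| size threshold | 450 | px | inclusive `>=` |
| central mask radius | 0.45 × size | px | negative sampling + prediction ROI |
| border margin | 5 | px | excluded from negative sampling |
| disk radius rule | 10% of equivalent diameter, clipped to [2, 12] | px | manual override honored |

## Design choices where the design was open

**Principal-axis handling.** The stored mean axis has norm 0.9918; it is
renormalized so the projection scale is well defined (< 1% change). Axis
sign is fixed to a positive component sum (the whitening direction).

**Spline boundary.** "Cubic spline interpolation" is implemented as the
natural spline (zero second derivative at the ends), the conventional
default, and is cross-checked in the tests against an independent
tridiagonal-solve implementation.

**Reflection threshold semantics.** The 0.25 threshold is applied to
the temporal maximum of the *projected scalar*, with strict inequality.
Applying it to raw channels instead would be a one-line config change.

**Region-growing anchor.** The homogeneity criterion compares each
candidate neighbor to the probability of the *originating seed* (a
`parent`-anchored variant is available via config). Subsequent seeds are
the highest-probability pixels not yet in any region; the first seed is
drawn uniformly from the top 0.5% of the map under the run seed. A seed
whose probability does not exceed the minimum-probability criterion
cannot start a region, and since every remaining candidate is lower
still, seeding stops there.

**Closing convention.** Closing (dilation then erosion, same 7 × 7
kernel) is computed as on the infinite plane — the grid is padded by the
kernel radius first — so closing is extensive (never removes a region
pixel) and regions touching the frame border are not clipped. Per-region
closing never overwrites a previously assigned label.

**Class balancing.** Negatives outnumber positives in the sampled
regions, so per fold the positive set is augmented by whole-curve
scaling up to the negative count, giving exact balance. (Had positives
outnumbered negatives, the positive set would be subsampled instead.)

**Training calibration.** Early stopping on a held-out accuracy plateau
is disabled by default: on well-separated pixel data the validation
*accuracy* saturates within ~15 epochs while the network's output
probabilities are still compressed toward 0.5, and downstream
postprocessing thresholds (minimum probability 0.5, homogeneity 0.27)
require calibrated, confident probabilities. Training the full 200
epochs costs well under a second per fold at these data sizes.

**Prediction ROI.** The network is evaluated only inside the central
disc also used for negative-pixel selection; outside pixels receive the
neutral probability 0.5, the same convention used for reflections and
for pixels that leave the field of view during stabilization. Neutral
pixels can never seed or join a region (0.5 × distance weight ≤ 0.5).
On real recordings the cervix fills the frame and the ROI is simply the
operator's crop; on phantoms it prevents the dark background — which no
training pixel ever represents — from producing undefined network
outputs.

## The phantom generator

`viadyn.synthetic` renders what the pipeline assumes about real data:

* an elliptical cervix disc (semi-axes 0.44/0.40 of the frame) with
  two-scale multiplicative texture (coarse mottling σ = 2 px plus fine
  speckle σ = 0.8 px, ±10% total) on a dark background;
* lesion pixels following a single-peak whitening pulse
  `w(t) = baseline + A·((t/t_peak)·e^(1−t/t_peak))^(t_peak/τ)` with
  amplitude `A = 0.16` (projected-scalar units), rise time
  `t_peak = 25 s`, decay constant `τ = 60 s`; benign pixels a slow
  sinusoidal drift of amplitude 0.02 around baseline 0.03. The pulse
  peaks exactly at `t_peak` and decays exponentially at rate 1/τ;
* whitening applied as an additive RGB shift along the principal axis,
  so the projection stage recovers the designed scalar curve by
  construction;
* static specular highlights: Gaussian-profile blobs clipped at channel
  saturation (4 per recording by default);
* global integer jitter per frame, drawn from N(0, 1.2 px) and recorded
  in the truth; the last frame's shift is forced to (0, 0) so truth
  masks, annotated in last-frame coordinates, coincide with the
  stabilization reference;
* i.i.d. Gaussian sensor noise (σ = 2.5 8-bit units) per pixel and
  channel.

All amplitudes were chosen once as plausible magnitudes for this
modality — the whitening pulse sits safely below the specular threshold
(maximum projected lesion value ≈ 0.20 vs 0.25) and the class contrast
(0.16) is an order of magnitude above the projected noise floor
(≈ 0.01 per frame). They are free parameters of the phantom, not
measured tissue constants.

What the phantom does **not** model: non-rigid tissue deformation,
mucus/blood artifacts, illumination drift, annotation subjectivity
(truth masks are exact), rotation/zoom of the camera, and benign
whitening mimics such as metaplasia. Passing the phantom benchmark
therefore demonstrates that the pipeline's machinery is correct and
leak-free — not that real-world accuracy would match it. Real VIA
curves are noisier and their class boundary far less crisp.

**Stabilization estimator.** Any standard corner detector satisfies the
module contract (translation recovery on known-shift phantoms); the
implementation uses Harris corners on a σ = 1 px smoothed grayscale with
an *absolute* response floor — a relative threshold would let saturated
specular highlights crowd out tissue corners — BRIEF descriptors with a
fixed sampling pattern, brute-force matching with cross-checking, a
median-displacement trim (3 px) encoding the small-wobble acquisition
prior, and an adaptive-termination RANSAC similarity fit. Keypoints are
integer-located, so single frames can be a few tenths of a pixel off.

## Problem sizes and numerical tolerances

The cross-validated phantom study uses 40 patients (20 positive / 20
negative) at the full working size of 150 × 150 × 120 — the same
resolution and length as real recordings, with cohort size chosen to
keep a complete run in single-digit minutes on one CPU. Each LOO fold
samples up to 150 positive and 150 negative pixels per patient and
augments positives to balance.

Numerical conventions: spline agreement with the independent oracle is
asserted at 1e-9; stabilization is asserted at 0.5 px median translation
error (keypoints are integer-located, so individual frames can be a few
tenths of a pixel off); metric arithmetic is exact rational arithmetic displayed at
two decimals; ties in seed selection resolve to the first pixel in
row-major order. Degenerate inputs degrade explicitly: featureless
frames fall back to identity transforms with a warning, empty masks
yield empty positive regions, all-low probability maps yield zero
regions and a negative call.

## Known limitations

* The stabilizer estimates a global similarity transform; rolling
  tissue deformation or parallax is not corrected.
* Reflection detection keys on the projected temporal maximum only;
  bright-but-unsaturated glints below 0.25 pass through (their
  probability is then whatever the network assigns).
* With fewer than ~4 patients per class, LOO folds can lack a class and
  the harness raises rather than silently training a one-class model.
* Curves are classified without baseline normalization; a recording
  with a global brightness offset shifts every curve equally, which the
  network must absorb from training diversity.
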