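# Methods

`cleftscore` scores the severity of cleft-lip facial anomalies by comparing
a photograph against a *normalized* version of the same face synthesized by
a generative model, and measuring how much energy the difference map holds
in the oral/nasal region. This note records the model, the numerical
choices, and what the synthetic test bed does and does not demonstrate.

## The appraisal model

Let `x_org` be a canonicalized face image and `G` a differentiable face
generator with intermediate latent space `W` and per-resolution noise maps
`n_i`. The pipeline has six stages.

**1. Canonicalization.** The face is detected, the canvas is adjusted to
roughly 60% face / 40% background (cropping margins, or padding with 8
mirrored replicates whose background is Gaussian-blurred), the image is
rotated so the eye centers are horizontal, isotropically rescaled so the
inter-eye distance is 100 px, and a 1024×1024 window is cropped around the
face anchor. These targets match the framing convention of the corpus the
production generator is trained on; the toy pipeline scales them to a 64-px
frame with 20-px eyes (same 100:1024 ratio). Eye centers are centroids of
each eye's six landmarks; interpolation is bilinear throughout; the crop
center sits 8% of the frame below the eye line (exposed as config — the
framing convention implies but does not pin this offset).

**2. Latent inversion.** Starting from the mean intermediate latent μ
(average of 10,000 mapped standard-normal draws; 2,000 at toy scale) and
freshly drawn noise maps, minimize

    L(w, n) = D_perc(x_org, G(w, n)) + α · R(n),        α = 1e5

by Adam steps on `w` and all noise maps (learning rate 0.05, linear ramp-up
over the first 5% of iterations, cosine ramp-down over the last 25% — the
standard projector recipe). `R` is the noise-randomness penalty: for every
noise map and every level of its 2×2-mean-pool pyramid down to 8×8, the
squared lag-1 autocorrelations (horizontal + vertical), each normalized by
`r²` for a level of side `r`, with clamped boundaries. It stops image
content from leaking into the noise maps. The production budget is 450
iterations; the toy budget is 120, with optional early stopping (off in
batch runs so every image gets an identical budget).

**3. Model adaptation.** The inverted latent and noise maps are frozen and
the *weights* of a copy `G'` are fine-tuned on

    L(W) = D_perc(x_org, G'(w)) + ‖x_org − G'(w)‖² / N_pix

for a short budget (50 iterations at production scale, 20 at toy scale).
The optimizer is plain gradient descent (lr 0.5 at toy scale). This is a
deliberate choice over Adam: GD steps are proportional to the gradient, so
the update concentrates in the few weights the one-face objective actually
pulls on, and images synthesized from unrelated latents move by well under
10% of the pixel range. Adam's sign-normalized steps move every weight at a
similar rate and measurably disturb the rest of the latent space. The
output of this stage, `x_norm = G'(w)`, is the normalized face. Stopping
early matters: the generator recovers smooth identity detail quickly but
needs many more iterations to rebuild a sharp localized defect, so the
defect is exactly what remains in `x_org − x_norm`. Running adaptation ~10×
longer visibly reconstructs the defect and collapses the severity signal
(this over-adaptation curve is asserted in the test suite).

**4. Color transform.** Both images are mapped RGB → YCbCr with the BT.601
affine transform (unit-range R'G'B' in, byte-scale Y'CbCr out, offsets
16/128/128). Cleft anomalies are structural, so they live in luma; lighting
and synthesis drift spread into chroma. Achromatic inputs give exactly
Cb = Cr = 128.

**5. Heatmap.** The default comparator is the pixel-wise squared error
(PSE): `D = Σ_channels (x_org − x_norm)²`, optionally preceded by one pass
of 3×3 morphological erosion (neighborhood minimum, per channel, in-bounds
neighborhoods at the borders) applied to *both images* to suppress speckle
from the synthesis. SSIM dissimilarity (1 − SSIM, 7-px uniform windows,
stabilizers c1=(0.01·L)², c2=(0.03·L)²) and a perceptual feature-difference
map are available as alternatives; the ablation grid enumerates all of
them. Heatmap arithmetic uses the byte-range convention; this scales the
absolute score but no ranking or correlation.

**6. Scoring.** With a landmark-derived region mask `M` (filled convex hull
of the nose + outer-mouth landmarks dilated by 4% of the frame side; or
the face outline minus dilated eye hulls), the severity score is

    S = −log( ‖M ⊙ D‖_F / N ),      N = #mask pixels.

Higher heatmap energy ⇒ lower S, aligning with the human 1 (least normal)
… 7 (most normal) scale; the log models the way human sensitivity to a
defect saturates as it grows. A masked-mean energy variant (`energy="mean"`)
is available, matching the prose description of the quotient rather than
the Frobenius form; the Frobenius form is the default. An identically zero
masked heatmap returns an infinite score flagged `perfectly_normal` rather
than raising. Machine–human agreement is evaluated as the Pearson
correlation between per-image scores and per-image mean ratings, keeping
images with at least 20 ratings.

## The perceptual backend

`D_perc` is LPIPS-shaped: features per layer are channel-unit-normalized at
each spatial position, weighted per channel, and squared differences are
averaged over positions and summed over layers. The default backend is a
fixed-seed two-stage random-convolution feature extractor (8 channels, 3×3
kernels, leaky-ReLU, 2× average pooling between stages). Random projections
preserve enough local structure to drive inversion at desk scale and need
no pretrained weights or network access. The identity-feature backend
(`PixelPerceptual`) reduces the same formula exactly to the mean squared
pixel difference and serves as an oracle in tests. Backends are pluggable;
a pretrained-feature implementation slots in behind the same interface.

## The toy generator

`ToyGenerator` is a constructed (not trained) convolutional synthesizer: a
16-dim latent is projected to an 8×8×16 feature map and refined through
conv blocks at resolutions 8/16/32/64, each adding one noise map through a
learned gain, with a sigmoid to-RGB head — a miniature of the production
generator's latent + per-resolution-noise interface (512-dim latent, 18
noise maps from 1024² down to 8²). Weights are fixed random draws from a
seed; inversion only needs a differentiable, expressive map, and the
smoothness of the stack is a feature: the toy generator approximates smooth
faces well but cannot cheaply represent a sharp localized defect, which is
the asymmetry the whole method rests on. Width 16 was chosen so inversion
tracks the fixture faces closely enough that the severity response is
clean; at width 8 the inversion residual floor drowned fine amplitude
differences. The generator and perceptual-backend construction seeds play
the role of fixed pretrained weights and are therefore decoupled from the
run seed, which drives only latent sampling, noise initialization, and
rater simulation.

All gradients flow through a small in-package reverse-mode autodiff tape
(`autodiff.py`) over numpy arrays, validated against central finite
differences to <1e-3 relative error (observed ~1e-9).

## Synthetic study material

`fixtures.py` generates everything the tests consume:

* **Faces** — smooth schematic faces (skin ellipse, eye blobs, nose ridge,
  mouth band, textured background) with all 68 landmarks placed
  analytically, parameterized in interocular units.
* **Defects** — `plant_anomaly` applies a compactly supported structural
  warp (tissue pulled away from the philtrum midline) plus a darkened
  midline notch, scaled by an amplitude in [0, 1]. Amplitude 0 is the
  identity and pixels outside the oral/nasal neighborhood are bit-identical.
* **Raters** — each simulated vote is `clip(round(7 − 6·g(a) + ε), 1, 7)`
  with `g(a) = a/(a+0.3)` (fast initial sensitivity, saturating — the shape
  human appraisal exhibits) and `ε ~ N(0, 0.5)`, 25 raters per image,
  matching the ~25 ratings per image of a realistic panel with a 20-rating
  inclusion floor.

What this test bed demonstrates: order preservation of the severity score
under graded structural defects, localization of the defect by the heatmap,
the inversion/adaptation division of labor, and machine–rater agreement
when severity is the dominant axis of variation. What it does not
demonstrate: identity invariance across diverse real faces (the toy
generator has no identity prior, so cross-identity baseline residuals are
larger than a pretrained face generator would leave — the agreement
experiment therefore grades severity within subject), robustness to pose,
lighting and occlusion, and any claim about real clinical imagery.

## Problem sizes and determinism

Toy-scale runs use 64-px frames, 120 inversion + 20 adaptation iterations,
and 2,000 mean-latent samples — sizes chosen so a severity batch of 10–30
images completes in a few minutes on one CPU while leaving comfortable
optimization margins. Every stochastic component takes an explicit seed and
is bit-reproducible; batch runs give every image an identical optimization
budget so scores are comparable within a batch.

## Known limitations

* The severity floor (inversion + adaptation residual) is nonzero and
  face-dependent; near amplitude zero the score measures this floor, not
  the defect.
* Strict rank preservation across a graded series is a property of the
  default seeds' optimization trajectories; single-seed normalization is
  inherently stochastic, and an occasional adjacent-pair inversion at other
  seeds is expected (the acceptance script reports the measured fraction).
* The eyes are masked out of the whole-face score region because generative
  reconstruction of eye reflections is unreliable — a limitation inherited
  from the underlying generator class.
* A pretrained StyleGAN2-class backend is an interface (`GeneratorSpec`),
  not a shipped implementation; all shipped results use the toy generator.
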