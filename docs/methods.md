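# Methods

## The model

The pipeline classifies histopathology image patches (benign vs malignant)
while keeping every decision inspectable:

1. **Frozen feature extraction.** Each patch is resized to 224×224 and mapped
   by a frozen, pretrained CNN (ResNet152's 2048-unit global-average-pool
   output in the reference configuration) to a feature vector *x* ∈ ℝ²⁰⁴⁸.
   The extractor is never trained here; the downstream contract is simply
   "feature table in". A deterministic hash-based stub extractor satisfies the
   same contract so that every path is testable without a deep-learning
   runtime (none is declared as a dependency; the real-backbone adapter is an
   extension point that requires torch/torchvision at construction).
2. **Trainable linear metric embedding.** A single bias-free linear map
   W : ℝ²⁰⁴⁸ → ℝ⁵¹² produces embeddings r = W x. W is the only trained
   component. Training minimizes the triplet margin loss
   `l(a,p,n) = max(0, d(r_a,r_p) − d(r_a,r_n) + m)` over triplets mined
   online within each mini-batch by the semi-hard rule
   `d(r_a,r_p) < d(r_a,r_n) < d(r_a,r_p) + m` — negatives already beyond the
   positive but still inside the margin. Consequences used as invariants:
   every mined triplet's loss lies strictly in (0, m), and the miner runs dry
   once all negatives clear the margin (a natural stopping signal).
3. **k-NN classification.** Test embeddings are labelled by majority vote of
   their k nearest training embeddings (k = 3 by default). The neighbours
   themselves are retained as the prediction's evidence.
4. **Patient-level evaluation.** PatientScore = N_rec / N_P (correct test
   images over that patient's test images); PLA is the unweighted mean of
   patient scores over patients. Image-level accuracy/precision/recall/F1/AUC
   are reported alongside, with **benign as the positive class** and AUC from
   the benign-neighbour fraction via the rank (Mann–Whitney, midrank-tie)
   statistic.

Train/test discipline is patient-disjoint throughout: the five folds are
independent, class-stratified 70/30 draws of *patients*, and `validate_fold`
rejects any split where a patient appears on both sides. Two regimes are
orchestrated: magnification-independent (MIB; one model over all images) and
magnification-specific (MSB; one model per magnification on scoped folds).
The ablation path removes W and runs k-NN on the raw 2048-dim features, with
per-magnification k = 3/7/5/9 for 40/100/200/400× in the MSB ablation.

## Parameters and defaults

| parameter | default | notes |
|---|---|---|
| embedding dim | 512 | < input dim; purely linear, no bias, no activation |
| distance d | euclidean | cosine also supported; recorded in run metadata |
| margin m | 0.2 | unitless in embedding-distance units; all tests set it explicitly |
| normalized embeddings | off | L2 normalization available; scale-invariant metrics skip init calibration |
| epochs / batch | 20 / 32 | per-epoch uniform shuffling, fixed seed |
| optimizer | Adam, lr 1e-5, weight decay 1e-4 | L2 decay added to the gradient |
| k (k-NN) | 3 | ablation-MSB map 3/7/5/9 per magnification |
| tie policies | vote tie → malignant; rank ties → stable training order | conservative for the clinical framing: missing a malignancy is the costly error |
| fold sd | sample sd (ddof = 1) | "mean ± sd over folds" convention |

### Initialization and scale calibration

W is initialized as a random orthonormal frame (QR of a Gaussian matrix,
sign-fixed for determinism), i.e. a random isometric projection. Its *scale*
is then calibrated so the median pairwise embedding distance of (a subsample
of) the training features equals 2m. Rationale: the triplet hinge only
produces gradients where the semi-hard band (d_ap, d_ap + m) is populated;
when typical embedding distances dwarf the margin, that band is a sliver and
a short training schedule cannot move a 512×2048 layer. Calibration puts the
untrained model in the loss's sensitive regime, after which the optimizer
dominates the final geometry. It is a no-op for cosine distance and
normalized embeddings (both scale-invariant), and is deterministic (evenly
spaced row subsample, no RNG).

### Mining selection rule

For every ordered same-class (anchor, positive) pair, among negatives
satisfying the semi-hard condition the one *closest to the anchor* is
selected, with exact ties resolved by lowest batch index. This makes mining
deterministic and lets tests compare the miner against exhaustive
enumeration exactly. A batch with a single class yields no triplets and a
logged warning; a batch where no negative falls inside the band yields an
empty list silently. Mining recomputes embeddings every optimization step
(standard online mining). Gradients are exact subgradients of the hinge
through the chosen distance (and through the normalization when enabled);
distance denominators are floored at 1e−12.

## The synthetic corpus generator

Real feature corpora cannot ship with the package, so studies run on a
hierarchical Gaussian generator: a random unit direction separates the two
class means by `class_separation`; each patient mean sits `patient_spread`
from its class mean in a random direction; each (patient, magnification)
cell is offset by `magnification_shift`; images add isotropic
`noise_sd`-per-coordinate noise. Subclasses (A/F/TA/PT benign, DC/LC/MC/PC
malignant) are assigned round-robin; an optional "straddler" mode draws a
fraction of a patient's images around the *opposite* class mean, emulating
the clinically unstable patients a per-patient fold grid exposes. A
census-shaped variant reproduces the reference corpus's patient counts
(24 benign / 58 malignant across eight subclasses) and per-patient image
rates at a configurable scale.

The generator produces class-level clustering, patient coherence and
magnification substructure — the three properties the pipeline relies on —
but none of the photometric reality of stained tissue: no stain variation,
no spatial texture, no anisotropic feature covariance, no label noise.
Passing studies therefore demonstrate that the machinery is correct and
behaves as designed under controlled geometry; they say nothing about
clinical performance on real slides.

## Study conditions

Chosen once and fixed (sizes are the package's own choices for desk-scale
studies):

* **Separation recovery** — 2048-dim features, 10+10 patients, 8 images per
  patient per magnification, four magnifications, separation 3× noise sd,
  patient spread 2× noise sd, five 70/30 folds, 10 seed replicates. At this
  geometry plain distance in ℝ²⁰⁴⁸ is almost blind to the class signal
  (inter/intra distance ratio ≈ 1.001), so raw-feature k-NN hovers near
  chance while a learned linear metric can isolate the separating direction —
  the regime where the embedding layer earns its keep. Reported: mean PLA of
  the full pipeline vs the ablation per replicate, and the training-set
  inter/intra ratio before vs after training.
* **Flat-k** — a well-separated corpus (separation 10× noise sd, 256-dim,
  8+8 patients) swept over k = 3..21; the max−min image-accuracy spread is
  the reported quantity.
* **Out-of-distribution** — same geometry at 64 dims; a foreign cloud offset
  by 10× the class separation in a random direction is embedded with the
  trained model and projected by a train-fitted 2-D projector; reported is
  the fraction of foreign points whose nearest projected training point is
  farther than the training set's own median nearest-neighbour distance.
  The moderate dimensionality is deliberate: a random offset direction in
  very high dimension is nearly orthogonal to the train-variance plane a
  *linear* projector keeps, which would hide the shift from the 2-D view
  (not from the embedding); at 64 dims the shift retains a clearly visible
  in-plane component.
* **Census-shaped end-to-end** — the BreakHis-census generator at scale 0.15
  (≈1 230 images, 13 patients), MIB + MSB + MIB ablation, five folds.

## Interpretability artifacts

The 2-D projector is fitted on training embeddings only and applied
out-of-sample to test/foreign points, so the view cannot be flattered by the
points being judged. UMAP (fixed seed) is the canonical choice; a PCA
projector satisfies the identical contract, is deterministic and fast, and
is used wherever the 2-D view is presentation rather than claim. Patient
views attribute each of a patient's projected points to the nearer projected
training-class centroid, flagging straddlers. Explanation bundles are the
k-NN evidence lists (neighbour ids, distances, labels, optional thumbnail
paths) written as delimited text; by construction their majority label *is*
the prediction. No formal OOD score is defined — the artifact is the
projection plus the distance summary above.

## Numerical and degenerate-input choices

* All randomness flows through seeded numpy generators; fixed-seed runs are
  bit-reproducible (loss history, weights, predictions, written reports).
  Per-fold seeds are derived as `(base·100003 + fold) mod (2³¹−1)`.
* k larger than the training set is clamped with a warning; an empty test
  set yields an empty prediction set; an all-one-class training set is an
  error for training, and a single-class truth set reports AUC as missing
  with a warning.
* Feature tables round-trip exactly through CSV (`%.17g` on write,
  round-trip float parsing on read).
* Fold-average sd uses ddof = 1; a single fold reports sd 0.
* Zero training epochs return the initialization untouched; non-finite loss
  aborts naming the epoch.

## Known limitations

* The embedding is strictly linear; corpora needing nonlinear metrics are
  out of scope by design (the point is the interpretable, minimal trained
  component).
* The synthetic generator's isotropic Gaussians make distance-based
  classification *harder* than real CNN features at matched separation
  (no low-dimensional manifold), so synthetic PLA values are analogues, not
  forecasts.
* MSB training sees roughly a quarter of the images per model, and the
  studies reproduce the expected drop relative to MIB; no augmentation is
  attempted.
* The tie policy (ties → malignant) is asymmetric by clinical intent;
  corpora where the benign class is the costly error should flip
  `POSITIVE_CLASS`/`TIE_PREDICTION` and re-pin the tests.
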