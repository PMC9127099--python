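# Methods

## The labelling model

The package operationalizes a simple observation: two kinds of coarse label
err in *opposite* directions. A hand-drawn convex rough label (MGRL, symbol
`C`) always over-covers its object; a colour-threshold label restricted to
the MGRL (CDTL, symbol `P'`) under-covers it, because the AND with the MGRL
removes any threshold response outside it and the threshold itself misses
boundary pixels. A network trained to fit *both* targets at once,

    L_all = Σ_t L(O, target_t),     targets = [C, P']

cannot satisfy either exactly; for the single-class mean-squared-error case
its pixel-wise optimum is (C + P')/2 — 1 inside the region both agree on,
0.5 in the disputed ring, 0 outside. Thresholding the output at 0.7 keeps
only the consensus region, which is the object. The target list generalizes
to any number of coarse labels (multi-target single output); the loss stays
an unweighted sum, so `clp_loss([C, P]) = clp_loss([C]) + clp_loss([P])`
exactly.

`L` is the pixel-mean squared error against a binary target for one
foreground class, and pixel-mean cross entropy against integer class masks
when there are several (the output then carries a softmax over background +
K classes; a sigmoid map otherwise). Inputs are normalized to [0, 1].

## Threshold-label generation

* Channels are normalized by their **per-image maximum**; an identically
  zero channel maps to zero. The difference of two normalized channels is
  thresholded at α, with `diff == α` counting as foreground.
* Plain CDTL uses a fixed pair (default G−R) and a fixed α (default 0.1);
  `alpha="auto"` reuses the GCDT scoring restricted to that pair so one
  selection principle backs both paths.
* GCDT, per class: the class's MGRL region is reduced to a **base** — its
  Euclidean distance transform, normalized by the maximum within each
  connected component, cut at 0.7 (a relative depth, so every disjoint blob
  keeps a seed; an isolated pixel is its own base). Every ordered channel
  pair (all six; the sign of the difference matters) × every α in the grid
  (default 0.02…0.50, step 0.02) produces a candidate that is first ANDed
  with the MGRL region, then scored by IOU against the base; the best
  candidate wins, with first-encountered order breaking exact ties. If all
  candidates are empty the base itself is used and a warning raised. A
  pixel claimed by several classes goes to the class with the higher
  selection score, ties to the lower class index.
* Scoring happens **after** the AND with the MGRL; an empty candidate
  scores 0 (no evidence) rather than 1, so it can never win against a
  nonempty base.
* Optional mask denoising (3×3 average-then-rebinarize at 0.5, or median)
  is provided for comparison but is off by default — the trained network
  suppresses CDTL noise on its own.

## Network

A U-Net-style encoder–decoder. Each level is conv3×3–BN–ReLU twice;
2×2 max pooling between encoder levels; the decoder upsamples by
nearest-neighbour ×2 followed by a 1×1 projection to the skip level's
channel width (nearest-neighbour is used rather than an interpolating
kernel: its adjoint is an exact 2×2 block sum, and at these feature-map
scales the kernel choice is immaterial to the fusion contract). The skip
merge is the weighted element-wise sum

    fused = (1 − γ)·E + γ·D,    γ = 0.2

rather than concatenation; `use_fusion=False` restores concatenation as the
ablation baseline (its decoder blocks then take twice the channels).
Architecture internals — depth 4, 32 base channels, batch norm, He
initialisation — are package choices made for desk-scale trainability; the
fusion rule is the modelling commitment. The whole network and its backward
pass are NumPy (im2col convolutions against BLAS); training is therefore
bit-deterministic given the seed.

## Training protocol and endpoint selection

Adam at learning rate 0.005, batch size 12, 40 epochs are the reference
settings for field-scale binary labelling (5 epochs suffice for the circle
scenes; 50 were used for public leaf data). Batches are reshuffled each
epoch from the run seed; partial batches are kept. A non-finite loss aborts
with a diagnostic.

Because the targets are deliberately wrong at the boundary, prolonged
training drifts the output toward the rough labels. The training endpoint
is therefore chosen by validation: a seeded fraction (default 10%) of the
images carries fine labels, and after every epoch the mIOU of thresholded
predictions against those fine labels is recorded. The validation images
stay **inside** the training set — the artifact's goal is labelling its own
training corpus, so holding them out would waste annotation. The endpoint
is the epoch of maximum validation mIOU (earliest on ties); best-so-far and
last checkpoints are retained so it is always recoverable. The history also
records each epoch's prediction-to-MGRL similarity, which exposes the drift
(it stops falling and plateaus — or rises — once the model starts fitting
the rough labels' errors).

## Evaluation

One-vs-rest confusion counts per foreground class give IOU, precision,
recall, F1 and MCC; mIOU is the unweighted class mean. Degenerate
denominators: empty-vs-empty counts as a perfect match (IOU/P/R/F1 = 1),
one-sided emptiness as 0, and MCC is 0 whenever a factor under its root
vanishes. Dataset-level reports accumulate counts over all images before
taking ratios (a per-image variant exists). The "similarity rate" between
two label sets is reported as 100·min/max of their mIOUs and is flagged in
the docstring as an interpretation, since no standard formula exists.

## Synthetic data

No real field imagery is redistributable, so two seeded generators stand in:

* **Circle scenes** (default 500 images at 512², noise σ = 10/255 of the
  intensity range): noisy discs on a noisy pallet; ground truth is the
  exact rasterized disc and the MGRL the same disc with radius ×1.3
  ("somewhat wider"). Discs are rendered with a green-biased foreground
  (80, 160, 90) over soil-grey (150, 130, 110) so the same
  channel-difference machinery applies to them — the colour model is a
  package choice; nothing about the original circle data's colours is
  documented.
* **Field scenes**: leaf-like blobs (unions of rotated ellipses, optional
  circular holes) at leaf-green over a low-frequency red-brown soil
  texture; MGRLs are per-class convex hulls dilated by 6 px. Foreground has
  G-dominance and background R ≥ G on average, mirroring vegetation colour
  statistics.

What these do **not** emulate: shadows and illumination gradients, specular
highlights, object overlap between classes, texture within leaves, weeds
with leaf-like colour. Passing tests therefore demonstrate the pipeline's
mechanics and its refinement property under the stated colour model, not
performance on real crops.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run the refinement experiment on
64 circle images at 128² (rough-label inflation 1.3, 8 training epochs,
3 seeds), the extended endpoint/drift run for 20 epochs on the same set,
and the target ablation on 24 field images at 96² for 20 epochs × 3 seeds —
the ablation compares *converged* endpoints, since before convergence all
target configurations score alike. The network in these runs is depth 2
with 8 base channels; the refinement margin is insensitive to making it
larger. Oracle comparisons (metrics, distance base, GCDT selection) use
≤32² grids where exhaustive per-pixel search is exact and fast.

## Known limitations

* Channel-max normalization ties the threshold to the brightest pixel of
  each channel; a single saturated pixel rescales the whole difference map.
  This is inherent to the labelling rule, not an implementation artifact.
* The base-IOU selection of α is biased toward slightly conservative
  thresholds (candidates resembling the deep interior score better), which
  is harmless downstream — the network recovers the boundary — but makes
  raw GCDT masks under-cover.
* The NumPy network is practical to tens of thousands of optimizer steps at
  128²–512² on a CPU; it is an exact, dependency-free implementation, not a
  performance claim.
* MGRL-only training depends strongly on where its endpoint lands (the
  validation subset is small); its run-to-run spread is visibly larger than
  the dual-target configuration's — consistent with the motivation for the
  coarse-label *pair*.
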