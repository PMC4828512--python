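# Methods

## Problem and approach

`hipposeg` segments the hippocampus in co-registered structural MR volumes
by classifying voxels. Inputs are 50×60×60 peri-hippocampal volumes of
interest (VOIs) already affine-registered to a common space, together with
binary manual masks for training (registration itself is out of scope).
The hippocampus occupies only a few percent of the VOI, so the voxel
classification problem is strongly class-imbalanced; the core classifier is
RUSBoost — confidence-rated boosting in which each round first randomly
undersamples the majority (background) class — with plain Adaboost available
as the same loop with undersampling disabled.

The pipeline has four stages:

1. **rVOI restriction.** The voxelwise OR of the training masks is dilated
   by a cubic kernel (default 2×2×2) to form the reduced VOI. Voxels outside
   it cannot be hippocampus in a co-registered scan (the dilation margin
   covers test subjects whose hippocampus slightly exceeds the training
   bounding region), so classification and training are restricted to it.
   On default phantom cohorts the rVOI holds roughly 35–40% hippocampal
   voxels, so the restriction also tames the imbalance before boosting.
2. **Features.** Every rVOI voxel is described by 315 numbers:
   248 Haar-like responses, 48 Haralick statistics, 16 gradients, 3
   positions (details below).
3. **Boosting.** Up to T rounds of undersample → fit weak tree → pseudo-loss
   → weight update.
4. **Evaluation.** Dice, Precision, Recall, Relative Overlap (Jaccard), plus
   volume agreement (Pearson r, OLS line, exact sign test) across a cohort.

## The boosting loop

Labels are y ∈ {−1, +1} with +1 the hippocampus (minority). Weights start
uniform, D₁(i) = 1/m. Each round t:

1. Random undersampling removes majority examples uniformly at random until
   a fraction N (default 50%) of the working set is minority. Minority
   examples are never removed, nothing is oversampled, and if the majority
   count is already at or below target the set is left unchanged. The
   retained weights are renormalised.
2. A weak learner is fit on the undersampled set with those weights: a
   depth-limited CART-style tree (default depth 3) grown greedily on
   weighted Gini impurity with exhaustive midpoint-threshold search.
   Leaf confidences are the weighted class fractions in the leaf, so
   h(x, +1) + h(x, −1) = 1 by construction. Ties in the split search are
   broken deterministically (lowest feature index, then lowest threshold).
3. The pseudo-loss is computed **on the full training set** with the current
   distribution D_t:
   ε_t = ½ Σ_{(i,y): y≠y_i} D_t(i) (1 − h_t(x_i, y_i) + h_t(x_i, y)),
   which for binary labels reduces to Σ_i D_t(i)(1 − h_t(x_i, y_i)).
   The ½ factor makes the uninformative hypothesis h ≡ 0.5 score exactly
   0.5, so the guarantee "α_t ≤ 1 iff ε_t ≤ ½" retains its random-guessing
   reading; `half_scaling=False` exposes the unhalved literal form for
   comparison.
4. α_t = ε_t / (1 − ε_t), with ε floored at 1e-10 so a perfect round keeps
   log(1/α_t) finite.
5. Weights update multiplicatively, D ← D · α^(η·½(1 + h(x_i,y_i) −
   h(x_i,ȳ_i))), then renormalise. With complementary confidences the
   exponent equals η·h(x_i, y_i): with hard 0/1 confidences and η = 1,
   correct examples are scaled by α and misclassified ones are untouched.
   The learning rate η (default 0.1) only shrinks the update exponent; the
   prediction weights stay log(1/α_t).
6. A round whose ε_t reaches 0.5 is retried with a fresh undersample up to
   3 times (once, when undersampling is disabled), after which the loop
   stops early and returns the rounds accumulated so far.

Prediction: H(x) = argmax_y Σ_t h_t(x, y) log(1/α_t); an exact tie returns
−1 (background), biasing toward the majority class on zero evidence.

Defaults mirror the selected operating point: T = 150, η = 0.1, N = 50%
for RUSBoost; the Adaboost preset is T = 400, η = 0.1 with undersampling
off.

## The feature vector (315 per voxel)

* **Haar-like (248).** Four cubic window scales s ∈ {3, 5, 7, 9} × a fixed
  catalogue of 62 templates per scale. Each template is a signed combination
  of mean intensities over axis-aligned blocks of the s³ window centred on
  the voxel: the full-window mean; half-slab means/differences/contrasts per
  axis; centre-plane and centre-row means and their contrasts with the full
  mean; quadrant means, diagonal contrasts and opposite-quadrant differences
  for each axis pair; octant means, the octant checkerboard and
  opposite-octant differences; the centre voxel, its contrast with the full
  mean, and an inner-cube mean at roughly half scale. Averaging templates
  have weights summing to 1, difference templates to 0 (hence zero response
  on constant images). The catalogue is enumerated as data in one source
  file and its size is locked by tests. At the smallest scale a few
  templates coincide numerically (e.g. the inner cube equals the full
  window at s = 3); they are kept so the bank has identical structure at
  every scale.
* **Haralick (48).** For each odd neighbourhood size n ∈ {3, 5, 7, 9}, the
  n³ cube is mean-projected along each axis to three n×n subimages; each is
  min–max quantized to G = 8 gray levels (a constant subimage maps to level
  0), a symmetric GLCM is accumulated at offset (1, 0), and energy,
  contrast, correlation and inverse difference moment are read off
  (correlation is defined as 0 for a degenerate marginal). 4 × 3 × 4 = 48.
* **Gradients (16).** Symmetric differences I(v + d·u) − I(v − d·u) for
  directions u ∈ {x, y, z, (1,1,1)} and distances d ∈ {1, 2, 3, 4}.
* **Position (3).** The voxel's 0-based (x, y, z) indices in the VOI grid —
  comparable across subjects because the VOIs are co-registered.

All neighbourhood operations use edge replication at the volume border, so
features are defined at every rVOI voxel. The batch extractor uses an
integral image (Haar) and full-volume running means plus per-voxel histogram
bincounts (Haralick); a naive per-voxel reference implementation of every
extractor is kept and the two are held to 1e-9 agreement by tests.

## rVOI construction details

The 2×2×2 structuring element has no centre voxel; the dilation is anchored
at the element's low-index corner, i.e. offsets {0, 1}³, so a single voxel
dilates to the 8-voxel cube {v, v+1}³ and a (1,1,1) kernel is the identity.
This one-sided convention is fixed and locked by a test; the rVOI is always
a superset of the union of training masks, and adding a training mask can
only grow it. Voxels are enumerated in raster order with x varying fastest.

## Synthetic phantoms

Real peri-hippocampal data cannot ship with the package, so a generator
produces cohorts that reproduce the *statistical* challenges of the task on
the same 50×60×60 grid: a compact irregular minority-class structure
(ellipsoid with semi-axes (11, 15, 15) voxels ≈ 5.8% of the grid, deformed
by a smooth random radial field of amplitude 0.18, translated by up to ±4
voxels and volume-scaled by 0.85–1.15 per subject), foreground +40 intensity
units over a background of 100, smoothed-noise texture (amplitude 6, σ = 2),
a smooth polynomial bias field of up to ±8%, and white Gaussian noise
(σ = 5). Masks are guaranteed connected and strictly interior (regenerated
up to 10 times otherwise). Cohort volumes vary by construction, so
volume-agreement statistics are non-degenerate.

What the phantoms do **not** emulate: anatomy (shape priors, neighbouring
structures with confusable intensity), MR physics (Rician noise, partial
volume), registration error, or rater variability in the manual labels.
Passing the synthetic end-to-end tests therefore shows the machinery is
correct and the pipeline recovers a textured minority structure under
noise and inhomogeneity — not that real-scan accuracy matches any particular
level. Phantom contrast is deliberately clean, which is why held-out Dice
on phantoms (~0.99) is far above what is achievable on real scans.

## Numerical and design choices

* Split search is exact (every midpoint between consecutive distinct
  values), with a sequential scan kernel (numba-accelerated when available;
  a pure-Python/numpy scan with identical arithmetic is the fallback and
  the reference in tests).
* A split must reduce the weighted Gini cost by more than 1e-12 to be
  accepted; otherwise the node becomes a leaf with the weighted class prior.
* Weight vectors are renormalised to sum 1 every round; tests enforce 1e-9.
* GLCM quantization: level = floor((v − min)/(max − min) · G) clipped to
  G − 1.
* Determinism: all randomness flows through `numpy.random.Generator` seeded
  from user-supplied seeds (cohorts use `SeedSequence.spawn` per subject);
  identical seeds give bit-identical model JSON.
* Model serialization is canonical JSON (sorted keys, fixed separators);
  a round-trip reproduces predictions exactly.
* Cross-validation uses repeated random subsampling (m train / rest test)
  rather than k-fold, matching experiments in which m is varied freely.
* Left/right hemispheres are independent runs of the same pipeline; the
  code carries a side tag only.

## Desk-scale problem sizes

The full-scale experiment trains on every voxel of every training rVOI
(~26,000 voxels × m subjects). The package's reference experiment
(`hipposeg.experiments.phantom_holdout_experiment`, also run by
`scripts/acceptance.py` and the end-to-end test) keeps the full operating
point (T = 150, η = 0.1, N = 50%, depth 3) but uniformly subsamples 3000
training voxels per subject — the optional desk-scale knob, recorded in the
model provenance; segmentation still classifies every rVOI voxel. Smaller
examples and tests shrink the grid (24×28×28) and T instead.

## Known limitations

* The Haar catalogue and the gradient direction/distance sets are one
  reasonable fixed choice of bank with the right cardinalities; other banks
  of the same size would be equally valid.
* Undersampling targets an exact integer majority count
  round(n_min(1−N)/N), so the realised minority fraction can differ from N
  by up to one part in the subset size.
* `volume_agreement` requires ≥3 subjects and nonzero variance on both
  sides.
* No post-processing (largest-component selection, morphological cleanup)
  is applied to predicted masks; with the rVOI restriction and strong
  features it has not been needed on phantoms.
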