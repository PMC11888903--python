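# Methods

This note documents the models, conventions and design choices behind
`phca`: what is computed, under which assumptions, and what the synthetic
experiments do and do not demonstrate.

## Vietoris–Rips persistence and the radius convention

All scales are expressed in the *radius* parameter ε: two points are joined
once `d(x_i, x_j) ≤ 2ε`, and a clique enters the filtration at half its
vertex-set diameter.  Under this convention the default filtration horizon
is `maxsc = ½ max d(x, y)` — half the cloud diameter — and the
two-point cloud `{(0,0), (3,4)}` merges at exactly ε = 2.5.  Any backend
thresholding on raw distances would have to be driven at 2ε with its
outputs halved; the in-package engines work in radius units natively.

**Essential classes.**  The filtration cannot be run forever, so features
still alive at the horizon (always the final connected component, sometimes
1-cycles) are reported with `death = maxsc` and a `capped` flag, and they
*do* participate in lifespan totals.  This keeps the score function finite
and makes the dimension-0 closed form exact:

```
Σ lifespans (dim 0) = maxsc + ½ · Σ MST edge weights,
```

because single-linkage merge heights are half the minimum-spanning-tree
edge weights.  The closed form is both the fast H0 path and an independent
invariant asserted across random clouds in the tests.

**Zero-lifespan rows** are retained in diagrams (they contribute nothing to
any total) because engines legitimately differ on emitting them; engine
equivalence is always asserted modulo zero-length bars.  One consequence:
on a collinear cloud the horizon edge closes a cycle that the clique rule
fills at the same instant, producing a dim-1 row of zero lifespan — that
row is correct, not a defect.

**Tie-breaking** in the simplexwise order is `(entry scale, dimension,
lexicographic vertex tuple)`, making both engines fully deterministic.

**Supported dimensions.**  H0 and H1 — the range the classifier tunes over.
Dimension 2 raises an explicit unsupported error; voids never enter the
score function here.

**Engines.**  `vr_persistence` computes H0 by a union-find sweep and H1 by
column reduction of the triangle boundary matrix over F2, with columns held
as integer bitsets.  `brute_force_persistence` is the oracle: full clique
enumeration and textbook left-to-right reduction of the complete boundary
matrix, restricted to ≤ 10 points.  The two are cross-checked on suites of
random small clouds; `h0_persistence_mst` is additionally checked against
the general engine on larger clouds.

## The classifier

`fit` stores each class cloud `X_i` and its baseline total lifespan over
the active dimensions; `score_class` recomputes persistence of
`Y_i = X_i ∪ {α}` *under the horizon of `Y_i` itself* (the horizon is a
property of whatever cloud is being filtered, so it is not frozen from
training — a deliberate choice the score examples rely on).  Prediction is
the argmin of scores with ties broken by training-declared label order,
making prediction deterministic.

Scores inherit the geometry of Euclidean distances: rigid motions leave
them unchanged, and scaling all coordinates by `c > 0` scales every score
by exactly `c` — both asserted as properties.

The default homology dimension is H0 only: it is the cheapest setting, and
in cross-validation on every synthetic corpus we generate it is never
beaten by settings that include H1 (isolated landmark clouds carry little
stable 1-dimensional structure).  No per-query caching is attempted; the
MST fast path bounds the cost of the common case.  Training features pass
through the same standard scaler as every other classifier in the harness.

## Evaluation protocol

Per trial: stratified 90/10 split → standard scaling → random-search tuning
→ refit → test metrics.  Specific conventions:

* **Stratified split** uses largest-remainder rounding of per-class test
  counts so totals are exact for imbalanced data.  Within each class, rows
  are put in lexicographic order before the seeded shuffle, so the
  partition of the row multiset is invariant to input row order.
* **Scaling** centers every feature and divides by the population standard
  deviation; zero-variance features are centered only.  Inside
  cross-validation the scaler is refit on the training folds only.
* **Random search** runs 20 iterations over the published per-classifier
  distributions (SVM: C ~ U(2⁻³, 2¹⁵), rbf, gamma ∈ {auto, scale}; RF:
  n_estimators 1–350, max_depth 1–5, min_samples_split 2–10; KNN:
  n_neighbors 1–500; LDA: solver ∈ {svd, lsqr, eigen}, shrinkage ~ U(0,1);
  CART: max_depth 1–30, min_samples_leaf 1–60, min_samples_split 2–60;
  PHCA: homology dimension ∈ {H0, H1, H0+H1}), scoring each draw by mean
  stratified 5-fold CV accuracy; first-sampled wins ties.  Identical
  repeated draws reuse their (deterministic) score rather than recomputing
  it.  KNN draws larger than the training size are clamped; LDA shrinkage
  is dropped for the svd solver (incompatible); min_samples_split starts at
  2 because a split of one sample is meaningless.
* **Metrics** are computed from one-vs-rest confusion counts: macro
  precision/recall/F1/specificity over classes, accuracy over the whole
  test set.  Undefined precision or recall contributes 0 (and forces that
  class's F1 to 0); undefined specificity — a class with no negative
  instances — counts as vacuously 1, which preserves "perfect classifier ⇒
  specificity 1".
* **Seeds.**  Trial `t` uses `base_seed + t` for its split, fold shuffling
  and samplers, so any run is reproducible bit for bit.

## Classifier comparison

Within a trial the six classifiers are compared on N = 5 blocks — the five
metric values — ranked "higher is better" with mean ranks for ties.  The
Friedman statistic uses the standard tie-corrected form
`(k−1)·Σ(R_j − N(k+1)/2)² / (A − C)` (statistic 0 and p = 1 when every
block is fully tied), cross-checked against `scipy.stats.friedmanchisquare`
where scipy supports the shape.  Nemenyi p-values come from the Studentized
range distribution at infinite degrees of freedom applied to average-rank
differences, reported capped to [0.001, 0.900] — the range of the standard
tabulations — and are exactly consistent with the critical-difference rule
`|ΔR| ≥ CD ⇔ p ≤ α`, with `CD = q_α √(k(k+1)/6N)` and
`q_α = Q_{1−α,k,∞}/√2` (for k = 6, α = 0.05: q = 2.850, CD at N = 5 is
3.372).  Blocking on metric values makes the five blocks correlated, so
these per-trial tests are descriptive rather than strictly calibrated; the
block structure is configurable (blocks = trials gives a pooled test).

A caption in the source literature for this comparison style inverts the
usual convention ("greater than α ⇒ significant"); this package follows the
standard reading — p ≤ α means significantly different — which matches the
accompanying narrative ("no significant difference at p = 0.9").

## Synthetic data

Two generators emulate the post-extraction form of a static sign-alphabet
image corpus (24 static letters, A–Y without the motion letters J and Z):

* **Gaussian blobs** place k isotropic classes at mutually equidistant
  centers along *random orthonormal* directions.  Axis-aligned centers
  would concentrate all between-class variance in k of the 63 coordinates,
  which the mandatory per-feature standardization then flattens — with
  random orthonormal directions the separation survives scaling.  Defaults:
  m = 63, σ = 1, separation 20 (landmark classes are tightly concentrated
  relative to pose differences); the parameter-recovery tests verify
  held-out PHCA accuracy ≥ 0.95 down to separation 8σ.  Note that in 63
  dimensions the within-class inter-point distance is ≈ σ√126 ≈ 11σ, so
  "separation ≥ 8σ" describes clusters that already touch in distance
  terms — a genuinely nontrivial recovery condition.
* **Hand-like clouds** build one stylized skeleton per class (wrist + five
  finger chains of four joints, distinct per-class fan and curl angles),
  then jitter (σ = 0.02), randomly translate (±0.05) and scale (±10%) each
  sample, flattening to 63 features.  A per-class conversion-failure
  probability excludes samples from the dataset while counting them in the
  conversion report, emulating an image front-end that fails to detect a
  hand.  The study-shaped default is 24 classes × 450 samples with two
  classes fully converted, two at 30% failure (minimum converted count near
  313) and 5% elsewhere.  `build_balanced` subsamples every class to the
  minimum converted count (re-drawn per trial with the trial seed);
  `build_imbalanced` keeps all converted samples.
* **Shape fixtures** (circle, sphere, torus with R = 2, r = 0.5 and proper
  area-weighted sampling) anchor the qualitative persistence checks — a
  dense circle yields one dominant 1-cycle; a torus sample shows a dominant
  tunnel bar against the noise bars within a capped horizon (0.5), chosen
  to keep the clique filtration tractable at 400 points.

What passing these tests shows — and does not.  The generators provide
within-class geometric coherence, class imbalance and conversion loss, but
not the heavy-tailed landmark noise, detection jitter correlated across
joints, lighting- and signer-dependent variation, or inter-class similarity
structure of real extracted corpora.  Perfect synthetic accuracy therefore
validates the machinery (scoring, tuning, metrics, statistics), not
real-world recognition rates.

## Problem sizes

The shipped experiment (`scripts/acceptance.py`) runs the full pipeline at
desk scale — 6 classes × 40 samples, 2 trials, the complete roster and
tuning budget (20 × 5-fold) — the sizes at which the whole protocol,
including the O(n³)-simplex dimension-1 searches inside cross-validation,
completes in a few minutes on one core.  The same code runs the
study-shaped corpus (24 × 450) unchanged when more time is available.  On
this easy synthetic corpus most classifiers reach perfect test metrics, so
the per-trial Friedman test is frequently fully tied (p = 1) and PHCA's
Nemenyi p-values against the strong baselines sit at the 0.900 cap —
exactly the "no significant difference" outcome the comparison machinery
is designed to detect.

## Known limitations

* Dimension-1 scoring enumerates all triangles under the horizon; beyond a
  few hundred points per class this dominates runtime.  Dimension 2 is not
  implemented.
* PHCA as specified has no probabilistic output, and scores of different
  classes are not calibrated against class size (a larger class changes
  less when a point is added; the balanced builder mitigates this).
* The per-trial Friedman/Nemenyi blocks are the five correlated metrics of
  one split; treat the per-trial p-values as descriptive summaries.
* The image front-end depends on an optional third-party landmark model;
  its conversion counts are environment-dependent and are not treated as
  reproducible quantities.
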