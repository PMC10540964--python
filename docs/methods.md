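# Methods

This note records the modelling choices, parameter defaults, numerical
conventions and known limitations of the package. It states nothing that
the test suite or `scripts/acceptance.py` does not itself compute.

## The phantom generator

The generator emulates the aspects of a thoracic CT stack that the
retrieval method actually consumes; it is not an anatomical simulator.

Per case it draws, from a generator seeded by `(seed, case_seed)`:

* a thorax disc at tissue intensity (0 HU) on an air background
  (−1000 HU), radius 0.46 of the image side;
* two elliptical lung lobes at parenchyma intensity (−700 HU). The lobe
  semi-axes follow a *monotone* linear growth over the stack (25–40%
  over the full stack, drawn per case) times a small (±4%) sinusoidal
  modulation. Monotonicity is deliberate: it makes the inter-slice
  dissimilarity strictly increasing in the layer gap for **every** case
  and every layer, which is the geometric fact the weak contour labels
  (adjacent ≈ similar, distant = dissimilar) rely on. A purely periodic
  profile would let slices half a period apart coincide.
* 3–7 bright "white stripes" per case — filled discs (nodule-like,
  radius 2.5–5.5% of the image side) and thick short polylines
  (vessel-like) — placed inside the lobes, each drifting by at most
  `stripe_drift` (default 1.5 px) per slice along a random walk, each
  present over a contiguous ~60–100% of the stack;
* additive Gaussian noise, σ = 10 HU, applied last and clipped to
  [−1000, +50] HU. The noise prevents exact-equality shortcuts in the
  learned similarity.

Defaults are 64×64 pixels and 20 slices — small enough that the whole
pipeline trains on one CPU in minutes; 512×512 works unchanged.

What the phantom does **not** emulate: anatomy (real lobe shapes,
mediastinum, trachea), reconstruction physics (beam hardening, streaks),
intensity texture inside the parenchyma, and inter-patient intensity
variation. Passing tests therefore demonstrate that the machinery is
correct and that the weak-label scheme is learnable when its geometric
assumptions hold — not that the learned scores transfer to clinical CT.

## Preprocessing

Air/tissue separation at −320 HU (a conventional parenchyma threshold;
the method itself only requires "air-like vs not"). Exterior air is the
set of air pixels 4-connected to the image border (flood fill seeded
from every border pixel); remaining air components below 0.5% of the
image area are dropped as specks. Hollows are closed with a disc.

Two closing radii exist deliberately. `extract_lung_mask` defaults to
the vessel-scale `ceil(7·size/512)`, which fills fibrous texture. The
pipeline-level `mask_case` defaults to the structure-scale
`ceil(size/16)`: fully enclosed nodule-size structures punch holes in
the air-threshold mask that a vessel-scale disc cannot reclaim, and the
detail network needs those bright structures *inside* the masked slice.
At 64 px this is radius 4 (radius 1 demonstrably strips nearly all
stripe pixels from the masked slice).

Coordinates are (row, col), 0-based, row-major throughout.

## The spatial transformation layer

The warp is a thin-plate-spline displacement field interpolated from a
5×5 control grid: the grid generator is `scipy`'s RBF interpolator with
the thin-plate kernel and a degree-1 polynomial tail, evaluated at every
output pixel; the sampler is bilinear (`map_coordinates`, border value
outside). The degree-1 tail means identical displacements at all 25
control points reduce the field to an exact translation — one of the
two identities the acceptance script checks (the other is the zero-θ
identity). θ lives in the normalized [−1, 1] coordinate system; an
entry of magnitude m displaces by m·(size−1)/2 pixels. θ is drawn and
normalized per sample.

Warping and then warping with −θ is only an *approximate* inverse:
measured on a noise-free phantom slice at magnitude 0.05, the residual
mean error is ≈2.8% of the dynamic range, concentrated at the sharp
lobe edges where bilinear resampling is not invertible. The test bound
is 4%.

## Weak-label pair construction

**Contour pairs** (default magnitude 0.05, negative gap 0.3 of the
stack, 1:1): *both channels of every pair — positive and negative —
receive the same light augmentation* (an independent warp of the same
magnitude plus fresh σ = 10 HU noise). The symmetric augmentation is a
deliberate and load-bearing choice: if only the positive's second
channel were warped, interpolation artifacts and the shared noise field
would be perfectly label-correlated, and the network reliably learns to
detect *warping* rather than outline shape — in that failure mode even
the identical pair (A, A) scores ≈0 and adjacent layers rank below
arbitrary ones. With symmetric augmentation the contour logit decays
monotonically with layer gap, which is the behaviour retrieval needs.

**Detail pairs** (default threshold 0.8, ratio 3:1): positives are
adjacent layers of one case; negatives are randomly drawn pairs
(different case or layer gap > 1) whose contour score exceeds the
threshold. If a candidate budget (2000 draws; 300 in the pipeline) is
exhausted the threshold relaxes in 0.05 steps with a logged warning —
with a freshly trained, sharply calibrated contour scorer few random
pairs clear 0.8, so relaxation is the common path at desk scale. The
exact label ratio is enforced by construction (largest counts with the
exact ratio and total ≤ requested). Negative mining is inherently noisy
(a contour-similar pair may well also be detail-similar); no correction
is applied, the 3:1 ratio is the mitigation.

## The similarity calculators

Both consume the pair as a 2-channel image, normalized from HU by
(x+1000)/1050; both emit one logit, sigmoid-mapped to [0, 1] for
scoring. The loss applies the sigmoid exactly once (the network output
is a logit): any reading that squashes an already-[0,1] score through a
second sigmoid would confine probabilities to [0.5, 0.731] and make
zero loss unattainable.

* **Contour net:** token = flattened 2-channel block (block 8 px),
  linear embedding (dim 64), learned positional embedding, 2 pre-norm
  transformer blocks (2 heads, MLP ratio 2), mean pooling, linear head.
* **Detail net:** 3×3 stem conv (width 16) + BN + ReLU + 2×2 max-pool,
  then four residual basic blocks (widths 16/32/64/128, strides
  1/2/2/2), then a full-extent valid convolution to one logit. The
  full-extent conv replaces the usual pooling+FC head precisely because
  its weights differ per spatial position: the logit depends on where
  bright structures sit, verified against a global-average-pooling
  ablation sharing the same trunk (>3× more translation-sensitive).

Training: Adam, lr 0.001, batch 16, 10 epochs by default. All
arithmetic is float64 numpy with hand-written reverse-mode gradients,
checked layer-by-layer against central finite differences (≤1e−5
combined abs/rel error; note a conv bias feeding a batch norm has a
true gradient of exactly zero, so pure relative error is the wrong
metric there). Everything is deterministic under the seed — there is no
backend nondeterminism to document.

Scores are not symmetrized: s(a,b) may differ from s(b,a). The pairwise
distance matrix used by the index evaluates each unordered pair once
(i < j order) and mirrors it.

## White-stripe graphs

Bright pixels of a masked slice (> −300 HU; parenchyma sits at −700,
soft tissue at 0) are graph vertices; two vertices are adjacent iff
their Euclidean distance is ≤ 2, giving the 12-neighbourhood of offsets
with lengths 1, √2 and 2 (radius 1.5 gives plain 8-connectivity if
wanted). Components are grown by breadth-first search with a
deterministic (lexicographic) seed order; edges are exactly the
adjacent in-component pairs. Component structure is verified against a
union-find oracle on random binaries.

Stripe similarity gates on relative vertex-count difference
(`count_tol` 0.25) and on the Euclidean distance (`shape_tol` 0.5)
between descriptors; the descriptor is the first four Hu
central-moment invariants of the stripe mask, log-scaled as
−sign(h)·log₁₀|h| so stripes of very different sizes remain comparable.
Hu invariants are translation-invariant by construction, which is the
property the comparison needs; edges are retained in the data structure
but do not enter the similarity. PTA-level `bSimilar` keeps the printed
asymmetric threshold `θ·|PTA₁|` (with multiplicity — one stripe
matching many counts many times); a `symmetric=True` variant uses
min(|PTA₁|, |PTA₂|). Defaults `θ = 0.5`. An empty first PTA is
degenerately TRUE and logged. The graph model motivates and labels
detail similarity; it is not the runtime detail scorer.

## Index and retrieval

Affinity propagation uses the canonical responsibility/availability
updates with damping 0.5, availabilities initialized to zero, the
median pairwise similarity as the preference, 200 iterations max and a
15-iteration stable-exemplar convergence window; a tiny seeded jitter
(1e−12 relative) breaks exact ties between identical points.
Non-convergence returns the last assignment with a warning flag. The
implementation is cross-checked in tests against scikit-learn's
affinity propagation on the same similarity matrices.

Cluster centres default to the AP exemplar. The "pick a random member
as centre" variant is available (seeded) but inflates radii and weakens
pruning, so it is not the default. The radius is the maximum
centre-to-member distance — the only definition that makes the
affected-cluster test sound. Boundary conventions: a cluster is pruned
iff d(centre, query) **>** R + r; a result is admitted iff d ≤ r
(boundaries kept).

For a metric distance the pruned range query is provably exact and is
tested as such (500 points, Euclidean, 50 queries, zero disagreement,
evaluation count ≤ n + #clusters). The learned distance 1 − SScore is
**not** provably metric, so with learned scores the pruned-vs-sequential
recall is *reported as a measurement*, never asserted. At desk scale the
learned distances are compressed near their extremes, cluster radii are
large and little pruning occurs — the speedup lives on metric-like
instances and larger databases.

## Evaluation

Precision is over the returned list; AP divides the summed
precision-at-relevant-ranks by the number of relevant retrieved items
(the standard reading; dividing by the list length is exposed as an
option), with AP = 0 for a query retrieving nothing relevant (the
formula is 0/0 there). Phantom ground truth: a result is relevant iff
it comes from the query's case within 2 layers. The end-to-end bar is a
*permutation* baseline: database provenance is shuffled 200 times and
the fixed rankings rescored; the trained system must beat the 95th
percentile of the permuted mean precisions.

## Problem sizes

Defaults throughout are chosen so each component is exercised at the
smallest size where its behaviour is non-trivial: 64×64 slices, 6
cases × 20 slices, 120 + 120 training pairs, 10 epochs, a ~108-slice
database with 12 held-out queries, 500-point metric instances, 200
random binaries for the graph oracle. The mechanisms are
size-independent; scaling up changes widths and wall-clock only.

## Known limitations

* The contour net trained on warp-positives generalizes to genuinely
  adjacent layers only through the symmetric-augmentation design; its
  raw-pair probabilities saturate near 1 at desk scale, so rankings rest
  on logit differences, not calibrated probabilities.
* Detail-negative mining is noisy by construction (see above).
* `bSimilar`'s multiplicity semantics let one stripe inflate the match
  sum; no de-duplication is performed.
* The learned distance may violate the triangle inequality; pruning is
  then best-effort and its recall is measured, not guaranteed.
* The alignment front-end (a spatial transformer normalizing pose
  between the two inputs) is a no-op hook: pairs are assumed already
  grid-aligned, which the phantom guarantees.
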