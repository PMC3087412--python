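# Methods

## Perceptual systems and the tolerance relation

Objects are described by `l` probe values, each required to lie in
`[0, 1]`; the constructor validates rather than rescales, because the
tolerance `ε` is only interpretable against a known feature range. The
relation `‖φ(x) − φ(y)‖₂ ≤ ε` is evaluated with an absolute slack of
1e-12 so that reflexivity and the inclusive boundary (`distance
exactly ε` relates) are robust to floating-point round-off. The metric
is fixed to L2; there is no metric plug-in.

For normalized features, two conventions circulate for the largest
attainable distance: the feature count `l` (the convention the tHD
definition uses) and the tight L2 diameter `√l` of the unit cube. The
implementation accepts any `ε ≥ 0` and does not police either bound;
the tHD largest-distance constant defaults to `l` with `√l` available
(`largest_distance="sqrt"`).

All neighbourhood and range searches are exact (vectorized distance
scans over the full description matrix). Approximate nearest-neighbour
indexing was deliberately not used: at desk scale exactness is cheap
and it makes oracle comparisons meaningful.

## Class enumeration

`find_classes_chaining` implements neighbourhood chaining. For each
anchor `z`, each eligible start `z′ ∈ N(z)` opens a chain; the chain
repeatedly queries the *nearest remaining neighbour* of the current
query point (ties broken by ascending object id — the tie rule is a
package choice, made for determinism), computes the next neighbourhood
only within the previous one, and excludes query points from subsequent
neighbourhoods. When a query's neighbourhood contains nothing further,
the chain is a maximal preclass. Duplicate classes are removed by
hashing the sorted member-id tuple. The skip heuristic (on by default)
ignores a start object that was already placed in a class derived from
the same `N(z)`, resetting at each new anchor; it prunes redundant
chains at a possible cost in completeness.

Two properties have different standing:

* **Soundness** (every emitted class is a valid, maximal preclass) is a
  theorem of the construction and is asserted in tests against a direct
  extension scan and against Bron–Kerbosch cliques.
* **Completeness** (every maximal preclass is emitted) is *not*
  guaranteed, with or without the heuristic; `completeness_report`
  measures the gap against `find_classes_exact` (networkx
  Bron–Kerbosch, guarded to ≤ 200 objects) instead of assuming it.

Two fast paths short-circuit the generic loop without changing the
contract: `ε = 0` degenerates to grouping by exact description
equality (byte-wise on the float vectors), and a complete tolerance
graph yields the single whole-set class directly. The chain walk
itself is compiled with numba; the first call in a fresh environment
pays a one-time JIT cost of a few seconds. The implementation is a
single deterministic thread; the recursion of the chaining is realized
iteratively, so no platform recursion limits apply. Memory is
quadratic in the object count (boolean adjacency plus rank matrices),
which is the intended desk-scale envelope of a few thousand objects.

## Measures

`tnm` and `thd` aggregate over one shared class cover of `Z = X ∪ Y`
(by default the chaining cover at the same ε; any cover can be passed
in). The weight normalizer is the total class size `Σ|C|`, counting
every class including one-sided ones. A class wholly inside `X` or `Y`
contributes 0 to tNM's numerator, and — since the Hausdorff distance is
undefined against an empty set — is treated as *maximally distant* in
tHD, contributing `l − l = 0`. This convention was genuinely open; it
was chosen for consistency with tNM's treatment and because it keeps
the normalized tHD inside `[0, 1]`. The per-class Hausdorff distance
is computed with `scipy.spatial.distance.directed_hausdorff` in both
directions; tests check it against a brute-force double loop.

Degenerate behaviour worth knowing: at `ε = 0` every class has zero
internal spread, so `d_H = 0` in every split class and normalized tHD
attains 1 — tHD cannot distinguish sets once classes shrink toward
equivalence classes, which is why tNM is preferred at small ε. The
test-bench asserts the directional claim (tNM's retrieval mAP ≥ tHD's
at ε ≤ 0.05) on the synthetic database.

## Image features

Multiscale edge detection is realized as the gradient of a
Gaussian-smoothed image (Gaussian-derivative filters, default
σ = 1.5 px) followed by non-maximum suppression along the quantized
gradient direction and a magnitude threshold at a percentile of the
nonzero magnitudes (default 70th). These defaults are package choices;
the edge model (locally maximal gradient magnitude in the gradient
direction) is the defining property. Orientation is the gradient angle
in `[0, 2π)`.

The orientation probe averages edge-pixel orientations in each `p × p`
block (default p = 10 px, a required notion with no canonical value)
and normalizes into `[0, 1]`. By default orientations are **folded to
`[0, π)` before averaging**: an edge *line* has no polarity, and the
two gradient senses of one stripe family (θ and θ + π) would otherwise
average to a spurious mid-angle that destroys the feature — folding is
what makes "average orientation of lines" well defined for gratings.
The unfolded `[0, 2π)` mean is available (`fold=False`) for
completeness. The arithmetic mean (the default) remains discontinuous
where orientations straddle the fold boundary at 0/π; a circular
(resultant-vector) mean is available behind `circular=True`, and
`dominant_orientation` provides the axial circular mean, the robust
estimator used when recovering stripe normals near 0°. Blocks with no
edge pixels map to probe value 0.

Masks are inputs, not computed: segmentation is out of scope. A block
is retained when less than half of it is masked out (threshold 0.5,
configurable); cropping to the largest `p`-multiple window is top-left
anchored. RGB is converted to intensity with ITU-R 601 luminance
weights before edge detection. The shipped pipeline uses the single
orientation probe (`l = 1`); the object schema is unchanged for
`l > 1`.

## Retrieval harness

Rankings are by descending measure value with ties broken by ascending
image id. "Retrieved before a miss" counts leading same-category items
before the first other-category item. Tolerance selection sweeps the
grid `{0.01, 0.03, 0.05, 0.07, 0.09, 0.1, 0.2, 0.3}` (configurable)
and scores, per ε, the per-query count of retrievals before precision
drops below a floor (default 90%); the sweep reports the mean count
overall and per category plus the best query, and `best_epsilon` is the
argmax of the overall mean (ties to the smaller ε). One pairwise
matrix is computed per ε and all per-query rankings are read off it.
Matrix self-pairs are *computed*, not assigned: the image's object set
is compared against a relabelled duplicate of itself so the two sides
stay disjoint by id; tNM is exactly 1 there because maximal classes of
a duplicated set always split evenly.

## Synthetic fixtures

`gen_cloud` draws clustered points in `[0, 1]^l` (round-robin cluster
assignment, isotropic Gaussian noise, clipped to the cube) with the
cluster as ground-truth label. `gen_texture_db` renders anti-aliased
sinusoidal gratings — smooth gradients keep edge orientation well
defined, unlike binary stripes — with per-image normal angle drawn
from a small per-category set, random phase, and additive intensity
noise. All randomness flows through `numpy.random.default_rng(seed)`
(PCG64), so regeneration is bit-identical under a fixed seed.

The stock database (`default_texture_spec`) has three categories of 10
images (100 × 100 px, block size 10, so 100 objects per image), normals
at 30°, 90° and 150° with ±5° per-image jitter, period 8 px, noise
σ = 0.02. The category normals are maximally separated on the axial
circle and sit interior to the fold interval, away from the arithmetic
mean's 0/π wrap-around; 10 images per category keeps the all-pairs
sweep (8 ε × 435 pairs) comfortably at desk scale. These sizes are the
package's study conditions, not tuned quantities.

What the generator does *not* emulate: real segmentation masks, hand
anatomy, motion continuity between frames, illumination variation, or
categories that differ in anything other than orientation statistics.
Passing the end-to-end tests therefore shows that the pipeline
separates categories whose edge-orientation distributions differ well
beyond within-category spread — it does not certify performance on
clinical imagery, where feature overlap, segmentation error and
temporal correlation all matter.

## Known limitations

* Chaining completeness is measured, not proven; on some instances the
  exact oracle finds maximal cliques the chaining route misses.
* The arithmetic orientation mean is fragile for stripe normals near
  0° ≡ 180°; use the circular/axial options there.
* Quadratic memory in the number of objects per comparison.
* tHD's empty-side convention (maximally distant) is a package
  decision; other treatments (skipping such classes entirely) would
  rescale the measure.
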