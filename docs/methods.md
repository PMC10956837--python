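# Methods

## Geometry

Three equivalent models of the space of constant curvature −1/β are used,
each where it is strongest. The **Lorentz (hyperboloid) model**
H^{d,β} = {x ∈ R^{d+1} : ⟨x,x⟩_L = −β, x₀ > 0}, with
⟨x,y⟩_L = −x₀y₀ + Σ_{i≥1} x_i y_i, hosts the model's latents because
distance computations there are numerically stable. The **Poincaré ball**
(chart h(x) = (x₁…x_d)/(x₀+1) for β = 1) hosts visualization; its metric
d_P(p,q) = arccosh(1 + 2‖p−q‖²/((1−‖p‖²)(1−‖q‖²))) satisfies
d_P(h(x),h(y)) = arccosh(−⟨x,y⟩_L), an identity the tests enforce to 1e−7.
The **Klein model** exists only to average: the Einstein midpoint is the
γ-weighted Euclidean mean in Klein coordinates (γ_i = 1/√(1−‖k_i‖²)),
converted back to the ball.

The encoder output v ∈ R^d is lifted to the canonical tangent vector
(0, v) at the hyperboloid origin, for which the Lorentz norm equals the
Euclidean norm r = ‖v‖, and mapped by
exp₀(v) = (√β cosh(r/√β), √β sinh(r/√β)·v/r). This is the standard
exponential map written with √⟨v,v⟩_L — the only form whose image satisfies
the manifold constraint, which every output is tested against (|⟨x,x⟩_L+β|
≤ 1e−6). The squared Lorentzian distance d²_L = −2β − 2⟨x,y⟩_L satisfies
all metric axioms except the triangle inequality; it is monotone in d_P,
so rankings agree across the two charts.

Numerical guards: arccosh arguments are clamped to ≥ 1 (exact equality
gives distance 0), conformal denominators (1−‖p‖²) to ≥ 1e−15, and disk
coordinates are projected to radius ≤ 1−1e−5 after every reducer step.
Klein/midpoint/Möbius-addition formulas use the standard gyrovector forms
and are locked by round-trip identities (≤ 1e−9) in the tests. Curvature
is fixed per run (β = 1 by default), not learned.

## Hierarchies and their distances

Leveled hierarchies (5-level ATC-style, 4-level kinome-style, 3-level
NR-style) are stored as root-to-leaf label paths per entity; one entity
may hold several paths (ATC allows it). The dissimilarity of two leaves is
the number of levels between a leaf and their lowest common ancestor:
1 when only the last level differs, up to `depth` when the top level
differs. Three refinements:

* **Catch-all override.** If the LCA is the top-level node of a flagged
  group ("other"/"atypical" in kinome trees), the distance is escalated
  from depth−1 to depth — membership in a catch-all group is not evidence
  of similarity. The override applies only when the LCA *is* that node;
  entities sharing a real family inside the group keep their distance.
* **Duplicate leaves.** Multi-path entities take the minimum distance over
  all path pairs (the most similar placement wins).
* **Floor.** Distinct entities mapped to one identical path get distance 1
  (the matrix keeps 1 ≤ D_ij ≤ depth off the diagonal).

Graph-shaped hierarchies (entities possibly at internal nodes) use
unweighted shortest-path hops instead, with disconnected pairs either an
error or an `inf` sentinel excluded from sampling.

**Regularization sampling.** Anchors are drawn uniformly without
replacement from entities with at least one *positive candidate* — a leaf
sharing a non-root ancestor (LCA distance < depth; for graphs, finite
positive hops). "Uniformly based on the hierarchy distance" is read
distance-first: draw a distance uniformly from those realized among the
anchor's candidates, then a candidate uniformly at that distance; this
keeps rare close relatives from being swamped by abundant distant ones.
Negatives are drawn uniformly without replacement from the leaves strictly
farther than the chosen positive; every batch re-asserts that ordering.
Anchors may repeat across batches (each batch samples independently).

## Model and objective

Both encoders are MLPs (default 1024-1024 hidden ReLU units, 10% dropout
between layers, Xavier-uniform init) over fixed input vectors. The
Euclidean head scores σ(⟨d,t⟩); the hyperbolic head clips latent norms at
α (default 1) — originally a vanishing-gradient guard, kept here because
it stabilizes training — maps through exp₀, and scores exp(−d²_L).
Predictions are clamped to [1e−7, 1−1e−7] before the cross-entropy.

The ranking regularizer per modality is
Σ_i [d(x_i,x_{i+}) + log Σ_{k∈K_i} exp(−d(x_i,x_k))] — the negated
log-ratio form, since the objective is minimized; the denominator excludes
the positive by default (`include_positive` switches to the softmax form).
Inside it, distance is head-matched: squared Lorentzian for the hyperbolic
model, Euclidean distance between raw latents for the dot-product model
(the inner product itself is not a distance). Entities without hierarchy
labels contribute to the interaction loss only. Defaults: 16 epochs,
interaction batches b = 1024, Adam at 5e−5, n = 10 anchors and m = 256
negatives per batch and modality, λ = 0.1 per applied hierarchy (0.5 in
the latent-space-analysis configuration), class weights chosen per
dataset's imbalance (e.g. 2:1 positive:negative for a negatives-heavy
panel, 1:2 for a positives-heavy one).

The training core is a small numpy reverse-mode autodiff engine with an
Adam implementation; analytic gradients of the full pipeline (clip →
exp-map → Lorentz distance → losses) are verified against central finite
differences. Training runs in float32 — the precision deep-learning stacks
use by default, and an order of magnitude faster on CPU BLAS — while all
geometry and metrics outside training run in float64. With a fixed seed
and one thread, losses and weights are bit-reproducible; dropout is active
only during training, so inference is deterministic.

## Evaluation

ROCAUC is the rank statistic, PRAUC the precision–recall step integral
(equivalently, average precision). Cross-validation splits *interactions*,
not entities, into near-equal folds, so every drug and target appears in
training; hierarchy preservation is accordingly evaluated in-sample, over
hierarchy-covered entities only — the question is how well hierarchies can
be encoded, not how they generalize.

Dendrograms come from farthest-point (complete-linkage) agglomerative
clustering of the head-matched latent distance matrix. Exact dendrogram
purity is computed by a merge-accumulation identity (each same-class pair
first meets at a unique merge), pooled over pairs across classes — and
cross-checked in tests against naive pair enumeration. EDP samples up to
k = 10 same-class pairs per class (without replacement; all pairs when
fewer exist), pools across classes, and averages over hierarchy levels;
levels without a same-class pair (e.g. all-singleton leaf levels) are
skipped with a warning. Sampled EDP equals exact purity under exhaustive k
and converges to it as k grows (both tested).

## Disk visualization

The cited disk reducer is re-implemented in simplified form: a
k-nearest-neighbor graph (k = 5, union-symmetrized) over the precomputed
Poincaré distance matrix, Gaussian kernel weights with self-tuning
bandwidths (each point's k-th-neighbor distance), relative-forest-
accessibility similarity (I+L)⁻¹ row-normalized into targets p_ij, and a
2-D disk embedding minimizing KL(p‖q) with q_ij ∝ exp(−d_P(z_i,z_j)) by
mini-batch gradient descent (2000 epochs, batch 64, learning rate 0.05,
projection into the open disk). Acceptance of this component is
property-based — loss decreases, outputs stay in the disk, well-separated
clusters are recovered — not pixel-level reproduction of any particular
figure. Hierarchy trees are drawn bottom-up: each internal node is the
Einstein midpoint of its children, so the root of a well-spread tree lands
near the center; Möbius translation recenters the view on any node without
changing hyperbolic distances.

## Synthetic benchmark

The generator emulates the structure of curated DTI panels so every module
is testable without downloads: a balanced leveled hierarchy per modality,
features from a hierarchical Gaussian (each node inherits its parent's
mean plus an isotropic offset of scale 1.0·0.7^(level−1); leaves add
observation noise of sd 0.5), and a sparse signed interaction matrix whose
positives follow per-(drug top-cluster, target top-cluster) block
probabilities. Defaults describe a nuclear-receptor-style study at desk
scale: 200 drugs on a (4,3,2,2,2) tree, 22 targets on a (4,3,2) tree,
300-d features, 30% of the grid observed, full hierarchy coverage,
checkerboard block affinities of 0.95/0.05.

Two defaults deserve their rationale. Leaf noise at 0.5 (the scale of the
deepest hierarchy offsets) deliberately obscures the deep levels in the
raw features, so an unregularized model does *not* start at the EDP
ceiling and the regularizer's contribution is measurable. Block
affinities are 0.95/0.05 because with Bernoulli labels given blocks the
best achievable held-out ROCAUC is p² + pq (ties split): 0.9/0.1 would cap
it at exactly 0.90, while 0.95/0.05 leaves a 0.95 ceiling — room for a
well-trained model to demonstrate >0.9 discrimination. The 30% observation
rate keeps ≈3k labeled pairs, so the standard 16-epoch/batch-1024 schedule
performs ~64 optimizer steps.

What the generator does **not** emulate: real chemistry (no SMILES, no
structure–activity cliffs), assay noise correlated across rows or columns,
entity-level cold starts, or the extreme sparsity of public panels
(98–99%). Passing tests therefore show that the machinery — geometry,
sampling, losses, metrics — behaves as specified and that regularization
measurably trades nothing for hierarchy preservation under controlled
conditions; they do not certify predictive performance on real compound
panels.

## Limitations

* Encoders are Euclidean; fully hyperbolic layers and Riemannian
  optimizers are out of scope (an explored-and-rejected direction), as are
  learned curvature and log-maps at arbitrary basepoints.
* The Eq-form of the ranking loss excludes the positive from its
  denominator by default; both variants are exposed but only the default
  is exercised by the benchmark.
* The reducer is a simplified re-implementation tuned for small inputs
  (dense (I+L)⁻¹); it is not meant for >10⁴ entities.
* EDP is reported in-sample by design; it says nothing about hierarchy
  generalization to unseen entities.
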