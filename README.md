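# hyperdti

Hierarchy-regularized joint-embedding drug–target interaction (DTI)
prediction, with a comparison between Euclidean and hyperbolic (Lorentz)
latent spaces, full evaluation of both predictive performance and hierarchy
preservation, and Poincaré-disk visualization of the learned space.

## The problem

Pairwise DTI predictors embed compounds and proteins into a shared latent
space where proximity encodes interaction likelihood. Such models predict
well but their latent spaces are hard to interpret. Both modalities,
however, come with curated *a priori* hierarchies — the 5-level ATC drug
classification, the 4-level kinome tree (group/family/subfamily/gene, with
"other"/"atypical" catch-all groups), the 3-level nuclear-receptor
taxonomy, or graph-shaped vocabularies measured in hops. `hyperdti` aligns
the joint latent space to these hierarchies while it learns interactions,
so that nearby embeddings are related both pharmacologically (they
interact) and taxonomically (they are close in the prior tree). Because
trees embed into hyperbolic space with far less distortion than into flat
space, the package implements the latent geometry both ways and lets them
be compared like for like.

## Model

Two feed-forward encoders (two ReLU hidden layers of 1024 units, 10%
dropout, Xavier init) map precomputed feature vectors — e.g. 300-d
Mol2vec/ProtVec embeddings; the package consumes vectors, never raw
SMILES/sequences — to latent vectors **d**, **t** ∈ R^d. Two heads:

* **Euclidean:** p(interact) = σ(⟨**d**, **t**⟩);
* **Hyperbolic:** latents are norm-clipped at α, lifted onto the
  hyperboloid H^{d,β} = {x : ⟨x,x⟩_L = −β, x₀ > 0} by the origin
  exponential map, and scored p = exp(−d²_L(**d**, **t**)) with the squared
  Lorentzian distance d²_L(x,y) = −2β − 2⟨x,y⟩_L.

Training minimizes a class-weighted binary cross-entropy over labeled
interactions plus one ranking regularizer per modality. For each of n
sampled anchors x_i, a positive x_{i+} is drawn among leaves sharing a
non-root ancestor (uniformly over realized LCA distances, then uniformly
within), and up to m negatives from the leaves strictly farther in the
hierarchy; the regularizer

  L_REG = Σ_i [ d(x_i, x_{i+}) + log Σ_{k∈K_i} exp(−d(x_i, x_k)) ]

pushes latent distances into the hierarchy's order. The total loss is
L = L_wBCE + λ^drug·L^drug_REG + λ^target·L^target_REG, optimized by Adam
(16 epochs, interaction batches of 1024, learning rate 5·10⁻⁵ by default).

Evaluation: ROCAUC and PRAUC on held-out interaction folds
(interaction-based k-fold split, so every entity stays in training), and
**expected dendrogram purity (EDP)** of the latent space — complete-linkage
clustering of the latent distance matrix, scored per hierarchy level by the
sampled average, over same-class leaf pairs, of the same-class fraction of
the smallest subtree containing the pair, then averaged over levels.

The `latentviz` module reduces high-dimensional hyperbolic latents to the
2-D Poincaré disk (kNN graph → relative-forest-accessibility similarity →
KL-fit of disk affinities), draws prior hierarchy trees bottom-up via
Einstein midpoints, and navigates the disk with distance-preserving Möbius
translations.

No deep-learning framework is required: the encoders, Adam and
backpropagation run on a small numpy reverse-mode autodiff core that is
gradient-checked against finite differences in the test suite.

## Worked example

`examples/` contains one narrative script per capability. From
`examples/03_train_and_evaluate.py` (a reduced benchmark that runs in
~15 s):

```
1417 labeled pairs, 80 drugs x 22 targets
lambda=0.0: held-out ROCAUC=0.959 PRAUC=0.935 | target-hierarchy EDP=0.516 | final loss=0.167
lambda=0.1: held-out ROCAUC=0.955 PRAUC=0.913 | target-hierarchy EDP=0.867 | final loss=3.387
```

Reading: with hierarchy regularization switched on (λ = 0.1), held-out
interaction prediction is essentially unchanged (ROCAUC 0.955 vs 0.959)
while hierarchy preservation jumps (target EDP 0.52 → 0.87) — the
regularizer reorganizes the latent space around the prior taxonomy at no
predictive cost.

The same pipeline is available as a CLI over TSV files:

```bash
hyperdti simulate --out fixtures --seed 0
hyperdti train    --data fixtures --out runs/model.npz --head lorentz --seed 0
hyperdti evaluate --data fixtures --out runs/report.json --folds 5
hyperdti embed    --checkpoint runs/model.npz --data fixtures --out runs/latents.tsv
hyperdti visualize --checkpoint runs/model.npz --data fixtures --out runs/viz
```

`simulate` writes a complete synthetic study (hierarchies, features whose
similarity tracks hierarchy proximity, block-structured sparse
interactions); the other subcommands accept any dataset directory in the
same TSV layout.

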