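"""Poincaré-disk view of a trained hyperbolic latent space.

Trains a small regularized Lorentz-head model, reduces the target latents
to the 2-D disk, embeds the prior hierarchy tree bottom-up with Einstein
midpoints, and recenters the view on one internal node. Writes
`scratch_disk.png` / `scratch_disk_focus.png` next to this script.
"""

from pathlib import Path

import numpy as np

from hyperdti import evaluation, geometry, hierarchy, latentviz, model, synthdata

cfg = synthdata.SynthConfig(
    branching_drugs=(4, 2, 2, 1, 1), branching_targets=(4, 3, 2),
    n_drugs=60, n_targets=24, feature_dim=80, sparsity=0.2, seed=2,
)
data, drug_tree, target_tree = synthdata.generate_benchmark(cfg)
dd = hierarchy.lca_distance_matrix(drug_tree)
td = hierarchy.lca_distance_matrix(target_tree)
xt = data.target_features.loc[target_tree.entities].to_numpy(float)

m, _ = model.train_model(
    data, dd, td,
    drug_cfg=model.EncoderConfig(data.drug_features.shape[1], hidden=(128, 128), latent_dim=8),
    target_cfg=model.EncoderConfig(xt.shape[1], hidden=(128, 128), latent_dim=8),
    head="lorentz_distance",
    train_cfg=model.TrainingConfig(epochs=16, batch_interactions=256, learning_rate=5e-4,
                                   lambda_drug=0.5, lambda_target=0.5, seed=1),
)

# hyperboloid -> ball chart -> pairwise Poincaré distances -> 2-D disk
ball = geometry.lorentz_to_poincare(m.encode_targets(xt))
D = geometry.poincare_distance(ball[:, None, :], ball[None, :, :])
np.fill_diagonal(D, 0.0)
disk, trace = latentviz.poincare_maps_reduce(
    D, latentviz.ReducerConfig(epochs=500, seed=0), ids=target_tree.entities, kinds=["target"] * len(ball)
)
print(f"reducer KL loss {trace[0]:.3f} -> {trace[-1]:.3f} over {len(trace)} epochs")

withtree = latentviz.embed_tree(disk, target_tree)
root = withtree.coords[withtree.index_of("<root>")]
leaf_norms = np.linalg.norm(disk.coords, axis=1)
print(f"root norm {np.linalg.norm(root):.3f} vs mean leaf norm {leaf_norms.mean():.3f} (root sits near the center)")

here = Path(__file__).parent
labels = {e: target_tree.paths[e][0][0] for e in target_tree.entities}
latentviz.save_disk_plot(withtree, here / "scratch_disk.png", labels=labels, title="target latents by top-level group")

focus = "g1"  # an internal (top-level group) node of the embedded tree
moved = latentviz.translate_view(withtree, focus)
latentviz.save_disk_plot(moved, here / "scratch_disk_focus.png", labels=labels, title=f"recentered on {focus}")
print(f"wrote {here / 'scratch_disk.png'} and {here / 'scratch_disk_focus.png'}")
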