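"""Predictive metrics, dendrograms, and expected dendrogram purity (EDP).

Hierarchy preservation is scored on the merge tree produced by
farthest-point (complete-linkage) agglomerative clustering of the latent
distance matrix. For a pair of same-class leaves, its *purity* is the
fraction of leaves of that class in the smallest subtree containing both;
dendrogram purity averages this over same-class pairs (pooled across
classes), and EDP samples ``k`` pairs per class instead of enumerating all,
then averages the per-level scores over the levels of the prior hierarchy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import average_precision_score, roc_auc_score

from .hierarchy import HierarchyTree, level_labels
from .workbench import InteractionSet

__all__ = [
    "Dendrogram",
    "FoldSplit",
    "binary_aucs",
    "build_dendrogram",
    "dendrogram_purity_exact",
    "expected_dendrogram_purity",
    "crossval_split",
    "latent_edp",
]


def binary_aucs(labels, scores) -> tuple:
    """ROCAUC (rank statistic) and PRAUC (precision-recall step integration).

    ``labels`` may be {0,1} or signed {-1,+1}; both classes must occur.
    """
    y = np.asarray(labels, dtype=float)
    y = (y > 0).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores length mismatch")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to compute AUCs")
    return float(roc_auc_score(y, s)), float(average_precision_score(y, s))


@dataclass
class Dendrogram:
    """Binary agglomerative merge tree over ``leaves``.

    ``Z`` is the standard linkage encoding: row ``i`` merges clusters
    ``Z[i,0]`` and ``Z[i,1]`` (ids ``>= n`` refer to earlier merges) at
    height ``Z[i,2]``.
    """

    leaves: list
    Z: np.ndarray

    def __post_init__(self):
        self.Z = np.asarray(self.Z, dtype=float)
        n = len(self.leaves)
        if self.Z.shape[0] != n - 1:
            raise ValueError("a binary tree over n leaves has exactly n-1 merges")
        if np.any(np.diff(self.Z[:, 2]) < -1e-12):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def merges(self) -> list:
        return [(int(a), int(b), float(h)) for a, b, h, _ in self.Z]

    def _children(self) -> dict:
        n = len(self.leaves)
        return {n + i: (int(a), int(b)) for i, (a, b, _, _) in enumerate(self.Z)}

    def node_leaf_sets(self) -> dict:
        """Leaf-index set of every node (leaves and internal merges)."""
        n = len(self.leaves)
        sets = {i: frozenset([i]) for i in range(n)}
        for i, (a, b, _, _) in enumerate(self.Z):
            sets[n + i] = sets[int(a)] | sets[int(b)]
        return sets

    def parents(self) -> dict:
        n = len(self.leaves)
        par = {}
        for i, (a, b, _, _) in enumerate(self.Z):
            par[int(a)] = n + i
            par[int(b)] = n + i
        return par

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        n = len(self.leaves)
        heights = {i: 0.0 for i in range(n)}
        for i, (_, _, h, _) in enumerate(self.Z):
            heights[n + i] = float(h)
        children = self._children()

        def fmt(node: int) -> str:
            if node < n:
                return str(self.leaves[node])
            a, b = children[node]
            h = heights[node]
            return f"({fmt(a)}:{h - heights[a]:g},{fmt(b)}:{h - heights[b]:g})"

        return fmt(2 * n - 2) + ";"


def build_dendrogram(D, leaves=None) -> Dendrogram:
    """Farthest-point (complete-linkage) agglomerative clustering.

    ``D`` is a symmetric non-negative distance matrix with zero diagonal.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")
    if leaves is None:
        leaves = list(range(D.shape[0]))
    if len(leaves) < 2:
        raise ValueError("need at least two leaves")
    Z = linkage(squareform((D + D.T) / 2.0, checks=False), method="complete")
    return Dendrogram(list(leaves), Z)


def _label_array(T: Dendrogram, labels) -> np.ndarray:
    try:
        out = np.empty(len(T.leaves), dtype=object)
        out[:] = [labels[leaf] for leaf in T.leaves]
        return out
    except KeyError as exc:
        raise ValueError(f"leaf {exc.args[0]!r} has no class label") from None


def dendrogram_purity_exact(T: Dendrogram, labels) -> float:
    """Exact dendrogram purity: average subtree purity over *all* same-class
    leaf pairs, pooled across classes.

    Every pair of same-class leaves first meets at a unique merge node, so
    the sum runs over merges: a merge of subtrees with ``cl`` and ``cr``
    leaves of class ``c`` contributes ``cl*cr`` pairs, each with purity
    ``(cl+cr)/size``. Equals 1 iff every class forms a pure subtree.
    """
    y = _label_array(T, labels)
    n = len(T.leaves)
    counts = {i: {y[i]: 1} for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    num = 0.0
    pairs = 0
    for i, (a, b, _, _) in enumerate(T.Z):
        a, b = int(a), int(b)
        merged = dict(counts[a])
        for c, k in counts[b].items():
            merged[c] = merged.get(c, 0) + k
        size = sizes[a] + sizes[b]
        for c, k in counts[b].items():
            cross = counts[a].get(c, 0) * k
            if cross:
                num += cross * merged[c] / size
                pairs += cross
        counts[n + i], sizes[n + i] = merged, size
        del counts[a], counts[b]
    if pairs == 0:
        raise ValueError("no same-class leaf pair; purity undefined")
    return num / pairs


def _pair_purity(T: Dendrogram, leaf_sets: dict, parents: dict, y: np.ndarray, i: int, j: int) -> float:
    anc = set()
    node = i
    while node in parents:
        anc.add(node)
        node = parents[node]
    anc.add(node)
    node = j
    while node not in anc:
        node = parents[node]
    members = leaf_sets[node]
    same = sum(1 for leaf in members if y[leaf] == y[i])
    return same / len(members)


def expected_dendrogram_purity(T: Dendrogram, levels, k: int = 10, rng=None) -> float:
    """Sampled EDP averaged over hierarchy levels.

    ``levels`` is a sequence of per-level class maps (entity -> label). At
    each level, up to ``k`` same-class pairs per class are drawn without
    replacement (all pairs when fewer exist), their subtree purities are
    pooled across classes, and the final score is the mean over levels.
    Levels without any same-class pair are skipped with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if isinstance(levels, dict):
        levels = [levels]
    leaf_sets = T.node_leaf_sets()
    parents = T.parents()
    scores = []
    for li, labels in enumerate(levels, 1):
        y = _label_array(T, labels)
        purities = []
        for c in sorted(set(y), key=str):
            members = np.flatnonzero([yi == c for yi in y])
            if len(members) < 2:
                continue
            all_pairs = [(int(members[a]), int(members[b])) for a in range(len(members)) for b in range(a + 1, len(members))]
            if len(all_pairs) > k:
                take = rng.choice(len(all_pairs), size=k, replace=False)
                sel = [all_pairs[t] for t in take]
            else:
                sel = all_pairs
            purities.extend(_pair_purity(T, leaf_sets, parents, y, i, j) for i, j in sel)
        if not purities:
            warnings.warn(f"level {li}: no same-class pair; level skipped", stacklevel=2)
            continue
        scores.append(float(np.mean(purities)))
    if not scores:
        raise ValueError("no level had a same-class pair; EDP undefined")
    return float(np.mean(scores))


@dataclass
class FoldSplit:
    """Partition of interaction indices into near-equal folds."""

    folds: list

    def __post_init__(self):
        sizes = [len(f) for f in self.folds]
        if min(sizes) == 0:
            raise ValueError("empty fold")
        if max(sizes) - min(sizes) > 1:
            raise ValueError("folds must be near-equal in size")

    def split(self, i: int) -> tuple:
        """(train_idx, test_idx) for fold ``i``."""
        test = self.folds[i]
        train = np.concatenate([f for j, f in enumerate(self.folds) if j != i])
        return train, test


def crossval_split(data: InteractionSet, k: int, rng=None) -> FoldSplit:
    """Interaction-based k-fold split.

    Interactions (not entities) are partitioned, so every drug and target
    can occur on both sides of the split — the regime in which hierarchy
    preservation is evaluated in-sample while AUCs are held out.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if data.n_interactions < k:
        raise ValueError("fewer interactions than folds")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    perm = rng.permutation(data.n_interactions)
    return FoldSplit([np.sort(f) for f in np.array_split(perm, k)])


def latent_edp(model, data: InteractionSet, tree: HierarchyTree, modality: str, k: int = 10, rng=None) -> float:
    """EDP of a trained model's latent space against a prior hierarchy.

    Encodes the hierarchy-covered entities of ``modality`` (``"drug"`` or
    ``"target"``), clusters their head-matched latent distance matrix with
    complete linkage, and scores the dendrogram against the class labels of
    every hierarchy level.
    """
    if modality not in ("drug", "target"):
        raise ValueError("modality must be 'drug' or 'target'")
    ids = data.drug_ids if modality == "drug" else data.target_ids
    feats = data.drug_features if modality == "drug" else data.target_features
    covered = [e for e in tree.entities if e in set(ids)]
    if len(covered) < 2:
        raise ValueError("need at least two hierarchy-covered entities")
    x = feats.loc[covered].to_numpy(dtype=float)
    z = model.encode_drugs(x) if modality == "drug" else model.encode_targets(x)
    D = model.latent_distance_matrix(z)
    T = build_dendrogram(D, leaves=covered)
    paths = {e: tree.paths[e] for e in covered}
    present = {p[0] for ps in paths.values() for p in ps}
    sub = HierarchyTree(kind=tree.kind, paths=paths, special_groups=tree.special_groups & present)
    levels = [level_labels(sub, lv) for lv in range(1, tree.depth + 1)]
    return expected_dendrogram_purity(T, levels, k=k, rng=rng)
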