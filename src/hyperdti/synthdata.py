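"""Synthetic benchmark generator: hierarchies, features, interactions.

The generator emulates the structure of public DTI benchmarks at desk
scale: a leveled hierarchy over each modality, per-entity feature vectors
whose similarity decays with hierarchy distance (standing in for
Mol2vec/ProtVec-style pre-trained inputs), and a sparse signed interaction
matrix whose positives concentrate on (drug top-cluster, target
top-cluster) blocks. Interaction signal and hierarchy signal are thus both
learnable but distinct, so experiments can separate what the interaction
loss and what the hierarchy regularizer contribute.

Everything is reproducible from ``(SynthConfig, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import prod

import numpy as np
import pandas as pd

from .hierarchy import KIND_DEPTH, HierarchyTree
from .workbench import InteractionSet

__all__ = ["SynthConfig", "gen_hierarchy", "gen_features", "gen_interactions", "generate_benchmark"]


@dataclass
class SynthConfig:
    """Shapes and signal strengths of the synthetic benchmark.

    Defaults are a desk-scale analogue of a nuclear-receptor-style panel:
    200 drugs on a 5-level tree, 22 targets on a 3-level tree,
    300-dimensional features. ``noise_sd`` (leaf-level feature noise, same
    scale as the deepest hierarchy offsets) partially obscures the deep
    hierarchy levels in the raw features; ``sparsity`` = 0.30 leaves about
    3k labeled pairs, enough for the standard 16-epoch/batch-1024 training
    schedule to take on the order of 60 optimizer steps.
    """

    branching_drugs: tuple = (4, 3, 2, 2, 2)
    branching_targets: tuple = (4, 3, 2)
    drug_kind: str = "atc5"
    target_kind: str = "nr3"
    n_drugs: int = 200
    n_targets: int = 22
    feature_dim: int = 300
    noise_sd: float = 0.5
    level_offset_sd: float = 1.0
    level_decay: float = 0.7
    block_affinity: np.ndarray | None = None  # default: 0.95/0.05 checkerboard
    sparsity: float = 0.30
    hierarchy_coverage: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.sparsity < 1.0:
            raise ValueError("sparsity must be in [0, 1)")
        if not 0.0 < self.hierarchy_coverage <= 1.0:
            raise ValueError("hierarchy_coverage must be in (0, 1]")
        if self.block_affinity is not None:
            ba = np.asarray(self.block_affinity, dtype=float)
            if np.any((ba < 0) | (ba > 1)):
                raise ValueError("block affinities must be probabilities")
            self.block_affinity = ba


def gen_hierarchy(
    branching,
    kind: str,
    rng: np.random.Generator,
    n_entities: int | None = None,
    entity_prefix: str = "e",
    special_group: str | None = None,
) -> HierarchyTree:
    """Balanced leveled hierarchy with entities assigned to its leaves.

    ``branching`` gives per-level child counts and must match the depth of
    ``kind``. Entities are spread over leaves as evenly as possible, in
    seeded random order (distinct leaves while they last, then reuse).
    ``special_group`` names the first top-level branch and flags it as a
    catch-all dissimilarity-override group (kinome-style "other").
    """
    branching = tuple(int(b) for b in branching)
    depth = KIND_DEPTH.get(kind)
    if depth is None:
        raise ValueError(f"gen_hierarchy supports leveled kinds, not {kind!r}")
    if len(branching) != depth:
        raise ValueError(f"branching length {len(branching)} != depth {depth} of {kind!r}")
    if any(b < 1 for b in branching):
        raise ValueError("branching factors must be >= 1")
    n_leaves = prod(branching)
    if n_entities is None:
        n_entities = n_leaves

    top_names = [f"g{i}" for i in range(branching[0])]
    if special_group is not None:
        top_names[0] = special_group

    leaf_paths = [()]
    for level, b in enumerate(branching):
        new = []
        for p in leaf_paths:
            for c in range(b):
                label = top_names[c] if level == 0 else f"{p[-1]}.{c}"
                new.append(p + (label,))
        leaf_paths = new

    reps = -(-n_entities // n_leaves)
    pool = np.tile(np.arange(n_leaves), reps)
    order = rng.permutation(len(pool))[:n_entities]
    width = len(str(max(n_entities - 1, 1)))
    paths = {
        f"{entity_prefix}{i:0{width}d}": [leaf_paths[pool[order[i]]]]
        for i in range(n_entities)
    }
    special = frozenset({special_group}) if special_group else frozenset()
    return HierarchyTree(kind=kind, paths=paths, special_groups=special)


def gen_features(
    tree: HierarchyTree,
    feature_dim: int,
    noise_sd: float,
    rng: np.random.Generator,
    level_offset_sd: float = 1.0,
    level_decay: float = 0.7,
) -> pd.DataFrame:
    """Hierarchy-correlated Gaussian features.

    Each tree node inherits its parent's mean plus an isotropic Gaussian
    offset whose scale shrinks geometrically with depth
    (``level_offset_sd * level_decay**(level-1)``); entity features are
    their leaf mean plus ``noise_sd`` observation noise. Entities closer in
    the hierarchy therefore have closer features in expectation.
    """
    means: dict = {(): np.zeros(feature_dim)}
    # visit node prefixes in breadth-first (level) order for a stable walk
    prefixes = sorted(
        {p[:k] for ps in tree.paths.values() for p in ps for k in range(1, len(p) + 1)},
        key=lambda q: (len(q), q),
    )
    for q in prefixes:
        scale = level_offset_sd * level_decay ** (len(q) - 1)
        means[q] = means[q[:-1]] + rng.normal(0.0, scale, size=feature_dim)
    rows = {
        ent: means[tree.paths[ent][0]] + rng.normal(0.0, noise_sd, size=feature_dim)
        for ent in tree.entities
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def _top_cluster_indices(tree: HierarchyTree) -> tuple:
    tops = sorted({p[0] for ps in tree.paths.values() for p in ps})
    lookup = {t: i for i, t in enumerate(tops)}
    return {e: lookup[tree.paths[e][0][0]] for e in tree.entities}, len(tops)


def _checkerboard(n_rows: int, n_cols: int, high: float = 0.95, low: float = 0.05) -> np.ndarray:
    i, j = np.indices((n_rows, n_cols))
    return np.where((i + j) % 2 == 0, high, low)


def gen_interactions(
    drug_tree: HierarchyTree,
    target_tree: HierarchyTree,
    cfg: SynthConfig,
    rng: np.random.Generator,
) -> InteractionSet:
    """Sparse signed interaction matrix with block-structured positives.

    A fraction ``1 - sparsity`` of the drug-by-target grid is observed
    uniformly at random; each observed pair is positive with probability
    ``block_affinity[drug top-cluster, target top-cluster]`` and negative
    otherwise.
    """
    d_top, n_d_top = _top_cluster_indices(drug_tree)
    t_top, n_t_top = _top_cluster_indices(target_tree)
    ba = cfg.block_affinity
    if ba is None:
        ba = _checkerboard(n_d_top, n_t_top)
    if ba.shape != (n_d_top, n_t_top):
        raise ValueError(f"block_affinity shape {ba.shape} != ({n_d_top}, {n_t_top})")
    drugs, targets = drug_tree.entities, target_tree.entities
    nd, nt = len(drugs), len(targets)
    observed = rng.random((nd, nt)) < (1.0 - cfg.sparsity)
    p = ba[
        np.array([d_top[d] for d in drugs])[:, None],
        np.array([t_top[t] for t in targets])[None, :],
    ]
    positive = rng.random((nd, nt)) < p
    pairs = np.argwhere(observed)
    labels = np.where(positive[observed], 1, -1)
    return InteractionSet(list(drugs), list(targets), pairs, labels)


def _prune_coverage(tree: HierarchyTree, coverage: float, rng: np.random.Generator) -> HierarchyTree:
    if coverage >= 1.0:
        return tree
    ents = tree.entities
    keep = max(2, int(round(coverage * len(ents))))
    chosen = set(rng.choice(len(ents), size=keep, replace=False))
    paths = {e: tree.paths[e] for i, e in enumerate(ents) if i in chosen}
    return HierarchyTree(kind=tree.kind, paths=paths, special_groups=tree.special_groups & {p[0] for ps in paths.values() for p in ps})


def generate_benchmark(cfg: SynthConfig | None = None):
    """Full synthetic study: trees, features and interactions.

    Returns ``(interactions, drug_tree, target_tree)`` where the
    interaction set has feature tables attached and the returned trees
    cover only the ``hierarchy_coverage`` fraction of entities (emulating
    datasets where most compounds lack curated hierarchy labels).
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    drug_tree = gen_hierarchy(
        cfg.branching_drugs, cfg.drug_kind, rng, cfg.n_drugs, entity_prefix="d"
    )
    target_tree = gen_hierarchy(
        cfg.branching_targets, cfg.target_kind, rng, cfg.n_targets, entity_prefix="t"
    )
    dfeat = gen_features(
        drug_tree, cfg.feature_dim, cfg.noise_sd, rng, cfg.level_offset_sd, cfg.level_decay
    )
    tfeat = gen_features(
        target_tree, cfg.feature_dim, cfg.noise_sd, rng, cfg.level_offset_sd, cfg.level_decay
    )
    data = gen_interactions(drug_tree, target_tree, cfg, rng)
    data.drug_features = dfeat
    data.target_features = tfeat
    drug_tree = _prune_coverage(drug_tree, cfg.hierarchy_coverage, rng)
    target_tree = _prune_coverage(target_tree, cfg.hierarchy_coverage, rng)
    return data, drug_tree, target_tree
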