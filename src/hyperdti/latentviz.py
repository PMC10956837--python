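"""Two-dimensional Poincaré-disk views of the latent space.

A high-dimensional hyperbolic latent space is reduced to the unit disk in
three steps: (1) a k-nearest-neighbor graph over the precomputed Poincaré
distance matrix with self-tuning Gaussian kernel weights, (2) a
relative-forest-accessibility similarity ``(I + L)^-1`` (L the graph
Laplacian) row-normalized into target affinities ``p_ij``, and (3) a 2-D
disk embedding fit by mini-batch gradient descent on the KL divergence
between ``p`` and disk affinities ``q_ij proportional to exp(-d_P(z_i, z_j))``.
Prior hierarchy trees are then drawn bottom-up: each internal node is the
Einstein midpoint of its children, so roots of well-embedded trees sit near
the disk center. Möbius translation navigates ("zooms into") the view
without distorting hyperbolic distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry
from ._autodiff import Tensor
from .hierarchy import HierarchyTree

__all__ = ["ReducerConfig", "DiskEmbedding", "poincare_maps_reduce", "embed_tree", "translate_view", "save_disk_plot"]

_BOUNDARY = 1.0 - 1e-5


@dataclass
class ReducerConfig:
    """Hyperparameters of the disk reducer (defaults follow the standard
    2000-epoch / batch-64 / lr-0.05 / 5-neighbor setting)."""

    epochs: int = 2000
    batch: int = 64
    learning_rate: float = 0.05
    neighbors: int = 5
    out_dim: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.out_dim != 2:
            raise ValueError("disk embedding is two-dimensional")
        if self.neighbors < 1:
            raise ValueError("neighbors must be >= 1")


@dataclass
class DiskEmbedding:
    """Per-entity 2-D Poincaré-disk coordinates.

    ``kinds[i]`` tags each row (``"drug"``, ``"target"`` or ``"internal"``);
    ``edges`` optionally holds (parent id, child id) pairs of an embedded
    hierarchy tree.
    """

    ids: list
    coords: np.ndarray
    kinds: list | None = None
    edges: list | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.ids), 2):
            raise ValueError("coords must be (n_ids, 2)")
        if np.any(np.sum(self.coords**2, axis=1) >= 1.0):
            raise ValueError("disk coordinates must lie strictly inside the unit disk")
        if self.kinds is None:
            self.kinds = ["entity"] * len(self.ids)

    def index_of(self, node) -> int:
        try:
            return self.ids.index(node)
        except ValueError:
            raise KeyError(f"unknown node {node!r}") from None

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tkind\tx\ty\n")
            for i, k, (x, y) in zip(self.ids, self.kinds, self.coords):
                fh.write(f"{i}\t{k}\t{x:.8f}\t{y:.8f}\n")


def _rfa_targets(D: np.ndarray, neighbors: int) -> np.ndarray:
    """kNN graph -> Gaussian weights -> relative forest accessibility ->
    row-normalized affinity targets with zero diagonal."""
    n = D.shape[0]
    order = np.argsort(D + np.eye(n) * (D.max() + 1.0), axis=1)
    knn = order[:, :neighbors]
    sigma = np.maximum(D[np.arange(n), knn[:, -1]], 1e-12)  # self-tuning bandwidth
    W = np.zeros((n, n))
    for i in range(n):
        for j in knn[i]:
            w = np.exp(-(D[i, j] ** 2) / (sigma[i] * sigma[j]))
            W[i, j] = max(W[i, j], w)  # union symmetrization
            W[j, i] = max(W[j, i], w)
    L = np.diag(W.sum(axis=1)) - W
    R = np.linalg.inv(np.eye(n) + L)
    P = np.maximum(R, 0.0)
    np.fill_diagonal(P, 0.0)
    return P / P.sum(axis=1, keepdims=True)


def _disk_loss(z: Tensor, P: np.ndarray, rows: np.ndarray) -> Tensor:
    """Cross-entropy -sum_j p_ij log q_ij for the given batch rows."""
    n = z.shape[0]
    zb = z[rows]
    # pairwise squared Euclidean distances via the Gram identity
    nz = (z * z).sum(axis=1)
    nb = (zb * zb).sum(axis=1, keepdims=True)
    gram = zb @ _transpose(z)
    sq = nb + nz - 2.0 * gram
    den = (1.0 - nb) * (1.0 - nz)
    arg = (1.0 + 2.0 * sq / den).clamp(lo=1.0 + 1e-9)
    d = arg.acosh()
    mask = np.zeros((len(rows), n))
    mask[np.arange(len(rows)), rows] = -1e9  # exclude j == i from the softmax
    ce = (Tensor(P[rows]) * d).sum() + ((d * -1.0) + Tensor(mask)).logsumexp(axis=1).sum()
    return ce * (1.0 / len(rows))


def _transpose(t: Tensor) -> Tensor:
    out = Tensor._from_op(t.data.T, (t,), lambda g: (g.T,))
    return out


def poincare_maps_reduce(D, cfg: ReducerConfig | None = None, ids=None, kinds=None):
    """Reduce a precomputed Poincaré distance matrix to the 2-D disk.

    Returns ``(DiskEmbedding, loss_trace)`` with one mean KL-loss entry per
    epoch. Deterministic under a fixed ``cfg.seed`` on a single thread; all
    coordinates stay strictly inside the unit disk (projection at radius
    ``1 - 1e-5`` after every step).
    """
    cfg = cfg or ReducerConfig()
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    if ids is None:
        ids = list(range(n))
    P = _rfa_targets(D, min(cfg.neighbors, n - 1))
    rng = np.random.default_rng(cfg.seed)
    z = Tensor(rng.normal(0.0, 1e-3, size=(n, 2)), requires_grad=True)
    trace = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch):
            rows = order[start : start + cfg.batch]
            loss = _disk_loss(z, P, rows)
            z.grad = None
            loss.backward()
            z.data = z.data - cfg.learning_rate * z.grad
            norms = np.linalg.norm(z.data, axis=1, keepdims=True)
            np.multiply(z.data, np.minimum(1.0, _BOUNDARY / np.maximum(norms, 1e-15)), out=z.data)
            losses.append(float(loss.data))
        if not np.all(np.isfinite(losses)):
            raise RuntimeError("disk embedding diverged (non-finite loss)")
        trace.append(float(np.mean(losses)))
    return DiskEmbedding(list(ids), z.data.copy(), list(kinds) if kinds else None), trace


def _tree_nodes(tree: HierarchyTree) -> dict:
    """Children map over path prefixes; entities hang off their first path."""
    children: dict = {}
    for ent in tree.entities:
        p = tree.paths[ent][0]
        children.setdefault(p, set()).add(("entity", ent))
        for k in range(len(p), 0, -1):
            parent, child = p[: k - 1], p[:k]
            children.setdefault(parent, set())
            children[parent].add(("node", child))
    return children


def _node_id(prefix) -> str:
    return "/".join(prefix) if prefix else "<root>"


def embed_tree(disk: DiskEmbedding, tree: HierarchyTree) -> DiskEmbedding:
    """Place hierarchy-tree internal nodes on the disk, bottom-up.

    Each internal node (including the root) is the Einstein midpoint of its
    children's positions; edges connect every node to its parent. All leaf
    entities of ``tree`` must already be embedded.
    """
    if tree.kind == "graph":
        raise ValueError("embed_tree requires a leveled hierarchy")
    children = _tree_nodes(tree)
    pos = {("entity", e): disk.coords[disk.index_of(e)] for e in tree.entities}

    def resolve(node) -> np.ndarray:
        if node in pos:
            return pos[node]
        pts = np.vstack([resolve(c) for c in sorted(children[node[1]])])
        pos[node] = geometry.einstein_midpoint(pts)
        return pos[node]

    for prefix in children:
        resolve(("node", prefix) if prefix else ("node", ()))
    ids, kinds, coords, edges = list(disk.ids), list(disk.kinds), [*disk.coords], disk.edges or []
    edges = list(edges)
    for (kind, key), xy in pos.items():
        if kind == "entity":
            continue
        ids.append(_node_id(key))
        kinds.append("internal")
        coords.append(xy)
    for parent, kids in children.items():
        pid = _node_id(parent)
        for kind, key in kids:
            edges.append((pid, key if kind == "entity" else _node_id(key)))
    return DiskEmbedding(ids, np.vstack(coords), kinds, edges)


def translate_view(disk: DiskEmbedding, focus) -> DiskEmbedding:
    """Möbius-translate the whole view so ``focus`` sits at the center.

    An isometry of the disk: pairwise Poincaré distances are unchanged
    while the neighborhood of ``focus`` is magnified.
    """
    center = disk.coords[disk.index_of(focus)]
    moved = geometry.mobius_translate(disk.coords, center)
    moved = np.clip(moved, -_BOUNDARY, _BOUNDARY)
    norms = np.linalg.norm(moved, axis=1, keepdims=True)
    moved = moved * np.minimum(1.0, _BOUNDARY / np.maximum(norms, 1e-15))
    return DiskEmbedding(list(disk.ids), moved, list(disk.kinds), disk.edges)


def save_disk_plot(disk: DiskEmbedding, path, labels: dict | None = None, title: str = "") -> None:
    """Static disk plot: unit circle, nodes colored by ``labels`` (or kind),
    tree edges drawn as straight segments if present."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.add_patch(plt.Circle((0, 0), 1.0, fill=False, color="black", lw=0.8))
    if disk.edges:
        lookup = {i: xy for i, xy in zip(disk.ids, disk.coords)}
        for a, b in disk.edges:
            if a in lookup and b in lookup:
                ax.plot(*zip(lookup[a], lookup[b]), color="0.8", lw=0.5, zorder=1)
    keys = [labels.get(i, "?") if labels else k for i, k in zip(disk.ids, disk.kinds)]
    for key in sorted(set(map(str, keys))):
        sel = np.array([str(c) == key for c in keys])
        ax.scatter(disk.coords[sel, 0], disk.coords[sel, 1], s=12, label=key, zorder=2)
    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(-1.05, 1.05)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    if len(set(map(str, keys))) <= 12:
        ax.legend(loc="upper right", fontsize=7)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
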