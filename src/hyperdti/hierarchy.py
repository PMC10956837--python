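"""A priori biological hierarchies and their distance matrices.

Supported hierarchy shapes mirror the common drug/target taxonomies:

* ``atc5`` — 5-level drug classification (ATC1 top ... ATC5 leaf); one drug
  may carry several root-to-leaf paths;
* ``kinase4`` — 4-level kinome tree (group / family / subfamily / gene) with
  catch-all groups ("other", "atypical") treated as dissimilarity overrides;
* ``nr3`` — 3-level nuclear-receptor tree (subfamily / group / member);
* ``graph`` — an arbitrary hierarchy given as an edge list (MeSH-style,
  entities may sit at internal nodes), measured by shortest-path hops.

The dissimilarity between two leaves of a leveled hierarchy is the number of
levels between a leaf and the pair's lowest common ancestor (LCA): 1 when
only the last level differs, up to ``depth`` when the top level differs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx

__all__ = [
    "KIND_DEPTH",
    "DEFAULT_SPECIAL_GROUPS",
    "HierarchyTree",
    "HierarchyDistanceMatrix",
    "RegularizationBatch",
    "parse_hierarchy",
    "lca_distance_matrix",
    "hop_distance_matrix",
    "sample_regularization_batch",
    "level_labels",
]

KIND_DEPTH = {"atc5": 5, "kinase4": 4, "nr3": 3}
DEFAULT_SPECIAL_GROUPS = {"kinase4": frozenset({"other", "atypical"})}


@dataclass
class HierarchyTree:
    """A leveled rooted tree (or hierarchy graph) whose leaves are entities.

    ``paths`` maps each entity to one or more root-to-leaf label paths, each
    of length ``depth``; an entity listed with several paths belongs to
    several branches at once (as drugs do in ATC). ``special_groups`` are
    top-level labels whose members are *not* considered similar merely for
    sharing that label.
    """

    kind: str
    paths: dict = field(default_factory=dict)
    special_groups: frozenset = frozenset()
    edges: list | None = None

    def __post_init__(self):
        if self.kind not in (*KIND_DEPTH, "graph"):
            raise ValueError(f"unknown hierarchy kind {self.kind!r}")
        if self.kind == "graph":
            if not self.edges:
                raise ValueError("graph hierarchy requires a non-empty edge list")
            return
        if not self.paths:
            raise ValueError("leveled hierarchy requires entity paths")
        depth = self.depth
        for ent, plist in self.paths.items():
            if not plist:
                raise ValueError(f"entity {ent!r} has no path")
            for p in plist:
                if len(p) != depth:
                    raise ValueError(
                        f"entity {ent!r}: path length {len(p)} != depth {depth}"
                    )
        bad = self.special_groups - {p[0] for ps in self.paths.values() for p in ps}
        if bad:
            raise ValueError(f"special groups not found at level 1: {sorted(bad)}")

    @property
    def depth(self) -> int:
        return 0 if self.kind == "graph" else KIND_DEPTH[self.kind]

    @property
    def entities(self) -> list:
        if self.kind == "graph":
            return sorted({n for e in self.edges for n in e})
        return list(self.paths)


@dataclass
class HierarchyDistanceMatrix:
    """Symmetric entity-by-entity hierarchy dissimilarity matrix.

    For leveled hierarchies entries are LCA level distances in
    ``{1..depth}`` off the diagonal (``depth`` doubling as "related only
    through the root"); for graph hierarchies they are shortest-path hop
    counts, possibly ``inf`` for disconnected pairs.
    """

    entities: list
    D: np.ndarray
    kind: str = "atc5"
    depth: int = 0

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.entities)
        if self.D.shape != (n, n):
            raise ValueError("distance matrix shape does not match entity list")
        if not np.array_equal(self.D, self.D.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.D) != 0):
            raise ValueError("distance matrix diagonal must be zero")

    def index_of(self, entity) -> int:
        try:
            return self.entities.index(entity)
        except ValueError:
            raise KeyError(f"unknown entity {entity!r}") from None

    def subset(self, entities) -> "HierarchyDistanceMatrix":
        idx = [self.index_of(e) for e in entities]
        return HierarchyDistanceMatrix(
            list(entities), self.D[np.ix_(idx, idx)], self.kind, self.depth
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(str(e) for e in self.entities) + "\n")
            for row in self.D:
                fh.write("\t".join(f"{v:g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path, kind: str = "atc5", depth: int = 0) -> "HierarchyDistanceMatrix":
        with open(path) as fh:
            entities = fh.readline().rstrip("\n").split("\t")
            D = np.loadtxt(fh, delimiter="\t", ndmin=2)
        return cls(entities, D, kind, depth)


@dataclass
class RegularizationBatch:
    """Anchor / positive / negatives index triples feeding the ranking loss.

    Indices refer to rows of the distance matrix the batch was drawn from.
    For every anchor, each negative is strictly farther in the hierarchy
    than the anchor's positive.
    """

    anchors: np.ndarray
    positives: np.ndarray
    negatives: list  # one int array per anchor

    def validate(self, D: np.ndarray) -> None:
        for a, p, negs in zip(self.anchors, self.positives, self.negatives):
            if p == a:
                raise ValueError("positive equals anchor")
            if len(negs) and not np.all(D[a, negs] > D[a, p]):
                raise ValueError("negative not farther than positive")


def parse_hierarchy(path, kind: str, special_groups=None) -> HierarchyTree:
    """Read a hierarchy TSV.

    Leveled kinds expect ``entity<TAB>level1<TAB>...<TAB>level_depth`` rows
    (an entity may appear on several rows, one per path); ``graph`` expects
    two-column edge rows. Header-less; blank lines ignored.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            rows.append((ln, line.split("\t")))
    if not rows:
        raise ValueError(f"empty hierarchy file: {path}")
    if kind == "graph":
        edges = []
        for ln, cols in rows:
            if len(cols) != 2:
                raise ValueError(f"{path}:{ln}: edge rows need exactly 2 columns")
            edges.append((cols[0], cols[1]))
        return HierarchyTree(kind="graph", edges=edges)
    if kind not in KIND_DEPTH:
        raise ValueError(f"unknown hierarchy kind {kind!r}")
    depth = KIND_DEPTH[kind]
    paths: dict = {}
    for ln, cols in rows:
        if len(cols) != depth + 1:
            raise ValueError(
                f"{path}:{ln}: expected entity + {depth} levels, got {len(cols)} columns"
            )
        paths.setdefault(cols[0], []).append(tuple(cols[1:]))
    if special_groups is None:
        special_groups = DEFAULT_SPECIAL_GROUPS.get(kind, frozenset())
    present = {p[0] for ps in paths.values() for p in ps}
    return HierarchyTree(
        kind=kind, paths=paths, special_groups=frozenset(special_groups) & present
    )


def _path_pair_distance(p, q, depth: int, special: frozenset) -> int:
    common = 0
    for a, b in zip(p, q):
        if a != b:
            break
        common += 1
    dist = depth - common
    # members of a catch-all top group are not similar for that reason alone
    if common == 1 and p[0] in special:
        dist = depth
    return max(dist, 1)


def lca_distance_matrix(tree: HierarchyTree) -> HierarchyDistanceMatrix:
    """LCA level distances between all entity pairs of a leveled hierarchy.

    Multi-path entities take the minimum over all path pairs (a duplicated
    leaf contributes its most similar placement). If the LCA of a pair is
    the top-level node of a special catch-all group, the distance is
    escalated from ``depth - 1`` to ``depth``. Distinct entities mapped to
    an identical path get the floor distance 1.
    """
    if tree.kind == "graph":
        raise ValueError("lca_distance_matrix requires a leveled hierarchy; use hop_distance_matrix")
    ents = tree.entities
    depth, special = tree.depth, tree.special_groups
    n = len(ents)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = min(
                _path_pair_distance(p, q, depth, special)
                for p in tree.paths[ents[i]]
                for q in tree.paths[ents[j]]
            )
            D[i, j] = D[j, i] = d
    return HierarchyDistanceMatrix(ents, D, tree.kind, depth)


def hop_distance_matrix(tree: HierarchyTree, on_disconnected: str = "error") -> HierarchyDistanceMatrix:
    """Unweighted shortest-path hop counts between entity nodes of a graph
    hierarchy.

    ``on_disconnected``: ``"error"`` raises on any unreachable pair;
    ``"inf"`` records ``inf`` (such pairs are excluded from regularization
    sampling).
    """
    if tree.kind != "graph":
        raise ValueError("hop_distance_matrix requires a graph hierarchy")
    if on_disconnected not in ("error", "inf"):
        raise ValueError("on_disconnected must be 'error' or 'inf'")
    g = nx.Graph(tree.edges)
    ents = tree.entities
    n = len(ents)
    D = np.full((n, n), np.inf)
    for i, src in enumerate(ents):
        lengths = nx.single_source_shortest_path_length(g, src)
        for j, dst in enumerate(ents):
            if dst in lengths:
                D[i, j] = lengths[dst]
    if np.isinf(D).any() and on_disconnected == "error":
        raise ValueError("hierarchy graph has disconnected entity pairs")
    return HierarchyDistanceMatrix(ents, D, "graph", 0)


def _positive_candidates(dist: HierarchyDistanceMatrix, i: int) -> np.ndarray:
    """Leaves sharing a non-root ancestor with ``i`` (finite, below-max distance)."""
    row = dist.D[i]
    if dist.kind == "graph":
        mask = np.isfinite(row) & (row > 0)
    else:
        mask = (row > 0) & (row < dist.depth)
    mask[i] = False
    return np.flatnonzero(mask)


def sample_regularization_batch(
    dist: HierarchyDistanceMatrix, n: int, m: int, rng: np.random.Generator
) -> RegularizationBatch:
    """Draw ``n`` anchors, one positive each, and up to ``m`` negatives each.

    Anchors are drawn uniformly without replacement from entities that have
    at least one positive candidate (a leaf sharing a non-root ancestor).
    The positive is drawn distance-first: uniformly over the hierarchy
    distances realized among the anchor's candidates, then uniformly among
    candidates at the drawn distance — so rare nearby relatives are sampled
    as often as abundant distant ones. Negatives come uniformly without
    replacement from the leaves strictly farther from the anchor than its
    positive.
    """
    if n < 1 or m < 0:
        raise ValueError("need n >= 1 and m >= 0")
    D = dist.D
    eligible = [i for i in range(len(dist.entities)) if len(_positive_candidates(dist, i))]
    if not eligible:
        raise ValueError("no entity has a positive candidate under the hierarchy")
    anchors = rng.choice(eligible, size=min(n, len(eligible)), replace=False)
    positives, negatives = [], []
    for a in anchors:
        cand = _positive_candidates(dist, a)
        dists = np.unique(D[a, cand])
        d_pos = rng.choice(dists)
        pool = cand[D[a, cand] == d_pos]
        pos = int(rng.choice(pool))
        ki = np.flatnonzero(D[a] > d_pos)
        ki = ki[ki != a]
        negs = rng.choice(ki, size=min(m, len(ki)), replace=False) if len(ki) else np.array([], dtype=int)
        positives.append(pos)
        negatives.append(np.sort(negs.astype(int)))
    batch = RegularizationBatch(np.asarray(anchors, dtype=int), np.asarray(positives, dtype=int), negatives)
    batch.validate(D)
    return batch


def level_labels(tree: HierarchyTree, level: int) -> dict:
    """Class label of every entity at hierarchy ``level`` (1 = top).

    The label is the length-``level`` path prefix; multi-path entities use
    their first listed path.
    """
    if tree.kind == "graph":
        raise ValueError("level labels are defined for leveled hierarchies only")
    if not 1 <= level <= tree.depth:
        raise ValueError(f"level must be in 1..{tree.depth}")
    return {e: tree.paths[e][0][:level] for e in tree.entities}
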