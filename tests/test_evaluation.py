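"""Metrics: AUCs vs a concordance oracle, dendrograms vs naive linkage,
purity vs pairwise enumeration, fold splitting."""

import numpy as np
import pytest

from hyperdti import evaluation as ev
from hyperdti.evaluation import Dendrogram


# ------------------------------------------------------------------ AUCs
def test_aucs_on_separated_and_random_scores(rng):
    y = np.array([0] * 50 + [1] * 50)
    s = np.concatenate([rng.uniform(0, 0.4, 50), rng.uniform(0.6, 1, 50)])
    roc, pr = ev.binary_aucs(y, s)
    assert roc == 1.0 and pr == 1.0
    y2 = rng.integers(0, 2, size=4000)
    s2 = rng.uniform(size=4000)
    roc2, _ = ev.binary_aucs(y2, s2)
    assert abs(roc2 - 0.5) < 0.03
    with pytest.raises(ValueError, match="both classes"):
        ev.binary_aucs(np.ones(5), rng.uniform(size=5))


def test_rocauc_matches_concordance_oracle(rng):
    y = rng.integers(0, 2, size=20)
    y[0], y[1] = 0, 1
    s = rng.normal(size=20)
    roc, _ = ev.binary_aucs(y, s)
    pos, neg = s[y == 1], s[y == 0]
    conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    assert roc == pytest.approx(conc / (len(pos) * len(neg)), abs=1e-12)


def test_prauc_matches_step_integration_oracle(rng):
    y = rng.integers(0, 2, size=25)
    y[:2] = [0, 1]
    s = rng.normal(size=25)
    _, pr = ev.binary_aucs(y, s)
    # step integration: sum over descending unique thresholds of dRecall * precision
    order = np.argsort(-s)
    ys = y[order]
    tp = np.cumsum(ys)
    fp = np.cumsum(1 - ys)
    prec = tp / (tp + fp)
    rec = tp / ys.sum()
    expected = prec[0] * rec[0] + np.sum((rec[1:] - rec[:-1]) * prec[1:])
    assert pr == pytest.approx(expected, abs=1e-12)


# ------------------------------------------------------------ dendrogram
def _naive_complete_linkage(D):
    """O(n^3) reference: clusters merge at their maximum pairwise distance."""
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    partitions = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai, a in enumerate(keys):
            for b in keys[ai + 1 :]:
                h = max(D[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or h < best[0]:
                    best = (h, a, b)
        h, a, b = best
        clusters[max(keys) + 1] = clusters.pop(a) + clusters.pop(b)
        partitions.append(frozenset(frozenset(c) for c in clusters.values()))
    return partitions


def _partition_sequence(T):
    n = len(T.leaves)
    clusters = {i: frozenset([i]) for i in range(n)}
    out = []
    for i, (a, b, _, _) in enumerate(T.Z):
        clusters[n + i] = clusters.pop(int(a)) | clusters.pop(int(b))
        out.append(frozenset(clusters.values()))
    return out


def test_build_dendrogram_small_cases():
    D = np.array([[0.0, 2.0], [2.0, 0.0]])
    T = ev.build_dendrogram(D)
    assert len(T.merges) == 1 and T.merges[0][2] == 2.0
    # two tight pairs merge before the pairs merge with each other
    D4 = np.array(
        [[0, 0.1, 5, 5], [0.1, 0, 5, 5], [5, 5, 0, 0.2], [5, 5, 0.2, 0]], dtype=float
    )
    T4 = ev.build_dendrogram(D4)
    parts = _partition_sequence(T4)
    assert frozenset({frozenset({0, 1}), frozenset({2, 3})}) == parts[1]
    assert np.all(np.diff(T4.Z[:, 2]) >= 0)
    with pytest.raises(ValueError, match="symmetric"):
        ev.build_dendrogram(np.array([[0, 1], [2, 0.0]]))
    with pytest.raises(ValueError, match="non-negative"):
        ev.build_dendrogram(np.array([[0, -1], [-1, 0.0]]))


def test_build_dendrogram_matches_naive_linkage(rng):
    for n in (5, 9, 15):
        X = rng.normal(size=(n, 3))
        D = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
        T = ev.build_dendrogram(D)
        assert _partition_sequence(T) == _naive_complete_linkage(D)


def test_newick_export_parses(rng):
    import io

    from Bio import Phylo

    X = rng.normal(size=(6, 2))
    D = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
    T = ev.build_dendrogram(D, leaves=[f"leaf{i}" for i in range(6)])
    tree = Phylo.read(io.StringIO(T.to_newick()), "newick")
    assert sorted(t.name for t in tree.get_terminals()) == sorted(T.leaves)


# ---------------------------------------------------------------- purity
def _oracle_purity(T, labels):
    """Naive oracle: enumerate same-class pairs, walk up to the LCA."""
    parents = T.parents()
    leaf_sets = T.node_leaf_sets()
    y = [labels[leaf] for leaf in T.leaves]
    vals = []
    for i in range(len(y)):
        for j in range(i + 1, len(y)):
            if y[i] != y[j]:
                continue
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
            vals.append(sum(1 for m in members if y[m] == y[i]) / len(members))
    return float(np.mean(vals))


def _random_dendrogram(rng, n):
    X = rng.normal(size=(n, 2))
    D = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
    return ev.build_dendrogram(D)


def test_purity_hand_example():
    # 4 leaves, classes A,A,B,B on tree ((a1,b1),(a2,b2)): every pair meets at the root
    Z = np.array([[0, 2, 1.0, 2], [1, 3, 1.0, 2], [4, 5, 2.0, 4]])
    T = Dendrogram(["a1", "a2", "b1", "b2"], Z)
    labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    assert ev.dendrogram_purity_exact(T, labels) == pytest.approx(0.5)


def test_purity_pure_subtrees_score_one(rng):
    Z = np.array([[0, 1, 1.0, 2], [2, 3, 1.0, 2], [4, 5, 3.0, 4]])
    T = Dendrogram(["a1", "a2", "b1", "b2"], Z)
    labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    assert ev.dendrogram_purity_exact(T, labels) == 1.0
    # invariant to renaming classes
    renamed = {k: {"A": "X", "B": "Y"}[v] for k, v in labels.items()}
    assert ev.dendrogram_purity_exact(T, renamed) == 1.0


def test_purity_matches_pairwise_oracle(rng):
    for n in (4, 6, 8, 12):
        for _ in range(5):
            T = _random_dendrogram(rng, n)
            labels = {i: int(c) for i, c in enumerate(rng.integers(0, 3, size=n))}
            if len({v for v in labels.values()}) == n:
                continue
            try:
                exact = ev.dendrogram_purity_exact(T, labels)
            except ValueError:
                continue
            assert exact == pytest.approx(_oracle_purity(T, labels), abs=1e-12)


def test_purity_requires_a_same_class_pair():
    Z = np.array([[0, 1, 1.0, 2]])
    with pytest.raises(ValueError, match="purity undefined"):
        ev.dendrogram_purity_exact(Dendrogram(["x", "y"], Z), {"x": 0, "y": 1})


# ------------------------------------------------------------------- EDP
def test_edp_exhaustive_k_equals_exact(rng):
    for n in (4, 6, 8):
        for _ in range(8):
            T = _random_dendrogram(rng, n)
            labels = {i: int(c) for i, c in enumerate(rng.integers(0, 2, size=n))}
            if len(set(labels.values())) < 2 or min(
                sum(1 for v in labels.values() if v == c) for c in set(labels.values())
            ) < 1:
                continue
            try:
                exact = ev.dendrogram_purity_exact(T, labels)
            except ValueError:
                continue
            edp = ev.expected_dendrogram_purity(T, [labels], k=1000, rng=0)
            assert edp == pytest.approx(exact, abs=1e-12)


def test_edp_pure_subtree_levels_score_one(rng):
    # leaves grouped 4+4 with huge between-group distance: both levels pure
    X = np.vstack([rng.normal(0, 0.1, (4, 2)), rng.normal(10, 0.1, (4, 2))])
    D = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
    T = ev.build_dendrogram(D)
    l1 = {i: i // 4 for i in range(8)}
    assert ev.expected_dendrogram_purity(T, [l1], k=100, rng=0) == pytest.approx(1.0)


def test_edp_sampling_converges_to_exact(rng):
    T = _random_dendrogram(rng, 20)
    labels = {i: int(c) for i, c in enumerate(rng.integers(0, 3, size=20))}
    exact = ev.dendrogram_purity_exact(T, labels)
    edp = ev.expected_dendrogram_purity(T, [labels], k=200, rng=1)
    assert abs(edp - exact) < 0.05


def test_edp_seeded_and_level_averaged(rng):
    T = _random_dendrogram(rng, 12)
    l1 = {i: i // 6 for i in range(12)}
    l2 = {i: i // 3 for i in range(12)}
    a = ev.expected_dendrogram_purity(T, [l1, l2], k=3, rng=42)
    b = ev.expected_dendrogram_purity(T, [l1, l2], k=3, rng=42)
    assert a == b
    s1 = ev.expected_dendrogram_purity(T, [l1], k=1000, rng=0)
    s2 = ev.expected_dendrogram_purity(T, [l2], k=1000, rng=0)
    both = ev.expected_dendrogram_purity(T, [l1, l2], k=1000, rng=0)
    assert both == pytest.approx((s1 + s2) / 2, abs=1e-12)


def test_edp_skips_pairless_levels():
    Z = np.array([[0, 1, 1.0, 2], [2, 3, 2.0, 3]])
    T = Dendrogram(["a", "b", "c"], Z)
    lv_ok = {"a": 0, "b": 0, "c": 1}
    lv_single = {"a": 0, "b": 1, "c": 2}
    with pytest.warns(UserWarning, match="level skipped"):
        v = ev.expected_dendrogram_purity(T, [lv_ok, lv_single], k=10, rng=0)
    assert v == ev.expected_dendrogram_purity(T, [lv_ok], k=10, rng=0)


# ------------------------------------------------------------ fold split
def test_crossval_split_partitions(small_benchmark, rng):
    data = small_benchmark[0]
    split = ev.crossval_split(data, 5, rng)
    allidx = np.sort(np.concatenate(split.folds))
    np.testing.assert_array_equal(allidx, np.arange(data.n_interactions))
    sizes = [len(f) for f in split.folds]
    assert max(sizes) - min(sizes) <= 1
    tr, te = split.split(2)
    assert set(tr) | set(te) == set(range(data.n_interactions))
    assert not set(tr) & set(te)


def test_crossval_split_ten_by_five_and_reproducible():
    from hyperdti.workbench import InteractionSet

    pairs = [[i, 0] for i in range(10)]
    data = InteractionSet([f"d{i}" for i in range(10)], ["t0"], np.array(pairs), np.ones(10, dtype=int))
    s1 = ev.crossval_split(data, 5, np.random.default_rng(3))
    s2 = ev.crossval_split(data, 5, np.random.default_rng(3))
    assert all(len(f) == 2 for f in s1.folds)
    for a, b in zip(s1.folds, s2.folds):
        np.testing.assert_array_equal(a, b)
    with pytest.raises(ValueError, match="fewer interactions"):
        ev.crossval_split(data, 11, np.random.default_rng(0))
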