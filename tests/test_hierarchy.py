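"""Hierarchies: parsing, LCA distances vs an independent oracle, sampling."""

import numpy as np
import networkx as nx
import pytest

from hyperdti import hierarchy as hi
from hyperdti.workbench import write_hierarchy_tsv


def toy_atc(paths, special=frozenset()):
    return hi.HierarchyTree(kind="atc5", paths=paths, special_groups=special)


# ---------------------------------------------------------------- parsing
def test_parse_leveled_hierarchy_round_trip(tmp_path):
    tree = toy_atc(
        {
            "d1": [("A", "A.1", "A.1.1", "A.1.1.1", "A.1.1.1.1")],
            "d2": [
                ("A", "A.1", "A.1.1", "A.1.1.1", "A.1.1.1.2"),
                ("B", "B.1", "B.1.1", "B.1.1.1", "B.1.1.1.1"),
            ],
            "d3": [("B", "B.2", "B.2.1", "B.2.1.1", "B.2.1.1.1")],
        }
    )
    f = tmp_path / "h.tsv"
    write_hierarchy_tsv(tree, f)
    back = hi.parse_hierarchy(f, "atc5")
    assert back.depth == 5
    assert back.paths == tree.paths  # duplicate paths retained
    assert len(back.paths["d2"]) == 2


def test_parse_rejects_wrong_path_length(tmp_path):
    f = tmp_path / "bad.tsv"
    f.write_text("d1\ta\tb\tc\td\n")  # 4 levels in an atc5 file
    with pytest.raises(ValueError, match="expected entity \\+ 5 levels"):
        hi.parse_hierarchy(f, "atc5")
    (tmp_path / "empty.tsv").write_text("\n")
    with pytest.raises(ValueError, match="empty"):
        hi.parse_hierarchy(tmp_path / "empty.tsv", "atc5")
    with pytest.raises(ValueError, match="unknown hierarchy kind"):
        hi.parse_hierarchy(f, "atc7")


def test_parse_graph_hierarchy(tmp_path):
    f = tmp_path / "g.tsv"
    f.write_text("root\ta\nroot\tb\na\tc\n")
    tree = hi.parse_hierarchy(f, "graph")
    assert tree.kind == "graph" and len(tree.edges) == 3


# ------------------------------------------------------------- LCA matrix
def test_lca_distance_printed_ranges():
    tree = toy_atc(
        {
            "same4": [("A", "A.1", "A.1.1", "A.1.1.1", "x")],
            "same4b": [("A", "A.1", "A.1.1", "A.1.1.1", "y")],
            "othertop": [("B", "B.1", "B.1.1", "B.1.1.1", "z")],
        }
    )
    dm = hi.lca_distance_matrix(tree)
    i, j, k = (dm.index_of(e) for e in ("same4", "same4b", "othertop"))
    assert dm.D[i, j] == 1  # only the leaf level differs
    assert dm.D[i, k] == 5  # different top level
    assert np.all(np.diag(dm.D) == 0)


def test_kinase_special_group_override():
    paths = {
        "k1": [("other", "f1", "s1", "k1")],
        "k2": [("other", "f2", "s2", "k2")],
        "k3": [("other", "f1", "s1b", "k3")],
        "k4": [("TK", "f3", "s3", "k4")],
        "k5": [("TK", "f4", "s4", "k5")],
    }
    tree = hi.HierarchyTree(kind="kinase4", paths=paths, special_groups=frozenset({"other"}))
    dm = hi.lca_distance_matrix(tree)
    d = {e: dm.index_of(e) for e in paths}
    assert dm.D[d["k1"], d["k2"]] == 4  # LCA is the 'other' node: 4, not 3
    assert dm.D[d["k1"], d["k3"]] == 2  # same family inside 'other': no override
    assert dm.D[d["k4"], d["k5"]] == 3  # regular group keeps distance 3


def _oracle_lca_distance(tree):
    """Independent oracle: build the explicit node graph and take, per path
    pair, depth minus the deepest common node on the two root paths."""
    depth = tree.depth
    out = {}
    ents = tree.entities
    for i, a in enumerate(ents):
        for b in ents[i + 1 :]:
            best = None
            for p in tree.paths[a]:
                for q in tree.paths[b]:
                    nodes_p = [p[:k] for k in range(depth + 1)]
                    nodes_q = {q[:k] for k in range(depth + 1)}
                    common = [x for x in nodes_p if x in nodes_q]
                    lca = max(common, key=len)
                    d = depth - len(lca)
                    if len(lca) == 1 and lca[0] in tree.special_groups:
                        d = depth
                    d = max(d, 1)
                    best = d if best is None else min(best, d)
            out[(a, b)] = best
    return out


@pytest.mark.parametrize("kind", ["atc5", "kinase4", "nr3"])
def test_lca_matrix_matches_bruteforce_oracle(kind, rng):
    depth = hi.KIND_DEPTH[kind]
    for trial in range(12):
        n = int(rng.integers(4, 30))
        paths = {}
        tops = [f"g{t}" for t in range(int(rng.integers(2, 4)))]
        special = frozenset({tops[0]}) if kind == "kinase4" and trial % 2 else frozenset()
        for e in range(n):
            n_paths = 2 if rng.random() < 0.3 else 1
            plist = []
            for _ in range(n_paths):
                p = [tops[rng.integers(0, len(tops))]]
                for lv in range(1, depth):
                    p.append(f"{p[-1]}.{rng.integers(0, 2)}")
                plist.append(tuple(p))
            paths[f"e{e}"] = plist
        tree = hi.HierarchyTree(kind=kind, paths=paths, special_groups=special)
        dm = hi.lca_distance_matrix(tree)
        oracle = _oracle_lca_distance(tree)
        for (a, b), d in oracle.items():
            assert dm.D[dm.index_of(a), dm.index_of(b)] == d


def test_lca_matrix_invariant_to_entity_order():
    paths = {
        "a": [("g0", "g0.0", "g0.0.0")],
        "b": [("g0", "g0.1", "g0.1.0")],
        "c": [("g1", "g1.0", "g1.0.0")],
    }
    t1 = hi.HierarchyTree(kind="nr3", paths=paths)
    t2 = hi.HierarchyTree(kind="nr3", paths={k: paths[k] for k in ["c", "a", "b"]})
    d1, d2 = hi.lca_distance_matrix(t1), hi.lca_distance_matrix(t2)
    for x in paths:
        for y in paths:
            assert d1.D[d1.index_of(x), d1.index_of(y)] == d2.D[d2.index_of(x), d2.index_of(y)]
    with pytest.raises(ValueError, match="leveled"):
        hi.lca_distance_matrix(hi.HierarchyTree(kind="graph", edges=[("a", "b")]))


# ------------------------------------------------------------ hop matrix
def test_hop_distances_match_bfs():
    tree = hi.HierarchyTree(kind="graph", edges=[("a", "b"), ("b", "c"), ("c", "d")])
    dm = hi.hop_distance_matrix(tree)
    g = nx.Graph(tree.edges)
    for x in dm.entities:
        for y in dm.entities:
            assert dm.D[dm.index_of(x), dm.index_of(y)] == nx.shortest_path_length(g, x, y)
    assert dm.D[dm.index_of("a"), dm.index_of("d")] == 3
    assert dm.D[dm.index_of("a"), dm.index_of("b")] == 1
    assert dm.D[dm.index_of("a"), dm.index_of("a")] == 0


def test_hop_distance_disconnected_handling():
    tree = hi.HierarchyTree(kind="graph", edges=[("a", "b"), ("c", "d")])
    with pytest.raises(ValueError, match="disconnected"):
        hi.hop_distance_matrix(tree)
    dm = hi.hop_distance_matrix(tree, on_disconnected="inf")
    assert np.isinf(dm.D[dm.index_of("a"), dm.index_of("c")])
    # disconnected entities are still usable for sampling (inf pairs excluded)
    batch = hi.sample_regularization_batch(dm, n=4, m=3, rng=np.random.default_rng(0))
    batch.validate(dm.D)


# --------------------------------------------------------------- sampler
def nr3_fixture():
    paths = {}
    for g in range(3):
        for f in range(2):
            for leaf in range(2):
                paths[f"e{g}{f}{leaf}"] = [(f"g{g}", f"g{g}.{f}", f"g{g}.{f}.{leaf}")]
    return hi.lca_distance_matrix(hi.HierarchyTree(kind="nr3", paths=paths))


def test_sampler_negatives_strictly_farther(rng):
    dm = nr3_fixture()
    for _ in range(20):
        batch = hi.sample_regularization_batch(dm, n=5, m=4, rng=rng)
        batch.validate(dm.D)
        for a, p, negs in zip(batch.anchors, batch.positives, batch.negatives):
            assert np.all(dm.D[a, negs] > dm.D[a, p])
            assert p != a


def test_sampler_excludes_root_only_anchors(rng):
    # 'lone' shares only the root with everyone: never anchor/positive/negative-source
    paths = {
        "a": [("g0", "g0.0", "g0.0.0")],
        "b": [("g0", "g0.0", "g0.0.1")],
        "lone": [("g9", "g9.0", "g9.0.0")],
    }
    dm = hi.lca_distance_matrix(hi.HierarchyTree(kind="nr3", paths=paths))
    lone = dm.index_of("lone")
    for _ in range(20):
        batch = hi.sample_regularization_batch(dm, n=3, m=2, rng=rng)
        assert lone not in batch.anchors
        assert lone not in batch.positives
    only_lone = dm.subset(["lone"])
    with pytest.raises(ValueError, match="no entity has a positive candidate"):
        hi.sample_regularization_batch(only_lone, n=1, m=1, rng=rng)


def test_sampler_positive_distance_rule(rng):
    """When the positive is at distance d, negatives all sit beyond d."""
    dm = nr3_fixture()
    seen_far_negatives = False
    for _ in range(50):
        b = hi.sample_regularization_batch(dm, n=2, m=8, rng=rng)
        for a, p, negs in zip(b.anchors, b.positives, b.negatives):
            dpos = dm.D[a, p]
            assert dpos < dm.depth  # positives share a non-root ancestor
            if dpos == 2:
                # then K_i is exactly the distance-3 leaves
                assert set(np.unique(dm.D[a, negs])) <= {3.0}
                seen_far_negatives = True
    assert seen_far_negatives


def test_sampler_deterministic_under_seed():
    dm = nr3_fixture()
    b1 = hi.sample_regularization_batch(dm, 4, 3, np.random.default_rng(9))
    b2 = hi.sample_regularization_batch(dm, 4, 3, np.random.default_rng(9))
    np.testing.assert_array_equal(b1.anchors, b2.anchors)
    np.testing.assert_array_equal(b1.positives, b2.positives)
    for x, y in zip(b1.negatives, b2.negatives):
        np.testing.assert_array_equal(x, y)


def test_distance_matrix_tsv_round_trip(tmp_path):
    dm = nr3_fixture()
    f = tmp_path / "d.tsv"
    dm.to_tsv(f)
    back = hi.HierarchyDistanceMatrix.from_tsv(f, dm.kind, dm.depth)
    assert back.entities == dm.entities
    np.testing.assert_array_equal(back.D, dm.D)
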