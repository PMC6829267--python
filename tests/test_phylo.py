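"""Neighbor joining, distances, bootstrap and Newick round-trips,
cross-checked against dendropy."""

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from cbfsurvey import phylo, synthetic_data as sd
from cbfsurvey.phylo import (
    DistanceMatrix,
    bootstrap,
    neighbor_joining,
    pairwise_columns,
    pairwise_distance,
    write_newick,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def rf_distance(nwk_a: str, nwk_b: str) -> int:
    ns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=nwk_a, schema="newick", taxon_namespace=ns)
    tb = dendropy.Tree.get(data=nwk_b, schema="newick", taxon_namespace=ns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return treecompare.symmetric_difference(ta, tb)


def test_distance_matrix_validation():
    with pytest.raises(ValueError):
        DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError):
        DistanceMatrix(("a", "b"), np.array([[0.0, -1.0], [-1.0, 0.0]]))


def test_pairwise_distance_identical_and_counted():
    seqs = [("a", "MKVLAWERTY"), ("b", "MKVLAWERTY"), ("c", "MKVLAWERTA")]
    dm = pairwise_distance(seqs, aligned=True)
    assert dm.d[0, 1] == 0.0
    # c differs from a at 1 of 10 positions
    assert dm.d[0, 2] == pytest.approx(0.1)


def test_pairwise_distance_two_of_ten():
    seqs = [("a", "AAAAAAAAAA"), ("b", "AAAAAAAACC"), ("c", "GGGGGGGGGG")]
    dm = pairwise_distance(seqs, aligned=True)
    assert dm.d[0, 1] == pytest.approx(0.2)


def test_pairwise_distance_matches_per_pair_oracle(rng):
    seqs = [
        (f"s{i}", "".join(rng.choice(list("ACGT"), size=60))) for i in range(5)
    ]
    dm = pairwise_distance(seqs, aligned=True)
    for i in range(5):
        for j in range(i + 1, 5):
            expected = np.mean(
                [a != b for a, b in zip(seqs[i][1], seqs[j][1])]
            )
            assert dm.d[i, j] == pytest.approx(expected)


def test_nw_alignment_distance_zero_for_identical_proteins():
    seqs = [("a", "MKVLAWER" * 5), ("b", "MKVLAWER" * 5), ("c", "MKVIAWER" * 5)]
    dm = pairwise_distance(seqs)  # unaligned path: NW + p-distance
    assert dm.d[0, 1] == 0.0
    assert 0 < dm.d[0, 2] <= 0.2


def test_nj_three_taxa_closed_form():
    d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
    tree = neighbor_joining(DistanceMatrix(("A", "B", "C"), d))
    lengths = {c.name: bl for c, bl in tree.root.children}
    assert lengths["A"] == pytest.approx((5 + 9 - 10) / 2)
    assert lengths["B"] == pytest.approx((5 + 10 - 9) / 2)
    assert lengths["C"] == pytest.approx((9 + 10 - 5) / 2)


@pytest.mark.parametrize("n_taxa", [4, 5, 6, 8])
def test_nj_recovers_additive_matrices_exactly(n_taxa):
    rng = np.random.default_rng(n_taxa)
    for _ in range(10):
        nwk = sd.random_tree(n_taxa, rng)
        taxa, d = sd.additive_matrix(nwk)
        tree = neighbor_joining(DistanceMatrix(taxa, d))
        # branch lengths: path-length matrix reproduces the input
        pl = tree.path_length_matrix()
        assert np.abs(pl.d - d).max() < 1e-9
        # topology: RF distance 0 against the generating tree
        assert rf_distance(write_newick(tree), nwk) == 0


def test_nj_requires_three_taxa():
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(("a", "b"), np.zeros((2, 2))))


def test_nj_on_evolved_sequences_recovers_topology():
    nwk = "((t1:0.1,t2:0.1):0.08,(t3:0.1,t4:0.1):0.08,(t5:0.1,t6:0.15):0.05);"
    hits = 0
    for seed in range(20):
        leaves = sd.evolve(nwk, rate=1.0, seed=seed, n_sites=1000)
        tree = phylo.build_tree(sorted(leaves.items()), aligned=True)
        if rf_distance(write_newick(tree), nwk) == 0:
            hits += 1
    assert hits >= 19  # >= 95 % recovery at this rate and length


def test_bootstrap_congruent_columns_give_full_support():
    # every column supports the same split -> every resample agrees
    seqs = [("a", "AAAA"), ("b", "AAAA"), ("c", "CCCC"), ("d", "CCCC"), ("e", "GGGG")]
    cols = pairwise_columns(seqs, aligned=True)
    _, support = bootstrap(cols, reps=50, seed=1)
    assert support and all(v == 100 for v in support.values())


def test_bootstrap_single_rep_is_zero_or_hundred():
    rng = np.random.default_rng(0)
    seqs = [(f"t{i}", "".join(rng.choice(list("ACGT"), size=100))) for i in range(5)]
    cols = pairwise_columns(seqs, aligned=True)
    _, support = bootstrap(cols, reps=1, seed=3)
    assert set(support.values()) <= {0, 100}


def test_bootstrap_deterministic_under_seed():
    nwk = "((t1:0.1,t2:0.1):0.05,(t3:0.1,t4:0.1):0.05,t5:0.2);"
    leaves = sd.evolve(nwk, rate=0.8, seed=11, n_sites=300)
    cols = pairwise_columns(sorted(leaves.items()), aligned=True)
    _, s1 = bootstrap(cols, reps=100, seed=77)
    _, s2 = bootstrap(cols, reps=100, seed=77)
    assert s1 == s2


def test_bootstrap_rejects_zero_reps():
    seqs = [("a", "AC"), ("b", "AG"), ("c", "GG")]
    cols = pairwise_columns(seqs, aligned=True)
    with pytest.raises(ValueError):
        bootstrap(cols, reps=0, seed=1)


def test_newick_three_leaf_star():
    d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
    tree = neighbor_joining(DistanceMatrix(("A", "B", "C"), d))
    nwk = write_newick(tree)
    assert nwk.startswith("(") and nwk.endswith(");")
    parsed = dendropy.Tree.get(data=nwk, schema="newick")
    assert {t.label for t in parsed.taxon_namespace} == {"A", "B", "C"}


def test_newick_round_trip_preserves_lengths_and_supports(rng):
    nwk = sd.random_tree(6, rng)
    leaves = sd.evolve(nwk, rate=0.8, seed=5, n_sites=400)
    cols = pairwise_columns(sorted(leaves.items()), aligned=True)
    tree, support = bootstrap(cols, reps=20, seed=2)
    out = write_newick(tree)
    parsed = dendropy.Tree.get(data=out, schema="newick")
    # branch lengths survive the round trip
    expected = sorted(
        round(bl, 9)
        for node, bl in _all_edges(tree.root)
    )
    got = sorted(
        round(e.length, 9) for e in parsed.edges() if e.length is not None
    )
    assert got == expected
    # supports serialized as integers 0-100 on internal nodes
    labels = [
        int(n.label) for n in parsed.internal_nodes() if n.label is not None
    ]
    assert sorted(labels) == sorted(support.values())


def _all_edges(node):
    for child, bl in node.children:
        yield child, bl
        yield from _all_edges(child)


def test_two_clade_separation_recovered():
    # two diverged groups -> the tree contains the group bipartition
    rng = np.random.default_rng(42)
    root = "".join(rng.choice(list("ACGT"), size=500))
    nwk = "((a1:0.05,(a2:0.05,a3:0.05):0.03):0.4,(b1:0.05,b2:0.05):0.4,b3:0.45);"
    leaves = sd.evolve(nwk, rate=1.0, seed=9, n_sites=500, root_seq=root)
    tree = phylo.build_tree(sorted(leaves.items()), aligned=True)
    splits = phylo.bipartitions(tree)
    group_a = frozenset({"a1", "a2", "a3"})
    group_b = frozenset({"b1", "b2", "b3"})
    assert group_a in splits or group_b in splits


def test_path_length_matrix_nonnegative(genome_fixture, rng):
    nwk = sd.random_tree(7, rng)
    taxa, d = sd.additive_matrix(nwk)
    tree = neighbor_joining(DistanceMatrix(taxa, d))
    assert (tree.path_length_matrix().d >= 0).all()
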