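"""Alignment DP, distance models, neighbor joining and bootstrap."""

import itertools
import math
import random

import numpy as np
import pytest

from pncc.conservation import Alignment
from pncc.phylo import (
    DistanceMatrix,
    PhyloTree,
    blosum62,
    bootstrap_support,
    distance_matrix,
    neighbor_joining,
    pairwise_align,
)

AA = sorted("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# Pairwise alignment
# ---------------------------------------------------------------------------

def brute_force_global_score(a, b, matrix, go, ge):
    """Enumerate every monotone alignment path with affine gap accounting."""
    first = go + ge
    best = [-math.inf]

    def rec(i, j, score, last):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = matrix.get((a[i], b[j]), matrix.get((b[j], a[i]), -4.0))
            rec(i + 1, j + 1, score + s, "M")
        if i < len(a):
            cost = ge if last == "X" else first
            rec(i + 1, j, score - cost, "X")
        if j < len(b):
            cost = ge if last == "Y" else first
            rec(i, j + 1, score - cost, "Y")

    rec(0, 0, 0.0, "start")
    return best[0]


class TestPairwiseAlign:
    def test_self_alignment_identity_one(self):
        r = pairwise_align("ACDE", "ACDE")
        assert r.identity == 1.0

    def test_single_substitution_identity(self):
        r = pairwise_align("ACDE", "ACDF", mode="global")
        assert r.identity == pytest.approx(0.75)
        assert len(r.aligned_a) == 4

    def test_local_mode_spans_the_similar_region(self):
        r = pairwise_align("GGGGACDEFGHIKGGGG", "ACDEFGHIK", mode="local")
        assert r.aligned_a == "ACDEFGHIK"
        assert r.identity == 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_align("", "ACD")

    def test_dp_score_equals_brute_force_enumeration(self):
        matrix = blosum62()
        rng = random.Random(17)
        for _ in range(20):
            a = "".join(rng.choice(AA) for _ in range(rng.randint(2, 6)))
            b = "".join(rng.choice(AA) for _ in range(rng.randint(2, 6)))
            got = pairwise_align(a, b, mode="global").score
            want = brute_force_global_score(a, b, matrix, 11.0, 1.0)
            assert got == pytest.approx(want), (a, b)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

class TestDistances:
    def test_identical_rows_zero(self):
        aln = Alignment(ids=("a", "b"), rows=("ACDEFGHIKL", "ACDEFGHIKL"))
        assert distance_matrix(aln).matrix[0, 1] == 0.0

    def test_p_distance_direct_count(self):
        aln = Alignment(ids=("a", "b"), rows=("ACDEFGHIKL", "ACDEFGHIWW"))
        assert distance_matrix(aln).matrix[0, 1] == pytest.approx(0.2)

    def test_poisson_correction_closed_form(self):
        aln = Alignment(ids=("a", "b"), rows=("ACDEFGHIKL", "ACDEFGHIWW"))
        d = distance_matrix(aln, model="poisson").matrix[0, 1]
        assert d == pytest.approx(-math.log(0.8))

    def test_gapped_columns_excluded(self):
        aln = Alignment(ids=("a", "b"), rows=("AC-EF", "ACW-F"))
        # compared columns: 0,1,4 -> no mismatches
        assert distance_matrix(aln).matrix[0, 1] == 0.0

    def test_saturated_pair_errors_under_poisson(self):
        aln = Alignment(ids=("a", "b"), rows=("AAAA", "CCCC"))
        with pytest.raises(ValueError, match="a.*b|Poisson"):
            distance_matrix(aln, model="poisson")

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), m)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def random_additive_matrix(n_leaves, rng):
    """Random unrooted binary tree -> (ids, path-length matrix)."""
    nodes = [(f"L{i}",) for i in range(n_leaves)]
    adjacency = {}
    names = {}
    next_id = 0

    def new_node(name=None):
        nonlocal next_id
        nid = next_id
        next_id += 1
        adjacency[nid] = []
        if name:
            names[nid] = name
        return nid

    leaf_ids = [new_node(f"L{i}") for i in range(n_leaves)]
    pool = leaf_ids[:]
    while len(pool) > 3:
        i, j = sorted(rng.sample(range(len(pool)), 2), reverse=True)
        a, b = pool.pop(i), pool.pop(j)
        parent = new_node()
        for child in (a, b):
            w = rng.uniform(0.5, 5.0)
            adjacency[parent].append((child, w))
            adjacency[child].append((parent, w))
        pool.append(parent)
    center = new_node()
    for child in pool:
        w = rng.uniform(0.5, 5.0)
        adjacency[center].append((child, w))
        adjacency[child].append((center, w))
    tree = PhyloTree(adjacency=adjacency, leaf_names=names)
    return tree.path_length_matrix()


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            ("a", "b", "c"),
            np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float),
        )
        tree = neighbor_joining(dm)
        assert tree.path_length("a", "b") == pytest.approx(4.0)
        assert tree.path_length("a", "c") == pytest.approx(6.0)
        assert tree.path_length("b", "c") == pytest.approx(8.0)

    def test_four_taxon_additive_round_trip(self):
        # built from a known tree with branch lengths {1,2,3,4,5}
        dm = DistanceMatrix(
            ("A", "B", "C", "D"),
            np.array(
                [[0, 3, 9, 10], [3, 0, 10, 11], [9, 10, 0, 5], [10, 11, 5, 0]],
                dtype=float,
            ),
        )
        tree = neighbor_joining(dm)
        got = tree.path_length_matrix(("A", "B", "C", "D")).matrix
        assert np.allclose(got, dm.matrix)
        assert tree.bipartitions() == {frozenset({"C", "D"})}

    def test_random_additive_matrices_inverted_exactly(self):
        rng = random.Random(23)
        for n in (4, 5, 6, 8, 10, 12):
            dm = random_additive_matrix(n, rng)
            tree = neighbor_joining(dm)
            got = tree.path_length_matrix(dm.ids).matrix
            assert np.allclose(got, dm.matrix, atol=1e-9), n

    def test_q_tie_joins_lowest_index_pair(self):
        # equidistant taxa: every Q equal, so (0, 1) must be joined first
        m = np.ones((4, 4)) - np.eye(4)
        tree = neighbor_joining(DistanceMatrix(("t0", "t1", "t2", "t3"), m))
        assert tree.bipartitions() == {frozenset({"t2", "t3"})}

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(
                DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [1.0, 0.0]]))
            )

    def test_agrees_with_skbio_on_random_additive_matrix(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj

        rng = random.Random(41)
        dm = random_additive_matrix(7, rng)
        ours = neighbor_joining(dm)
        theirs = nj(SkbioDM(dm.matrix, ids=list(dm.ids)))
        ours_splits = ours.bipartitions()
        anchor = min(dm.ids)
        theirs_splits = set()
        for node in theirs.non_tips():
            side = frozenset(t.name for t in node.tips())
            if anchor in side:
                side = frozenset(set(dm.ids) - side)
            if 1 < len(side) < len(dm.ids) - 1:
                theirs_splits.add(side)
        assert ours_splits == theirs_splits


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _two_clade_alignment():
    rng = random.Random(5)
    block_a = "".join(rng.choice(AA) for _ in range(60))
    block_b = "".join(rng.choice(AA) for _ in range(60))
    rows = [block_a, block_a, block_a[:-1] + "W"]
    rows += [block_b, block_b, block_b[:-1] + "W"]
    ids = ("a1", "a2", "a3", "b1", "b2", "b3")
    return Alignment(ids=ids, rows=tuple(rows))


class TestBootstrap:
    def test_saturated_split_gets_full_support(self):
        aln = _two_clade_alignment()
        tree = bootstrap_support(aln, n_replicates=50, seed=2)
        sep = frozenset({"b1", "b2", "b3"})
        assert tree.supports[sep] == 100.0

    def test_single_replicate_supports_are_binary(self):
        aln = _two_clade_alignment()
        tree = bootstrap_support(aln, n_replicates=1, seed=9)
        assert set(tree.supports.values()) <= {0.0, 100.0}

    def test_seeded_runs_are_identical(self):
        aln = _two_clade_alignment()
        t1 = bootstrap_support(aln, n_replicates=30, seed=4)
        t2 = bootstrap_support(aln, n_replicates=30, seed=4)
        assert t1.supports == t2.supports
        assert t1.newick() == t2.newick()

    def test_taxon_order_invariance(self):
        aln = _two_clade_alignment()
        order = [3, 0, 5, 2, 4, 1]
        shuffled = Alignment(
            ids=tuple(aln.ids[i] for i in order),
            rows=tuple(aln.rows[i] for i in order),
        )
        t1 = bootstrap_support(aln, n_replicates=30, seed=4)
        t2 = bootstrap_support(shuffled, n_replicates=30, seed=4)
        assert t1.supports == t2.supports

    def test_newick_carries_supports(self):
        aln = _two_clade_alignment()
        tree = bootstrap_support(aln, n_replicates=10, seed=1)
        nwk = tree.newick()
        assert nwk.endswith(";") and "100" in nwk
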