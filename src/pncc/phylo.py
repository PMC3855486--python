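"""Pairwise alignment, distance matrices, neighbor joining and bootstrap.

The tree machinery behind the two-origin classification: affine-gap global
and local alignment by dynamic programming (BLAST-comparable defaults,
BLOSUM62 / gap open 11 / extend 1, where a gap of length k costs
open + k*extend), p-distance or Poisson-corrected distances from an MSA,
Saitou-Nei neighbor joining with deterministic tie-breaking, and bootstrap
supports over column resampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .conservation import Alignment

NEG_INF = float("-inf")


def blosum62() -> dict[tuple[str, str], float]:
    m = substitution_matrices.load("BLOSUM62")
    out = {}
    for a in m.alphabet:
        for b in m.alphabet:
            out[(a, b)] = float(m[a, b])
    return out


@dataclass(frozen=True)
class PairwiseResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity: float          # identical columns / aligned columns
    start_a: int = 0         # local mode: 0-based starts of the aligned span
    start_b: int = 0


def pairwise_align(
    seq_a: str,
    seq_b: str,
    mode: str = "global",
    matrix: Optional[dict] = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> PairwiseResult:
    """Optimal affine-gap alignment (Gotoh) with deterministic traceback.

    Ties are broken preferring diagonal, then up (gap in ``seq_b``), then
    left.  Identity is identical columns over aligned columns; in local mode
    the denominator is the local alignment span.
    """
    if not seq_a or not seq_b:
        raise ValueError("both sequences must be non-empty")
    if mode not in ("global", "local"):
        raise ValueError("mode must be 'global' or 'local'")
    if matrix is None:
        matrix = blosum62()
    n, m = len(seq_a), len(seq_b)
    go, ge = gap_open, gap_extend
    first = go + ge  # cost of the first residue of a gap (BLAST convention)

    # M: a[i] aligned to b[j]; X: gap in b (consume a, "up"); Y: gap in a ("left")
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    local = mode == "local"
    M[0][0] = 0.0
    if not local:
        for i in range(1, n + 1):
            X[i][0] = -(go + ge * i)
        for j in range(1, m + 1):
            Y[0][j] = -(go + ge * j)
    else:
        for i in range(n + 1):
            M[i][0] = 0.0
        for j in range(m + 1):
            M[0][j] = 0.0

    for i in range(1, n + 1):
        ca = seq_a[i - 1]
        Mi, Mi1 = M[i], M[i - 1]
        Xi, Xi1 = X[i], X[i - 1]
        Yi = Y[i]
        Yi1 = Y[i - 1]
        for j in range(1, m + 1):
            s = matrix.get((ca, seq_b[j - 1]), matrix.get((seq_b[j - 1], ca), -4.0))
            diag = max(Mi1[j - 1], Xi1[j - 1], Y[i - 1][j - 1])
            val = diag + s if diag > NEG_INF else NEG_INF
            if local:
                val = max(val, 0.0)
            Mi[j] = val
            Xi[j] = max(Mi1[j] - first, Xi1[j] - ge)
            Yi[j] = max(Mi[j - 1] - first, Yi[j - 1] - ge)

    # pick end state
    if local:
        best = (0.0, 0, 0)
        for i in range(n + 1):
            for j in range(m + 1):
                if M[i][j] > best[0]:
                    best = (M[i][j], i, j)
        score, ei, ej = best
        state = "M"
    else:
        i, j = n, m
        score = max(M[i][j], X[i][j], Y[i][j])
        if M[i][j] == score:
            state = "M"
        elif X[i][j] == score:
            state = "X"
        else:
            state = "Y"
        ei, ej = i, j

    # traceback (prefer diagonal, then up, then left at ties)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = ei, ej
    while True:
        if local and state == "M" and M[i][j] == 0.0:
            break
        if not local and i == 0 and j == 0:
            break
        if state == "M":
            if not local and (i == 0 or j == 0):
                state = "X" if j == 0 else "Y"
                continue
            s = matrix.get(
                (seq_a[i - 1], seq_b[j - 1]),
                matrix.get((seq_b[j - 1], seq_a[i - 1]), -4.0),
            )
            prev_target = M[i][j] - s
            out_a.append(seq_a[i - 1])
            out_b.append(seq_b[j - 1])
            i, j = i - 1, j - 1
            if M[i][j] == prev_target:
                state = "M"
            elif X[i][j] == prev_target:
                state = "X"
            elif Y[i][j] == prev_target:
                state = "Y"
            elif local and prev_target <= 0:
                state = "M"  # alignment start
            else:          # numerical guard
                state = "M"
        elif state == "X":
            out_a.append(seq_a[i - 1])
            out_b.append("-")
            if M[i - 1][j] - first == X[i][j]:
                state = "M"
            else:
                state = "X"
            i -= 1
            if not local and i == 0 and j == 0:
                break
        else:  # Y
            out_a.append("-")
            out_b.append(seq_b[j - 1])
            if M[i][j - 1] - first == Y[i][j]:
                state = "M"
            else:
                state = "Y"
            j -= 1
            if not local and i == 0 and j == 0:
                break
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    cols = len(aligned_a)
    ident = (
        sum(1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-") / cols
        if cols
        else 0.0
    )
    return PairwiseResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(score),
        identity=ident,
        start_a=i,
        start_b=j,
    )


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match taxa count")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(m) != 0).any():
            raise ValueError("diagonal must be zero")
        if (m < 0).any():
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.ids)


def distance_matrix(msa: Alignment, model: str = "p") -> DistanceMatrix:
    """Pairwise distances from an MSA.

    ``model='p'``: mismatches / compared columns (columns gapped in either
    row excluded).  ``model='poisson'``: d = -ln(1 - p), undefined at p = 1.
    """
    if model not in ("p", "poisson"):
        raise ValueError("model must be 'p' or 'poisson'")
    n = msa.n_rows
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = msa.rows[i], msa.rows[j]
            compared = mismatch = 0
            for x, y in zip(a, b):
                if x == "-" or y == "-":
                    continue
                compared += 1
                if x != y:
                    mismatch += 1
            if compared == 0:
                raise ValueError(
                    f"no comparable columns between {msa.ids[i]!r} and {msa.ids[j]!r}"
                )
            p = mismatch / compared
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"p-distance of 1 between {msa.ids[i]!r} and {msa.ids[j]!r}: "
                        "Poisson correction undefined"
                    )
                d = -math.log(1.0 - p)
            else:
                d = p
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(ids=tuple(msa.ids), matrix=mat)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """Unrooted tree: adjacency lists over integer nodes; leaves are named."""

    adjacency: dict[int, list[tuple[int, float]]]
    leaf_names: dict[int, str]
    supports: dict[frozenset[str], float] = field(default_factory=dict)
    negative_branch_clamped: bool = False

    @property
    def leaves(self) -> list[int]:
        return sorted(self.leaf_names)

    def path_length(self, a: str, b: str) -> float:
        name_to_node = {v: k for k, v in self.leaf_names.items()}
        start, goal = name_to_node[a], name_to_node[b]
        stack = [(start, -1, 0.0)]
        while stack:
            node, parent, dist = stack.pop()
            if node == goal:
                return dist
            for nbr, w in self.adjacency[node]:
                if nbr != parent:
                    stack.append((nbr, node, dist + w))
        raise ValueError(f"no path between {a!r} and {b!r}")

    def path_length_matrix(self, order: Optional[Sequence[str]] = None) -> DistanceMatrix:
        names = list(order) if order else sorted(self.leaf_names.values())
        n = len(names)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = self.path_length(names[i], names[j])
                mat[i, j] = mat[j, i] = d
        return DistanceMatrix(ids=tuple(names), matrix=mat)

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each as the leaf-name set on the side not
        containing the lexicographically smallest leaf (canonical form)."""
        all_names = set(self.leaf_names.values())
        anchor = min(all_names)
        splits: set[frozenset[str]] = set()
        seen_edges = set()
        for u, nbrs in self.adjacency.items():
            for v, _ in nbrs:
                edge = (min(u, v), max(u, v))
                if edge in seen_edges:
                    continue
                seen_edges.add(edge)
                side = self._side_leaves(u, v)
                if anchor in side:
                    side = all_names - side
                if len(side) > 1 and len(all_names) - len(side) > 1:
                    splits.add(frozenset(side))
        return splits

    def _side_leaves(self, u: int, v: int) -> set[str]:
        """Leaves on the v-side of edge (u, v)."""
        out = set()
        stack = [(v, u)]
        while stack:
            node, parent = stack.pop()
            if node in self.leaf_names:
                out.add(self.leaf_names[node])
            for nbr, _ in self.adjacency[node]:
                if nbr != parent:
                    stack.append((nbr, node))
        return out

    def newick(self, decimals: int = 6) -> str:
        """Newick string; bootstrap supports (if any) as internal labels."""
        internal = [n for n in self.adjacency if n not in self.leaf_names]
        root = max(internal) if internal else next(iter(self.adjacency))
        all_names = set(self.leaf_names.values())
        anchor = min(all_names)

        def support_label(node: int, parent: int) -> str:
            if not self.supports:
                return ""
            side = self._side_leaves(parent, node)
            if anchor in side:
                side = all_names - side
            key = frozenset(side)
            if key in self.supports:
                return f"{self.supports[key]:.0f}"
            return ""

        def emit(node: int, parent: int) -> str:
            children = [(n, w) for n, w in self.adjacency[node] if n != parent]
            if not children:
                return f"{self.leaf_names[node]}"
            inner = ",".join(
                f"{emit(n, node)}:{w:.{decimals}f}" for n, w in children
            )
            label = support_label(node, parent) if parent != -1 else ""
            return f"({inner}){label}"

        return emit(root, -1) + ";"


def tree_path_lengths(tree: PhyloTree) -> DistanceMatrix:
    return tree.path_length_matrix()


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei agglomeration on the Q-criterion.

    Ties in Q are resolved by joining the lexicographically lowest index
    pair.  Negative branch-length estimates are clamped to zero and flagged.
    On an additive matrix the tree's path lengths reproduce the input.
    """
    n0 = len(dm)
    if n0 < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    active = list(range(n0))
    d = {
        (i, j): float(dm.matrix[i, j])
        for i in range(n0)
        for j in range(n0)
        if i < j
    }

    def dist(i: int, j: int) -> float:
        return 0.0 if i == j else d[(min(i, j), max(i, j))]

    adjacency: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n0)}
    leaf_names = {i: dm.ids[i] for i in range(n0)}
    next_node = n0
    clamped = False

    def add_edge(u: int, v: int, w: float) -> None:
        nonlocal clamped
        if w < 0:
            clamped = True
            w = 0.0
        adjacency.setdefault(u, []).append((v, w))
        adjacency.setdefault(v, []).append((u, w))

    while len(active) > 3:
        n = len(active)
        r = {i: sum(dist(i, k) for k in active) for i in active}
        best = None
        best_pair = None
        for ai in range(n):
            for aj in range(ai + 1, n):
                i, j = active[ai], active[aj]
                q = (n - 2) * dist(i, j) - r[i] - r[j]
                if best is None or q < best - 1e-12:
                    best, best_pair = q, (i, j)
        i, j = best_pair  # type: ignore[misc]
        dij = dist(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (n - 2))
        lj = dij - li
        u = next_node
        next_node += 1
        add_edge(u, i, li)
        add_edge(u, j, lj)
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (dist(i, k) + dist(j, k) - dij)
            d[(min(u, k), max(u, k))] = duk
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    la = 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))
    lb = 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))
    lc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
    center = next_node
    add_edge(center, a, la)
    add_edge(center, b, lb)
    add_edge(center, c, lc)
    return PhyloTree(
        adjacency=adjacency, leaf_names=leaf_names, negative_branch_clamped=clamped
    )


def bootstrap_support(
    msa: Alignment,
    n_replicates: int = 1000,
    seed: int = 0,
    model: str = "p",
) -> PhyloTree:
    """NJ point-estimate tree with bootstrap supports on internal edges.

    Columns are resampled with replacement per replicate; support is the
    percentage of replicate trees containing each internal bipartition of
    the point tree.  Taxa are canonicalized (sorted by id) before distance
    computation so supports do not depend on input order.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    order = sorted(range(msa.n_rows), key=lambda k: msa.ids[k])
    canon = Alignment(
        ids=tuple(msa.ids[k] for k in order),
        rows=tuple(msa.rows[k] for k in order),
        lineage=msa.lineage,
    )
    point = neighbor_joining(distance_matrix(canon, model=model))
    targets = point.bipartitions()
    counts = {t: 0 for t in targets}
    rng = np.random.default_rng(seed)
    L = canon.n_cols
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rows = tuple("".join(row[c] for c in cols) for row in canon.rows)
        rep = Alignment(ids=canon.ids, rows=rows, lineage=canon.lineage)
        rep_tree = neighbor_joining(distance_matrix(rep, model=model))
        rep_splits = rep_tree.bipartitions()
        for t in targets:
            if t in rep_splits:
                counts[t] += 1
    point.supports = {t: 100.0 * c / n_replicates for t, c in counts.items()}
    return point
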