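"""Distance-based phylogeny: pairwise alignment distances, neighbor
joining with deterministic tie-breaking, column-resampling bootstrap
support, and Newick serialization.

Distances are p-distances (mismatched aligned positions / aligned
positions, gap columns excluded) computed either from global
Needleman-Wunsch alignments (unaligned protein input; BLOSUM62, affine
gaps) or positionally for pre-aligned equal-length sequences. A Poisson
correction (-ln(1-p)) is available behind a flag.

Neighbor joining follows Saitou-Nei with the Studier-Keppler Q
criterion; ties in Q are broken by the lowest (i, j) index pair, and
negative branch-length estimates are clamped to zero with the deficit
moved to the sibling branch (both logged).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger("cbfsurvey.phylo")

__all__ = [
    "DistanceMatrix",
    "PhyloTree",
    "PairwiseColumns",
    "pairwise_columns",
    "pairwise_distance",
    "neighbor_joining",
    "bipartitions",
    "bootstrap",
    "build_tree",
    "write_newick",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative distances with a zero diagonal."""

    taxa: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(d, d.T):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("distances must be nonnegative")
        object.__setattr__(self, "d", d)


class _Node:
    __slots__ = ("name", "children", "support")

    def __init__(self, name: str | None = None):
        self.name = name
        self.children: list[tuple["_Node", float]] = []
        self.support: int | None = None

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """An unrooted tree stored rooted at an internal trifurcation."""

    root: _Node
    taxa: tuple[str, ...]

    def leaf_names(self) -> list[str]:
        out: list[str] = []

        def walk(n: _Node) -> None:
            if n.is_leaf():
                out.append(n.name)
            for c, _ in n.children:
                walk(c)

        walk(self.root)
        return out

    def path_length_matrix(self) -> DistanceMatrix:
        """Leaf-to-leaf path lengths (additivity oracle substrate)."""
        index = {t: i for i, t in enumerate(self.taxa)}
        n = len(self.taxa)
        d = np.zeros((n, n))

        def leaves_below(node: _Node, depth: float, acc: list) -> None:
            if node.is_leaf():
                acc.append((index[node.name], depth))
            for c, bl in node.children:
                leaves_below(c, depth + bl, acc)

        def combine(node: _Node) -> list:
            if node.is_leaf():
                return [(index[node.name], 0.0)]
            groups = []
            for c, bl in node.children:
                acc: list = []
                leaves_below(c, bl, acc)
                groups.append(acc)
            for g1, g2 in itertools.combinations(groups, 2):
                for i, di in g1:
                    for j, dj in g2:
                        d[i, j] = d[j, i] = di + dj
            for c, _ in node.children:
                combine(c)
            return []

        combine(self.root)
        return DistanceMatrix(self.taxa, d)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

_NUC = set("ACGTN")


@dataclass
class PairwiseColumns:
    """Per-pair aligned residue columns, the bootstrap substrate.

    ``columns[(i, j)]`` holds two equal-length arrays of residues at the
    ungapped aligned positions of taxa i and j.
    """

    taxa: tuple[str, ...]
    columns: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]]

    def distance_matrix(self, model: str = "p") -> DistanceMatrix:
        n = len(self.taxa)
        d = np.zeros((n, n))
        for (i, j), (a, b) in self.columns.items():
            if a.size == 0:
                p = 0.0
            else:
                p = float(np.mean(a != b))
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError("saturated distance under Poisson correction")
                p = -np.log(1.0 - p)
            elif model != "p":
                raise ValueError(f"unknown distance model {model!r}")
            d[i, j] = d[j, i] = p
        return DistanceMatrix(self.taxa, d)

    def resample(self, master: np.ndarray) -> "PairwiseColumns":
        """Column-resampled copy driven by one master uniform vector.

        Each pair with L columns uses indices floor(master[:L] * L); for
        equal-length (pre-aligned) inputs this resamples the same
        columns jointly in every pair.
        """
        cols: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        for key, (a, b) in self.columns.items():
            L = a.size
            if L == 0:
                cols[key] = (a, b)
                continue
            idx = np.minimum((master[:L] * L).astype(np.int64), L - 1)
            cols[key] = (a[idx], b[idx])
        return PairwiseColumns(self.taxa, cols)


def _protein_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def pairwise_columns(
    seqs: Sequence[tuple[str, str]],
    aligned: bool = False,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> PairwiseColumns:
    """Aligned residue columns for every pair of sequences.

    ``aligned=True`` treats the input as a fixed alignment (all
    sequences equal length, positions compared directly) — appropriate
    for simulated sequences; otherwise each pair is globally aligned
    with Needleman-Wunsch (BLOSUM62, affine gaps) and gap columns are
    dropped.
    """
    if len(seqs) < 3:
        raise ValueError("need at least 3 sequences")
    for tid, s in seqs:
        if not s:
            raise ValueError(f"empty sequence for taxon {tid!r}")
    taxa = tuple(tid for tid, _ in seqs)
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon ids")
    cols: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    if aligned:
        lengths = {len(s) for _, s in seqs}
        if len(lengths) != 1:
            raise ValueError("aligned=True requires equal-length sequences")
        arrs = [np.frombuffer(s.upper().encode(), dtype="S1") for _, s in seqs]
        for i, j in itertools.combinations(range(len(seqs)), 2):
            cols[(i, j)] = (arrs[i], arrs[j])
    else:
        aligner = _protein_aligner(gap_open, gap_extend)
        for i, j in itertools.combinations(range(len(seqs)), 2):
            aln = next(iter(aligner.align(seqs[i][1].upper(), seqs[j][1].upper())))
            a_row, b_row = aln[0], aln[1]
            a_chars, b_chars = [], []
            for ca, cb in zip(a_row, b_row):
                if ca != "-" and cb != "-":
                    a_chars.append(ca)
                    b_chars.append(cb)
            cols[(i, j)] = (
                np.array(a_chars, dtype="S1"),
                np.array(b_chars, dtype="S1"),
            )
    return PairwiseColumns(taxa, cols)


def pairwise_distance(
    seqs: Sequence[tuple[str, str]],
    model: str = "p",
    aligned: bool = False,
) -> DistanceMatrix:
    """Pairwise distance matrix (see :func:`pairwise_columns`)."""
    return pairwise_columns(seqs, aligned=aligned).distance_matrix(model=model)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Q(i,j) = (n-2) d(i,j) - r_i - r_j is minimized at each step (ties:
    lowest index pair); branch lengths use the standard formulas with
    negative estimates clamped to 0 and the deficit moved to the
    sibling branch.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[_Node] = [_Node(t) for t in dm.taxa]
    d = dm.d.copy()
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            logger.debug("clamping negative branch %.3g; deficit to sibling", li)
            lj += li
            li = 0.0
        if lj < 0:
            logger.debug("clamping negative branch %.3g; deficit to sibling", lj)
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best, best_q = None, np.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = clamp(li, lj)
        parent = _Node()
        parent.children = [(nodes[i], li), (nodes[j], lj)]
        # grow matrix with the new node
        new = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
            d[new, k] = d[k, new] = max(dk, 0.0)
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [new]

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = _Node()
    root.children = [
        (nodes[i], max(li, 0.0)),
        (nodes[j], max(lj, 0.0)),
        (nodes[k], max(lk, 0.0)),
    ]
    return PhyloTree(root=root, taxa=dm.taxa)


def bipartitions(tree: PhyloTree) -> set[frozenset]:
    """Nontrivial splits of the unrooted tree.

    Each internal edge is encoded as the frozenset of leaf names on the
    side NOT containing the first taxon (a canonical orientation).
    """
    all_taxa = frozenset(tree.taxa)
    ref = tree.taxa[0]
    splits: set[frozenset] = set()

    def walk(node: _Node) -> frozenset:
        if node.is_leaf():
            return frozenset([node.name])
        below = frozenset()
        for c, _ in node.children:
            below |= walk(c)
        if node is not tree.root and 1 < len(below) < len(all_taxa) - 1:
            side = below if ref not in below else all_taxa - below
            splits.add(side)
        return below

    walk(tree.root)
    return splits


def bootstrap(
    columns: PairwiseColumns,
    reps: int,
    seed: int,
    model: str = "p",
) -> tuple[PhyloTree, dict[frozenset, int]]:
    """Column-resampling bootstrap support for the NJ tree.

    Rebuilds the tree on ``reps`` column resamples (one master uniform
    vector per replicate, fanned out to each pair) and reports, for each
    internal bipartition of the original tree, the percentage of
    replicates containing it. Supports are attached to the returned
    tree's internal nodes.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    tree = neighbor_joining(columns.distance_matrix(model=model))
    target = bipartitions(tree)
    counts = {s: 0 for s in target}
    rng = np.random.default_rng(seed)
    lmax = max((a.size for a, _ in columns.columns.values()), default=0)
    for _ in range(reps):
        master = rng.random(lmax)
        rep_cols = columns.resample(master)
        try:
            rep_tree = neighbor_joining(rep_cols.distance_matrix(model=model))
        except ValueError:
            continue  # saturated replicate under Poisson correction
        rep_splits = bipartitions(rep_tree)
        for s in target:
            if s in rep_splits:
                counts[s] += 1
    support = {s: int(round(100.0 * c / reps)) for s, c in counts.items()}

    all_taxa = frozenset(tree.taxa)
    ref = tree.taxa[0]

    def annotate(node: _Node) -> frozenset:
        if node.is_leaf():
            return frozenset([node.name])
        below = frozenset()
        for c, _ in node.children:
            below |= annotate(c)
        if node is not tree.root and 1 < len(below) < len(all_taxa) - 1:
            side = below if ref not in below else all_taxa - below
            node.support = support[side]
        return below

    annotate(tree.root)
    return tree, support


def build_tree(
    seqs: Sequence[tuple[str, str]],
    aligned: bool = False,
    model: str = "p",
    bootstrap_reps: int = 0,
    seed: int = 20191017,
) -> PhyloTree:
    """Distances -> NJ tree, optionally with bootstrap supports."""
    columns = pairwise_columns(seqs, aligned=aligned)
    if bootstrap_reps > 0:
        tree, _ = bootstrap(columns, reps=bootstrap_reps, seed=seed, model=model)
        return tree
    return neighbor_joining(columns.distance_matrix(model=model))


def write_newick(tree: PhyloTree) -> str:
    """Newick string with branch lengths and integer supports as
    internal-node labels."""

    def fmt(node: _Node) -> str:
        if node.is_leaf():
            return node.name
        inner = ",".join(f"{fmt(c)}:{bl:.10g}" for c, bl in node.children)
        label = "" if node.support is None else str(node.support)
        return f"({inner}){label}"

    return fmt(tree.root) + ";"
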