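"""Maximum-parsimony homology analysis for protein families.

The pipeline's phylogenetic step: complete deletion of alignment columns
containing gaps or missing data, Fitch small-parsimony scoring (unordered
states, unit cost), stepwise random-addition starting trees, and a
close-neighbour-interchange local search implemented as nearest-neighbour-
interchange (NNI) hill climbing — at search level 0 the CNI neighbourhood
reduces to the NNI neighbourhood.  For families small enough to enumerate,
`exhaustive_search` scores every unrooted topology.

Trees are unrooted with strictly binary internal nodes (degree 3); scoring
roots the tree on an arbitrary edge, which leaves the parsimony score
unchanged.  Pairwise percent identity uses global alignment (match +1,
mismatch 0, linear gap -1 by default) with terminal-gap columns excluded
from the denominator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from Bio.Align import PairwiseAligner

MISSING_SYMBOLS = {"-", "?", "X"}  # gaps and missing data, per complete deletion


# ---------------------------------------------------------------------------
# Alignment container and column filtering
# ---------------------------------------------------------------------------

@dataclass
class Msa:
    """A multiple sequence alignment: unique labels, equal-length rows."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("taxa labels must be unique")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def remove_gap_columns(msa: Msa) -> Msa:
    """Complete deletion: drop every column with a gap or missing symbol.

    A column is removed if ANY row carries '-', '?' or 'X' (case-blind)
    there; the order of retained columns is preserved.
    """
    keep = [
        j for j in range(msa.n_columns)
        if all(row[j].upper() not in MISSING_SYMBOLS for row in msa.rows)
    ]
    if not keep:
        raise ValueError("complete deletion removed every column")
    rows = ["".join(row[j] for j in keep) for row in msa.rows]
    return Msa(list(msa.labels), rows)


# ---------------------------------------------------------------------------
# Unrooted binary trees
# ---------------------------------------------------------------------------

class Tree:
    """Unrooted tree with labelled leaves and degree-3 internal nodes."""

    def __init__(self, adj: dict[int, list[int]], labels: dict[int, str],
                 score: int | None = None) -> None:
        self.adj = adj
        self.labels = labels  # leaf node id -> taxon label
        self.score = score

    # -- construction ------------------------------------------------------

    @classmethod
    def star3(cls, a: str, b: str, c: str) -> "Tree":
        """The unique unrooted topology on three taxa."""
        return cls(
            {0: [3], 1: [3], 2: [3], 3: [0, 1, 2]},
            {0: a, 1: b, 2: c},
        )

    def copy(self) -> "Tree":
        return Tree({k: list(v) for k, v in self.adj.items()},
                    dict(self.labels), self.score)

    @property
    def taxa(self) -> set[str]:
        return set(self.labels.values())

    def edges(self) -> list[tuple[int, int]]:
        return sorted(
            (min(u, v), max(u, v))
            for u in self.adj for v in self.adj[u] if u < v
        )

    def internal_edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u, v in self.edges()
                if u not in self.labels and v not in self.labels]

    def insert_leaf(self, edge: tuple[int, int], label: str) -> "Tree":
        """Attach a new labelled leaf by subdividing `edge`."""
        t = self.copy()
        u, v = edge
        w = max(t.adj) + 1   # new internal node
        leaf = w + 1
        t.adj[u].remove(v)
        t.adj[v].remove(u)
        t.adj[u].append(w)
        t.adj[v].append(w)
        t.adj[w] = [u, v, leaf]
        t.adj[leaf] = [w]
        t.labels[leaf] = label
        t.score = None
        return t

    # -- topology identity -------------------------------------------------

    def _leafset(self, node: int, parent: int) -> frozenset[str]:
        if node in self.labels:
            return frozenset([self.labels[node]])
        out: set[str] = set()
        for nb in self.adj[node]:
            if nb != parent:
                out |= self._leafset(nb, node)
        return frozenset(out)

    def splits(self) -> frozenset[frozenset[str]]:
        """Non-trivial bipartitions, each keyed by the side without a fixed taxon."""
        anchor = min(self.taxa)
        out = set()
        for u, v in self.internal_edges():
            side = self._leafset(u, v)
            if anchor in side:
                side = frozenset(self.taxa - side)
            if 1 < len(side) < len(self.taxa) - 1:
                out.add(side)
        return frozenset(out)

    def same_topology(self, other: "Tree") -> bool:
        return self.taxa == other.taxa and self.splits() == other.splits()

    # -- NNI ---------------------------------------------------------------

    def nni_neighbors(self) -> list["Tree"]:
        """The two alternative topologies across each internal edge."""
        out = []
        for u, v in self.internal_edges():
            a, b = [x for x in self.adj[u] if x != v]
            c, d = [x for x in self.adj[v] if x != u]
            for swap_u, swap_v in ((b, c), (b, d)):
                t = self.copy()
                t.adj[u].remove(swap_u)
                t.adj[v].remove(swap_v)
                t.adj[u].append(swap_v)
                t.adj[v].append(swap_u)
                t.adj[swap_u].remove(u)
                t.adj[swap_v].remove(v)
                t.adj[swap_u].append(v)
                t.adj[swap_v].append(u)
                t.score = None
                out.append(t)
        return out

    # -- newick ------------------------------------------------------------

    def _newick_sub(self, node: int, parent: int) -> str:
        if node in self.labels:
            return self.labels[node]
        parts = [self._newick_sub(nb, node) for nb in self.adj[node] if nb != parent]
        return "(" + ",".join(parts) + ")"

    def to_newick(self) -> str:
        internal = [n for n in self.adj if n not in self.labels]
        root = internal[0] if internal else next(iter(self.adj))
        parts = [self._newick_sub(nb, root) for nb in self.adj[root]]
        return "(" + ",".join(parts) + ");"


# ---------------------------------------------------------------------------
# Fitch scoring
# ---------------------------------------------------------------------------

def _leaf_masks(msa: Msa) -> dict[str, np.ndarray]:
    alphabet = sorted({ch for row in msa.rows for ch in row})
    if len(alphabet) > 62:
        raise ValueError("alphabet too large for bitmask Fitch")
    index = {ch: i for i, ch in enumerate(alphabet)}
    return {
        label: np.array([np.int64(1) << index[ch] for ch in row], dtype=np.int64)
        for label, row in zip(msa.labels, msa.rows)
    }


def fitch_score(tree: Tree, msa: Msa) -> int:
    """Minimum number of unordered state changes on the tree, summed over columns."""
    if tree.taxa != set(msa.labels):
        raise ValueError("tree leaves and alignment taxa differ")
    masks = _leaf_masks(msa)
    changes = np.zeros(msa.n_columns, dtype=np.int64)
    label_of = tree.labels
    adj = tree.adj

    def down(node: int, parent: int) -> np.ndarray:
        if node in label_of:
            return masks[label_of[node]]
        acc: np.ndarray | None = None
        for nb in adj[node]:
            if nb == parent:
                continue
            m = down(nb, node)
            if acc is None:
                acc = m
            else:
                inter = acc & m
                miss = inter == 0
                changes[miss] += 1
                acc = np.where(miss, acc | m, inter)
        assert acc is not None
        return acc

    # root on the edge incident to an arbitrary leaf
    leaf = next(iter(label_of))
    nb = adj[leaf][0]
    top = down(nb, leaf)
    inter = masks[label_of[leaf]] & top
    changes[inter == 0] += 1
    return int(changes.sum())


# ---------------------------------------------------------------------------
# Tree search
# ---------------------------------------------------------------------------

def random_addition_tree(msa: Msa, seed: int) -> Tree:
    """Stepwise addition in seeded random taxon order.

    Each taxon is attached at the edge minimising the Fitch score, taking
    the first minimum in a seeded enumeration order of the edges (so
    replicates with different seeds break score ties differently).
    """
    if msa.n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    order = [msa.labels[i] for i in rng.permutation(msa.n_taxa)]
    tree = Tree.star3(order[0], order[1], order[2])
    for label in order[3:]:
        best: Tree | None = None
        best_score = None
        edges = tree.edges()
        for edge in [edges[i] for i in rng.permutation(len(edges))]:
            cand = tree.insert_leaf(edge, label)
            sub = _restrict(msa, cand.taxa)
            s = fitch_score(cand, sub)
            if best_score is None or s < best_score:
                best, best_score = cand, s
        assert best is not None
        tree = best
    tree.score = fitch_score(tree, _restrict(msa, tree.taxa))
    return tree


def _restrict(msa: Msa, taxa: set[str]) -> Msa:
    pairs = [(l, r) for l, r in zip(msa.labels, msa.rows) if l in taxa]
    return Msa([p[0] for p in pairs], [p[1] for p in pairs])


def cni_search(tree: Tree, msa: Msa, level: int = 0) -> Tree:
    """Close-neighbour-interchange local search to a parsimony optimum.

    Level 0 examines the close neighbourhood of the current topology:
    first every single nearest-neighbour interchange (accepting the first
    strict improvement), then, if none improves, every composition of two
    interchanges.  Iterates until no topology in that neighbourhood scores
    better; the returned score is never worse than the input score.
    """
    if level != 0:
        raise NotImplementedError("only search level 0 is implemented")
    current = tree.copy()
    current.score = fitch_score(current, msa)
    improved = True
    while improved:
        improved = False
        for nb in current.nni_neighbors():
            s = fitch_score(nb, msa)
            if s < current.score:
                nb.score = s
                current = nb
                improved = True
                break
        if improved:
            continue
        # no single interchange improves: scan two-swap close neighbours
        for nb in current.nni_neighbors():
            for nb2 in nb.nni_neighbors():
                s = fitch_score(nb2, msa)
                if s < current.score:
                    nb2.score = s
                    current = nb2
                    improved = True
                    break
            if improved:
                break
    return current


def mp_search(msa: Msa, replicates: int = 10, seed: int = 0) -> tuple[list[Tree], int]:
    """Best parsimony tree(s) over seeded random-addition + CNI replicates.

    Returns the distinct best-scoring topologies and their score.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=replicates)
    best_score: int | None = None
    best: list[Tree] = []
    for s in rep_seeds:
        start = random_addition_tree(msa, int(s))
        final = cni_search(start, msa)
        assert final.score is not None
        if best_score is None or final.score < best_score:
            best_score = final.score
            best = [final]
        elif final.score == best_score and not any(
            final.same_topology(t) for t in best
        ):
            best.append(final)
    assert best_score is not None
    return best, best_score


def enumerate_topologies(taxa: list[str]):
    """Yield every unrooted binary topology on the given taxa.

    (2n-5)!! trees: 3 for n=4, 105 for n=6, 945 for n=7.
    """
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    base = Tree.star3(taxa[0], taxa[1], taxa[2])
    stack = [(base, 3)]
    while stack:
        tree, i = stack.pop()
        if i == len(taxa):
            yield tree
            continue
        for edge in tree.edges():
            stack.append((tree.insert_leaf(edge, taxa[i]), i + 1))


def exhaustive_search(msa: Msa) -> tuple[list[Tree], int]:
    """Global optimum by scoring every topology; feasible for <= ~8 taxa."""
    best_score: int | None = None
    best: list[Tree] = []
    for tree in enumerate_topologies(list(msa.labels)):
        s = fitch_score(tree, msa)
        if best_score is None or s < best_score:
            tree.score = s
            best_score, best = s, [tree]
        elif s == best_score and not any(tree.same_topology(t) for t in best):
            tree.score = s
            best.append(tree)
    assert best_score is not None
    return best, best_score


# ---------------------------------------------------------------------------
# Percent identity
# ---------------------------------------------------------------------------

def percent_identity(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = -1.0,
) -> float:
    """Global-alignment percent identity between two protein sequences.

    Identity = matching columns / aligned columns, with terminal-gap
    columns (overhangs before both sequences start or after one ends)
    excluded from the denominator, x 100.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    aln = aligner.align(seq_a, seq_b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    n = len(row_a)
    # terminal-gap columns: the leading and trailing runs where either row
    # has not started or has already ended
    lead = 0
    while lead < n and (row_a[lead] == "-" or row_b[lead] == "-"):
        lead += 1
    trail = n
    while trail > lead and (row_a[trail - 1] == "-" or row_b[trail - 1] == "-"):
        trail -= 1
    core_a, core_b = row_a[lead:trail], row_b[lead:trail]
    n_cols = len(core_a)
    if n_cols == 0:
        return 0.0
    matches = sum(1 for x, y in zip(core_a, core_b) if x == y and x != "-")
    return matches / n_cols * 100.0
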