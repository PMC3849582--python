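"""Genome-wide phenotype models: overlap distances and least-squares trees.

The distance between two phenotype gene sets is one minus the overlap
(Szymkiewicz–Simpson) coefficient,

    D_ij = 1 - |C_i ∩ C_j| / min(N(C_i), N(C_j)),

so identical (or nested) sets are at distance 0 and disjoint sets at 1.
An unrooted leaf-labeled tree is then fitted to the matrix by weighted
least squares on branch lengths, minimizing the Fitch–Margoliash criterion

    S = Σ_{i<j} n_ij (D_ij - d_ij)^2 / D_ij^P,

where d_ij is the sum of branch lengths on the i→j path, n_ij a replicate
weight (1 by default), and P = 2 (Fitch–Margoliash weighting) or P = 0
(unweighted least squares). Topologies are searched heuristically by
stepwise leaf addition in deterministic label order followed by
nearest-neighbor-interchange refinement; small instances can be solved by
exhaustive enumeration of all unrooted topologies.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from scipy.optimize import nnls
from skbio.stats.distance import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .errors import (
    ConfigurationError,
    FitError,
    UndefinedDistanceError,
)
from .genesets import GeneSet, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "TreeFitConfig",
    "PhenoTree",
    "pairwise_distance",
    "distance_matrix",
    "sum_of_squares",
    "fit_branch_lengths",
    "fit_tree",
    "neighbor_joining_tree",
    "enumerate_topologies",
    "expected_distances",
    "tree_splits",
    "to_newick",
    "write_newick",
    "write_distance_tsv",
    "read_distance_tsv",
]


# ---------------------------------------------------------------------------
# distances

def pairwise_distance(a: GeneSet, b: GeneSet) -> float:
    """Overlap distance 1 - |A∩B| / min(|A|, |B|) between two gene sets."""
    if len(a) == 0 or len(b) == 0:
        raise UndefinedDistanceError(
            f"distance undefined for empty set ({a.name!r} or {b.name!r})")
    shared = len(a.gene_keys & b.gene_keys)
    return 1.0 - shared / min(len(a), len(b))


def distance_matrix(coll: GeneSetCollection) -> DistanceMatrix:
    """All-pairs overlap distances over a collection, labels sorted.

    Computed from the gene-by-set incidence matrix so large collections stay
    tractable.
    """
    labels = coll.terms()
    if any(len(coll[t]) == 0 for t in labels):
        raise UndefinedDistanceError("collection contains an empty gene set")
    genes = sorted(coll.all_gene_keys())
    gidx = {g: i for i, g in enumerate(genes)}
    B = np.zeros((len(genes), len(labels)), dtype=np.int32)
    for j, t in enumerate(labels):
        for g in coll[t].gene_keys:
            B[gidx[g], j] = 1
    inter = B.T @ B
    sizes = np.diag(inter).astype(float)
    mins = np.minimum.outer(sizes, sizes)
    D = 1.0 - inter / mins
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, 1.0)
    D = (D + D.T) / 2.0
    return DistanceMatrix(D, ids=labels)


# ---------------------------------------------------------------------------
# tree structure

@dataclass
class TreeFitConfig:
    """Weighted least-squares fit settings.

    power
        Exponent P of the 1/D^P weight: 2.0 (Fitch–Margoliash) or 0.0
        (unweighted least squares).
    n_replicates
        Replicate weight n_ij: a scalar, or a matrix aligned with the sorted
        distance-matrix labels.
    allow_negative_branches
        If False (default), branch lengths are constrained nonnegative.
    zero_distance_epsilon
        Stand-in for zero off-diagonal distances in the weight denominator
        (identical or nested gene sets otherwise give an infinite weight).
    """

    power: float = 2.0
    n_replicates: float | np.ndarray = 1.0
    allow_negative_branches: bool = False
    zero_distance_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.power not in (0.0, 2.0):
            raise ConfigurationError("power must be 2.0 or 0.0")
        if np.isscalar(self.n_replicates) and self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.zero_distance_epsilon <= 0:
            raise ConfigurationError("zero_distance_epsilon must be > 0")


class PhenoTree:
    """Unrooted leaf-labeled tree with branch lengths.

    Nodes are integers; leaves carry gene-set names. Edges are stored as
    frozensets of node pairs with a length each. ``sum_of_squares`` is set
    by the fitting routines.
    """

    def __init__(self) -> None:
        self.adj: dict[int, set[int]] = {}
        self.leaf_name: dict[int, str] = {}
        self.length: dict[frozenset, float] = {}
        self.sum_of_squares: float | None = None
        self._next_id = 0

    # -- construction -------------------------------------------------
    def add_node(self, name: str | None = None) -> int:
        node = self._next_id
        self._next_id += 1
        self.adj[node] = set()
        if name is not None:
            if name in self.leaves():
                raise FitError(f"duplicate leaf label {name!r}")
            self.leaf_name[node] = name
        return node

    def add_edge(self, u: int, v: int, length: float = 0.0) -> None:
        self.adj[u].add(v)
        self.adj[v].add(u)
        self.length[frozenset((u, v))] = length

    def remove_edge(self, u: int, v: int) -> None:
        self.adj[u].discard(v)
        self.adj[v].discard(u)
        self.length.pop(frozenset((u, v)), None)

    def copy(self) -> "PhenoTree":
        t = PhenoTree()
        t.adj = {u: set(vs) for u, vs in self.adj.items()}
        t.leaf_name = dict(self.leaf_name)
        t.length = dict(self.length)
        t.sum_of_squares = self.sum_of_squares
        t._next_id = self._next_id
        return t

    # -- queries ------------------------------------------------------
    def leaves(self) -> dict[str, int]:
        return {name: node for node, name in self.leaf_name.items()}

    def edges(self) -> list[frozenset]:
        return sorted(self.length, key=lambda e: tuple(sorted(e)))

    def degree(self, u: int) -> int:
        return len(self.adj[u])

    def is_leaf(self, u: int) -> bool:
        return u in self.leaf_name

    def __repr__(self) -> str:
        return (f"PhenoTree(leaves={len(self.leaf_name)}, "
                f"edges={len(self.length)})")


def _star3(labels: Iterable[str]) -> PhenoTree:
    tree = PhenoTree()
    center = tree.add_node()
    for name in labels:
        leaf = tree.add_node(name)
        tree.add_edge(center, leaf)
    return tree


def _attach_leaf(tree: PhenoTree, edge: frozenset, name: str) -> None:
    """Split ``edge`` with a new internal node and hang ``name`` off it."""
    u, v = sorted(edge)
    mid = tree.add_node()
    leaf = tree.add_node(name)
    tree.remove_edge(u, v)
    tree.add_edge(u, mid)
    tree.add_edge(mid, v)
    tree.add_edge(mid, leaf)


def _parent_map(tree: PhenoTree, root: int) -> dict[int, int]:
    parent = {root: -1}
    stack = [root]
    while stack:
        u = stack.pop()
        for v in tree.adj[u]:
            if v not in parent:
                parent[v] = u
                stack.append(v)
    return parent


def _pair_incidence(tree: PhenoTree, labels: list[str]):
    """0/1 matrix of (leaf pair) x (edge): which edges lie on each path."""
    leaf_of = tree.leaves()
    missing = set(labels) ^ set(leaf_of)
    if missing:
        raise ConfigurationError(f"leaf/label mismatch: {sorted(missing)}")
    edge_list = tree.edges()
    eidx = {e: k for k, e in enumerate(edge_list)}
    pairs = [(i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    A = np.zeros((len(pairs), len(edge_list)))
    parents = {lab: _parent_map(tree, leaf_of[lab]) for lab in labels}
    for r, (i, j) in enumerate(pairs):
        par = parents[labels[i]]
        node = leaf_of[labels[j]]
        while par[node] != -1:
            A[r, eidx[frozenset((node, par[node]))]] = 1.0
            node = par[node]
    return A, pairs, edge_list


def expected_distances(tree: PhenoTree) -> DistanceMatrix:
    """Path-length (additive) distances implied by the tree's branch lengths."""
    labels = sorted(tree.leaves())
    leaf_of = tree.leaves()
    n = len(labels)
    M = np.zeros((n, n))
    for i, lab in enumerate(labels):
        par = _parent_map(tree, leaf_of[lab])
        for j in range(i + 1, n):
            node = leaf_of[labels[j]]
            total = 0.0
            while par[node] != -1:
                total += tree.length[frozenset((node, par[node]))]
                node = par[node]
            M[i, j] = M[j, i] = total
    return DistanceMatrix(M, ids=labels)


def tree_splits(tree: PhenoTree) -> set[frozenset]:
    """Non-trivial leaf bipartitions: one side of each internal edge.

    Each split is returned as the frozenset of leaf names on the side *not*
    containing the lexicographically smallest leaf.
    """
    labels = sorted(tree.leaves())
    anchor = labels[0]
    out: set[frozenset] = set()
    for e in tree.edges():
        u, v = tuple(e)
        # leaves on v's side when edge removed
        side: set[str] = set()
        stack, seen = [v], {u, v}
        while stack:
            w = stack.pop()
            if tree.is_leaf(w):
                side.add(tree.leaf_name[w])
            for x in tree.adj[w]:
                if x not in seen:
                    seen.add(x)
                    stack.append(x)
        if anchor in side:
            side = set(labels) - side
        if 2 <= len(side) <= len(labels) - 2:
            out.add(frozenset(side))
    return out


def _topology_key(tree: PhenoTree) -> tuple:
    """Canonical, label-based key used for deterministic tie-breaking."""
    return tuple(sorted(tuple(sorted(s)) for s in tree_splits(tree)))


# ---------------------------------------------------------------------------
# least-squares fitting

def _weights(dvec: np.ndarray, pairs, labels, config: TreeFitConfig) -> np.ndarray:
    if np.isscalar(config.n_replicates):
        nrep = np.full(len(dvec), float(config.n_replicates))
    else:
        nmat = np.asarray(config.n_replicates, dtype=float)
        nrep = np.array([nmat[i, j] for i, j in pairs])
    if config.power == 0.0:
        return nrep
    denom = np.maximum(dvec, config.zero_distance_epsilon)
    if np.any(dvec < config.zero_distance_epsilon):
        logger.warning(
            "zero off-diagonal distances replaced by epsilon=%g in weights",
            config.zero_distance_epsilon)
    return nrep / denom ** config.power


def _restrict(D: DistanceMatrix, labels: list[str]) -> DistanceMatrix:
    return D.filter(labels)


def fit_branch_lengths(topology: PhenoTree, D: DistanceMatrix,
                       config: TreeFitConfig | None = None) -> PhenoTree:
    """Fit branch lengths minimizing the weighted least-squares criterion.

    The fit is a linear least-squares problem on the path-incidence
    structure; with the default nonnegativity constraint it is solved by
    NNLS (equivalent to clamping negative solutions at zero and refitting).
    Returns a copy of the topology with lengths and ``sum_of_squares`` set.
    """
    cfg = config or TreeFitConfig()
    labels = sorted(topology.leaves())
    if len(labels) < 3:
        raise FitError("tree fitting requires >= 3 leaves")
    if set(labels) != set(D.ids):
        raise ConfigurationError(
            "tree leaves do not match distance-matrix labels")
    A, pairs, edge_list = _pair_incidence(topology, labels)
    dvec = np.array([D[labels[i], labels[j]] for i, j in pairs])
    w = _weights(dvec, pairs, labels, cfg)
    sw = np.sqrt(w)
    Aw = A * sw[:, None]
    bw = dvec * sw
    if cfg.allow_negative_branches:
        x, *_ = np.linalg.lstsq(Aw, bw, rcond=None)
    else:
        x, _ = nnls(Aw, bw)
    fitted = A @ x
    tree = topology.copy()
    for e, val in zip(edge_list, x):
        tree.length[e] = float(val)
    tree.sum_of_squares = float(np.sum(w * (dvec - fitted) ** 2))
    return tree


def sum_of_squares(D: DistanceMatrix, tree: PhenoTree,
                   config: TreeFitConfig | None = None) -> float:
    """Evaluate Σ_{i<j} n_ij (D_ij − d_ij)² / D_ij^P for the given tree."""
    cfg = config or TreeFitConfig()
    labels = sorted(tree.leaves())
    if set(labels) != set(D.ids):
        raise ConfigurationError("tree leaves do not match matrix labels")
    E = expected_distances(tree)
    pairs = [(i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    dvec = np.array([D[labels[i], labels[j]] for i, j in pairs])
    evec = np.array([E[labels[i], labels[j]] for i, j in pairs])
    w = _weights(dvec, pairs, labels, cfg)
    return float(np.sum(w * (dvec - evec) ** 2))


def enumerate_topologies(labels: list[str]) -> Iterator[PhenoTree]:
    """Yield every unrooted (binary) topology on the given leaf labels."""
    labels = sorted(labels)
    if len(labels) < 3:
        raise FitError("need >= 3 labels")

    def grow(tree: PhenoTree, remaining: list[str]) -> Iterator[PhenoTree]:
        if not remaining:
            yield tree
            return
        name, rest = remaining[0], remaining[1:]
        for edge in tree.edges():
            cand = tree.copy()
            _attach_leaf(cand, edge, name)
            yield from grow(cand, rest)

    yield from grow(_star3(labels[:3]), labels[3:])


def neighbor_joining_tree(D: DistanceMatrix) -> PhenoTree:
    """Agglomerative neighbor-joining topology (fast starting tree)."""
    sk = _skbio_nj(D)
    tree = PhenoTree()
    node_of: dict[int, int] = {}
    for sknode in sk.traverse(include_self=True):
        name = str(sknode.name) if sknode.is_tip() else None
        node_of[id(sknode)] = tree.add_node(name)
    for sknode in sk.traverse(include_self=False):
        parent = node_of[id(sknode.parent)]
        child = node_of[id(sknode)]
        tree.add_edge(parent, child, float(sknode.length or 0.0))
    _suppress_degree_two(tree)
    return tree


def _suppress_degree_two(tree: PhenoTree) -> None:
    for node in [u for u in list(tree.adj)
                 if tree.degree(u) == 2 and not tree.is_leaf(u)]:
        a, b = tuple(tree.adj[node])
        la = tree.length[frozenset((node, a))]
        lb = tree.length[frozenset((node, b))]
        tree.remove_edge(node, a)
        tree.remove_edge(node, b)
        tree.add_edge(a, b, la + lb)
        del tree.adj[node]


def _nni_candidates(tree: PhenoTree) -> Iterator[PhenoTree]:
    """The two nearest-neighbor interchanges around each internal edge."""
    for e in tree.edges():
        u, v = sorted(e)
        if tree.is_leaf(u) or tree.is_leaf(v):
            continue
        us = sorted(tree.adj[u] - {v})
        vs = sorted(tree.adj[v] - {u})
        if len(us) != 2 or len(vs) != 2:
            continue  # NNI is defined on binary internal edges
        a, b = us
        c, d = vs
        for x, y in ((b, c), (b, d)):
            cand = tree.copy()
            lx = cand.length[frozenset((u, x))]
            ly = cand.length[frozenset((v, y))]
            cand.remove_edge(u, x)
            cand.remove_edge(v, y)
            cand.add_edge(u, y, ly)
            cand.add_edge(v, x, lx)
            yield cand


_TOL = 1e-10


def _better(sos: float, key: tuple, best_sos: float, best_key: tuple) -> bool:
    if sos < best_sos - _TOL:
        return True
    return abs(sos - best_sos) <= _TOL and key < best_key


def fit_tree(D: DistanceMatrix, config: TreeFitConfig | None = None,
             *, search: str = "heuristic", start: str = "stepwise",
             max_nni_rounds: int = 200) -> PhenoTree:
    """Fit topology and branch lengths to a distance matrix.

    ``search='heuristic'`` (default): stepwise leaf addition in sorted label
    order, then NNI hill-climbing. ``search='exhaustive'``: score every
    unrooted topology (feasible up to ~7 leaves). ``start='nj'`` seeds the
    NNI refinement with a neighbor-joining topology instead of stepwise
    addition. Ties are broken by the lexicographically smallest canonical
    split set.
    """
    cfg = config or TreeFitConfig()
    labels = sorted(D.ids)
    if len(labels) < 3:
        raise FitError("tree fitting requires >= 3 labels")
    if len(labels) == 3:
        return fit_branch_lengths(_star3(labels), D, cfg)

    if search == "exhaustive":
        best = best_key = None
        for topo in enumerate_topologies(labels):
            cand = fit_branch_lengths(topo, D, cfg)
            key = _topology_key(cand)
            if best is None or _better(cand.sum_of_squares, key,
                                       best.sum_of_squares, best_key):
                best, best_key = cand, key
        return best
    if search != "heuristic":
        raise ConfigurationError(f"unknown search {search!r}")

    if start == "nj":
        tree = fit_branch_lengths(neighbor_joining_tree(D), D, cfg)
    elif start == "stepwise":
        tree = fit_branch_lengths(_star3(labels[:3]), _restrict(D, labels[:3]), cfg)
        for k in range(3, len(labels)):
            name = labels[k]
            sub = _restrict(D, labels[:k + 1])
            best = best_key = None
            for edge in tree.edges():
                topo = tree.copy()
                _attach_leaf(topo, edge, name)
                cand = fit_branch_lengths(topo, sub, cfg)
                key = _topology_key(cand)
                if best is None or _better(cand.sum_of_squares, key,
                                           best.sum_of_squares, best_key):
                    best, best_key = cand, key
            tree = best
    else:
        raise ConfigurationError(f"unknown start {start!r}")

    # NNI refinement
    best_key = _topology_key(tree)
    for _ in range(max_nni_rounds):
        improved = False
        for topo in _nni_candidates(tree):
            cand = fit_branch_lengths(topo, D, cfg)
            key = _topology_key(cand)
            if _better(cand.sum_of_squares, key, tree.sum_of_squares, best_key):
                tree, best_key = cand, key
                improved = True
                break
        if not improved:
            break
    return tree


# ---------------------------------------------------------------------------
# serialization

_PLAIN_LABEL_RE = re.compile(r"^[A-Za-z0-9_.\-|/]+$")


def _quote(label: str) -> str:
    if _PLAIN_LABEL_RE.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def to_newick(tree: PhenoTree, precision: int = 12) -> str:
    """Serialize as Newick, rooted for display at the internal node next to
    the lexicographically smallest leaf; children ordered deterministically."""
    labels = sorted(tree.leaves())
    leaf_of = tree.leaves()
    first = leaf_of[labels[0]]
    root = next(iter(tree.adj[first]))

    def min_desc(node: int, parent: int) -> str:
        if tree.is_leaf(node):
            return tree.leaf_name[node]
        return min(min_desc(c, node) for c in tree.adj[node] if c != parent)

    def rec(node: int, parent: int) -> str:
        length = tree.length[frozenset((node, parent))]
        tag = f":{length:.{precision}g}"
        if tree.is_leaf(node):
            return _quote(tree.leaf_name[node]) + tag
        kids = sorted((c for c in tree.adj[node] if c != parent),
                      key=lambda c: min_desc(c, node))
        return "(" + ",".join(rec(c, node) for c in kids) + ")" + tag

    kids = sorted(tree.adj[root], key=lambda c: min_desc(c, root))
    return "(" + ",".join(rec(c, root) for c in kids) + ");"


def write_newick(tree: PhenoTree, target, precision: int = 12) -> None:
    text = to_newick(tree, precision=precision) + "\n"
    if hasattr(target, "write"):
        target.write(text)
    else:
        with open(os.fspath(target), "w", encoding="utf-8") as fh:
            fh.write(text)


def write_distance_tsv(D: DistanceMatrix, target) -> None:
    """TSV matrix with a header row and a label column."""
    import pandas as pd

    df = pd.DataFrame(D.data, index=list(D.ids), columns=list(D.ids))
    if hasattr(target, "write"):
        df.to_csv(target, sep="\t")
    else:
        df.to_csv(os.fspath(target), sep="\t")


def read_distance_tsv(source) -> DistanceMatrix:
    import pandas as pd

    df = pd.read_csv(source, sep="\t", index_col=0, comment="#")
    M = df.to_numpy(dtype=float)
    M = (M + M.T) / 2.0
    np.fill_diagonal(M, 0.0)
    return DistanceMatrix(M, ids=[str(c) for c in df.columns])
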