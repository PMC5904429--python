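"""Neighbor-joining trees with nonparametric bootstrap support.

The tree is built by the classic Saitou–Nei agglomeration: at each step the
pair minimising the Q-criterion

    Q(i, j) = (N - 2) d(i, j) - r_i - r_j,   r_i = sum_k d(i, k)

is joined, branch lengths follow the standard three-point formulas, and the
reduced matrix uses d(u, k) = (d(i, k) + d(j, k) - d(i, j)) / 2.  NJ is
exact on additive matrices.  Ties in Q are broken by the lowest (i, j)
index pair in the current node ordering, so the result is deterministic.
Negative branch lengths are clamped to zero with the deficit moved to the
sister branch, preserving the path length through the join.

Bootstrap supports are percentages of column-resampled replicate trees that
contain each internal bipartition (unrooted split) of the reference tree;
they are keyed by split identity so rerooting never invalidates them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import numpy as np

from .distance import (
    DistanceMatrix,
    UndefinedDistanceError,
    _pair_tables,
    distance_matrix,
    distances_from_tables,
)
from .seqio import BarcodeAlignment

__all__ = [
    "PhyloTree",
    "nj",
    "bootstrap_support",
    "root_with_outgroup",
    "clade_support_by_species",
    "TRIVIALLY_MONOPHYLETIC",
    "NON_MONOPHYLETIC",
]

logger = logging.getLogger(__name__)

TRIVIALLY_MONOPHYLETIC = "trivially monophyletic"
NON_MONOPHYLETIC = "non-monophyletic"


@dataclass
class PhyloTree:
    """A phylogenetic tree plus bootstrap supports keyed by unrooted split.

    ``split_support`` maps each internal bipartition — canonicalised as the
    frozenset of leaf names on the side *not* containing the
    alphabetically-first leaf — to an integer bootstrap percentage.
    """

    tree: dendropy.Tree
    split_support: dict[frozenset, int] = field(default_factory=dict)

    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def canonical_split(self, side: Iterable[str]) -> frozenset:
        leaves = frozenset(self.leaf_names())
        side = frozenset(side)
        ref = min(leaves)
        return side if ref not in side else leaves - side

    def splits(self) -> set[frozenset]:
        """Non-trivial unrooted splits present in the tree."""
        leaves = frozenset(self.leaf_names())
        n = len(leaves)
        out: set[frozenset] = set()
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            side = frozenset(
                lf.taxon.label for lf in node.leaf_iter()
            )
            if 2 <= len(side) <= n - 2:
                out.add(self.canonical_split(side))
        return out


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def _nj_agglomerate(d0: np.ndarray):
    """Run NJ joins on a distance matrix.

    Returns ``(children, center_id)`` where ``children`` maps each internal
    node id to its list of (child id, branch length); leaf ids are
    0..n-1 and ``center_id`` is the final (trifurcating) node.
    """
    n0 = d0.shape[0]
    d = d0.astype(float).copy()
    node_ids = list(range(n0))
    children: dict[int, list[tuple[int, float]]] = {}
    next_id = n0
    while d.shape[0] > 3:
        m = d.shape[0]
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # row-major argmin gives the lowest (i, j) pair among ties
        i, j = divmod(int(np.argmin(q)), m)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj)
        children[next_id] = [(node_ids[i], li), (node_ids[j], lj)]
        dnew = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[: m - 2, : m - 2] = d[np.ix_(keep, keep)]
        d2[m - 2, : m - 2] = d2[: m - 2, m - 2] = dnew[keep]
        d2[m - 2, m - 2] = 0.0
        d = d2
        node_ids = [node_ids[k] for k in keep] + [next_id]
        next_id += 1
    # resolve the final three nodes around a central trifurcation
    a, b, c = node_ids
    la = max(0.0, 0.5 * (d[0, 1] + d[0, 2] - d[1, 2]))
    lb = max(0.0, 0.5 * (d[0, 1] + d[1, 2] - d[0, 2]))
    lc = max(0.0, 0.5 * (d[0, 2] + d[1, 2] - d[0, 1]))
    children[next_id] = [(a, la), (b, lb), (c, lc)]
    return children, next_id


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li = max(0.0, li + lj)
        lj = 0.0
    return li, lj


def nj(matrix: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree from a p-distance matrix (unrooted).

    Requires at least 3 taxa and finite distances; deterministic given the
    matrix (lowest-index tie-breaking).
    """
    n = len(matrix.ids)
    if n < 3:
        raise ValueError(f"neighbor joining needs >= 3 taxa, got {n}")
    if not np.all(np.isfinite(matrix.d)):
        raise ValueError("distance matrix contains non-finite values")
    children, center = _nj_agglomerate(matrix.d)
    taxa = dendropy.TaxonNamespace(matrix.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = False

    def build(node_id: int, length: float | None) -> dendropy.Node:
        node = dendropy.Node()
        node.edge.length = length
        if node_id < n:
            node.taxon = taxa.get_taxon(matrix.ids[node_id])
        else:
            for cid, cl in children[node_id]:
                node.add_child(build(cid, cl))
        return node

    seed = build(center, None)
    tree.seed_node = seed
    return PhyloTree(tree=tree)


def _nj_splits(d: np.ndarray) -> set[frozenset]:
    """Non-trivial splits of the NJ tree, as frozensets of leaf indices.

    Canonical side is the one not containing leaf 0.  Fast path used by the
    bootstrap, bypassing dendropy node construction.
    """
    n = d.shape[0]
    children, center = _nj_agglomerate(d)
    leafsets: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}

    def leafset(nid: int) -> frozenset:
        if nid not in leafsets:
            leafsets[nid] = frozenset().union(
                *(leafset(c) for c, _ in children[nid])
            )
        return leafsets[nid]

    full = frozenset(range(n))
    out: set[frozenset] = set()
    for nid in children:
        if nid == center:
            continue
        side = leafset(nid)
        if 2 <= len(side) <= n - 2:
            out.add(side if 0 not in side else full - side)
    # children of the center node also define splits
    for cid, _ in children[center]:
        side = leafset(cid)
        if 2 <= len(side) <= n - 2:
            out.add(side if 0 not in side else full - side)
    return out


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap_support(
    aln: BarcodeAlignment, replicates: int = 1000, seed: int = 0
) -> PhyloTree:
    """NJ reference tree with bootstrap percentages on internal splits.

    Columns are resampled with replacement to the original alignment length;
    each replicate's NJ tree is scored against the reference splits and the
    support of a split is the percentage of replicates containing it,
    rounded to the nearest integer.  A replicate whose resampled columns
    leave some pair with zero comparable sites is redrawn (up to
    ``10 * replicates`` attempts in total).  Reproducible given ``seed``;
    the random stream drives column indices only.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    ref = nj(distance_matrix(aln))
    enc = aln.encoded()
    n, L = enc.shape
    mm, vv, pairs = _pair_tables(enc)
    ids = aln.ids
    ref_splits = ref.splits()
    counts = {s: 0 for s in ref_splits}
    rng = np.random.default_rng(seed)
    done = 0
    attempts = 0
    max_attempts = 10 * replicates
    full_names = frozenset(ids)
    ref_leaf = min(full_names)
    while done < replicates:
        if attempts >= max_attempts:
            raise UndefinedDistanceError(
                f"exceeded {max_attempts} bootstrap attempts; alignment "
                "coverage too sparse for resampling"
            )
        attempts += 1
        cols = rng.integers(0, L, size=L)
        try:
            d, _ = distances_from_tables(mm, vv, pairs, n, columns=cols)
        except UndefinedDistanceError:
            logger.warning("bootstrap replicate redrawn: undefined distance")
            continue
        rep_splits = _nj_splits(d)
        for side in rep_splits:
            names = frozenset(ids[k] for k in side)
            if ref_leaf in names:
                names = full_names - names
            if names in counts:
                counts[names] += 1
        done += 1
    support = {
        s: int(round(100.0 * c / replicates)) for s, c in counts.items()
    }
    ref.split_support = support
    return ref


# ---------------------------------------------------------------------------
# rooting and per-species clade support
# ---------------------------------------------------------------------------


def root_with_outgroup(tree: PhyloTree, outgroup_ids: Iterable[str]) -> PhyloTree:
    """Reroot on the branch separating the outgroup set from the ingroup.

    If no edge induces exactly that bipartition, the tree is rooted at the
    edge that best separates outgroup from ingroup leaves (logged warning).
    """
    out = set(outgroup_ids)
    leaves = set(tree.leaf_names())
    unknown = out - leaves
    if unknown:
        raise KeyError(f"outgroup ids not in tree: {sorted(unknown)}")
    if out == leaves:
        raise ValueError("outgroup cannot contain every leaf")
    if not out:
        raise ValueError("outgroup set is empty")
    t = tree.tree.clone(depth=1)
    best_edge = None
    best_score = -1
    exact = None
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()}
        if side == out or (leaves - side) == out:
            exact = node.edge
            break
        score = max(
            len(side & out) + len((leaves - side) - out),
            len(side - out) + len((leaves - side) & out),
        )
        if score > best_score:
            best_score = score
            best_edge = node.edge
    edge = exact
    if edge is None:
        logger.warning(
            "outgroup %s is not monophyletic in the tree; rooting at the "
            "best-separating edge", sorted(out),
        )
        edge = best_edge
    el = edge.length or 0.0
    t.reroot_at_edge(edge, length1=el / 2.0, length2=el / 2.0)
    t.is_rooted = True
    return PhyloTree(tree=t, split_support=dict(tree.split_support))


def clade_support_by_species(
    tree: PhyloTree, labels: Mapping[str, str]
) -> dict[str, int | str]:
    """Bootstrap support of each species' clade, or a monophyly verdict.

    A species with >= 2 specimens is monophyletic iff the tree contains the
    split separating exactly its specimens from everything else; the value
    is then that split's support.  Singletons are reported as
    ``"trivially monophyletic"``.
    """
    leaves = tree.leaf_names()
    present_splits = tree.splits()
    by_species: dict[str, list[str]] = {}
    for lf in leaves:
        by_species.setdefault(labels[lf], []).append(lf)
    out: dict[str, int | str] = {}
    for sp, members in by_species.items():
        if len(members) == 1:
            out[sp] = TRIVIALLY_MONOPHYLETIC
            continue
        if len(members) >= len(leaves) - 1:
            # the complement has <= 1 leaf: the split is trivial and the
            # species is monophyletic in the unrooted sense by construction
            out[sp] = TRIVIALLY_MONOPHYLETIC
            continue
        split = tree.canonical_split(members)
        if split in present_splits:
            out[sp] = tree.split_support.get(split, 0)
        else:
            out[sp] = NON_MONOPHYLETIC
    return out
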