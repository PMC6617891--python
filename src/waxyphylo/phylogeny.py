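"""Neighbor-joining on uncorrected-P distances with bootstrap supports.

Trees are ``dendropy.Tree`` objects.  Bootstrap supports are percentages
in [0, 100] stored as internal-node labels, which is also how they are
written to and read from Newick.  The NJ implementation is the standard
Saitou–Nei agglomeration on the Q-criterion with deterministic
lowest-index tie-breaking; negative branch-length estimates are clamped
to zero with the deficit transferred to the sister edge so that the
joined pair's distance is preserved.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Literal

import dendropy
import numpy as np

from .seqstats import Alignment, DistanceMatrix, UndefinedDistanceError, distance_matrix

__all__ = [
    "RootingError",
    "nj_tree",
    "bootstrap_support",
    "root_with_outgroup",
    "clade_support",
    "node_leaf_labels",
    "tree_bipartitions",
    "node_support",
]


class RootingError(ValueError):
    """Raised when the requested outgroup is not a clade of the tree."""


# ---------------------------------------------------------------------------
# tree helpers
# ---------------------------------------------------------------------------

def node_leaf_labels(node: dendropy.Node) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def node_support(node: dendropy.Node) -> float | None:
    """Bootstrap support parsed from an internal node's label, if any."""
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Internal-edge bipartitions, each canonicalised as the leaf-set side
    that excludes the lexicographically smallest leaf label."""
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    anchor = min(all_leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = node_leaf_labels(node)
        if anchor in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            splits.add(side)
    return splits


def _support_map(tree: dendropy.Tree) -> dict[frozenset[str], float]:
    """Bipartition → support, for restoring labels after rerooting."""
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    anchor = min(all_leaves)
    out: dict[frozenset[str], float] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        support = node_support(node)
        if support is None:
            continue
        side = node_leaf_labels(node)
        if anchor in side:
            side = all_leaves - side
        out[side] = support
    return out


def _restore_supports(tree: dendropy.Tree, supports: dict[frozenset[str], float]) -> None:
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    anchor = min(all_leaves)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = node_leaf_labels(node)
        if anchor in side:
            side = all_leaves - side
        support = supports.get(side)
        node.label = _format_support(support) if support is not None else None


def _format_support(value: float) -> str:
    return f"{value:g}"


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(d: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining; returns an unrooted tree whose seed
    node is the conventional trifurcation."""
    n = len(d.ids)
    if n < 3:
        raise ValueError(f"neighbor joining needs >= 3 taxa, got {n}")
    dist = np.asarray(d.values, dtype=float).copy()
    if np.isnan(dist).any():
        raise ValueError("distance matrix contains NaN")

    namespace = dendropy.TaxonNamespace(list(d.ids))
    nodes: list[dendropy.Node] = []
    for label in d.ids:
        node = dendropy.Node()
        node.taxon = namespace.get_taxon(label)
        nodes.append(node)
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        # upper triangle only (q is symmetric up to float rounding)
        q[np.tril_indices(m)] = np.inf
        qmin = q.min()
        # lowest-index tie-break over *mathematical* ties: at the
        # four-cluster stage complementary pairs always share the same
        # Q, equal only up to rounding, so ties are detected with a
        # small tolerance rather than exact float equality
        tol = 1e-9 * (1.0 + abs(qmin))
        ti, tj = min((int(a), int(b)) for a, b in np.argwhere(q <= qmin + tol))
        dij = sub[ti, tj]
        vi = 0.5 * dij + (r[ti] - r[tj]) / (2.0 * (m - 2))
        vj = dij - vi
        if vi < 0.0:
            vi, vj = 0.0, dij
        elif vj < 0.0:
            vi, vj = dij, 0.0
        i_idx, j_idx = active[ti], active[tj]
        parent = dendropy.Node()
        child_i, child_j = nodes[i_idx], nodes[j_idx]
        child_i.edge.length = vi
        child_j.edge.length = vj
        parent.add_child(child_i)
        parent.add_child(child_j)
        # distances from the new node to all remaining clusters
        new_row = 0.5 * (
            dist[i_idx, active] + dist[j_idx, active] - dij
        )
        nodes.append(parent)
        dist = np.pad(dist, ((0, 1), (0, 1)), constant_values=0.0)
        new_idx = dist.shape[0] - 1
        # reduced distances are bookkeeping and may go negative; only
        # branch lengths are clamped
        for pos, k in enumerate(active):
            dist[new_idx, k] = dist[k, new_idx] = new_row[pos]
        dist[new_idx, new_idx] = 0.0
        active = [k for k in active if k not in (i_idx, j_idx)] + [new_idx]

    # final trifurcation: closed-form pendant lengths
    a, b, c = active
    va = max(0.5 * (dist[a, b] + dist[a, c] - dist[b, c]), 0.0)
    vb = max(0.5 * (dist[a, b] + dist[b, c] - dist[a, c]), 0.0)
    vc = max(0.5 * (dist[a, c] + dist[b, c] - dist[a, b]), 0.0)
    root = dendropy.Node()
    for idx, length in ((a, va), (b, vb), (c, vc)):
        nodes[idx].edge.length = length
        root.add_child(nodes[idx])
    tree = dendropy.Tree(taxon_namespace=namespace)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# nonparametric bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(
    aln: Alignment,
    n_reps: int = 1000,
    seed: int = 0,
    deletion: Literal["pairwise", "complete"] = "pairwise",
) -> dendropy.Tree:
    """NJ tree with bootstrap supports from column resampling.

    Columns are resampled with replacement ``n_reps`` times; the support
    of an internal edge is the percentage of successful replicates whose
    NJ tree contains the same bipartition.  Replicates in which some
    pair of sequences has no comparable sites are skipped and counted; a
    warning is issued when more than 5% are skipped.
    """
    if aln.n_sequences < 3:
        raise ValueError("bootstrap needs >= 3 sequences")
    # canonical row order → supports invariant to input leaf order
    order = sorted(range(aln.n_sequences), key=lambda i: aln.ids[i])
    aln = Alignment(tuple(aln.ids[i] for i in order), aln.matrix[order])
    base = nj_tree(distance_matrix(aln, deletion))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    successful = 0
    skipped = 0
    for _ in range(n_reps):
        cols = rng.integers(0, aln.n_columns, size=aln.n_columns)
        replicate = aln.columns(cols)
        try:
            rep_tree = nj_tree(distance_matrix(replicate, deletion))
        except UndefinedDistanceError:
            skipped += 1
            continue
        successful += 1
        for split in tree_bipartitions(rep_tree):
            counts[split] = counts.get(split, 0) + 1
    if n_reps and skipped > 0.05 * n_reps:
        warnings.warn(
            f"{skipped}/{n_reps} bootstrap replicates skipped "
            "(undefined distances)", RuntimeWarning, stacklevel=2,
        )
    all_leaves = frozenset(aln.ids)
    anchor = min(all_leaves)
    for node in base.preorder_node_iter():
        if node.is_leaf() or node is base.seed_node:
            continue
        side = node_leaf_labels(node)
        if anchor in side:
            side = all_leaves - side
        pct = 100.0 * counts.get(side, 0) / successful if successful else 0.0
        node.label = _format_support(pct)
    return base


# ---------------------------------------------------------------------------
# rooting and clade queries
# ---------------------------------------------------------------------------

def root_with_outgroup(
    tree: dendropy.Tree, outgroup: Iterable[str]
) -> dendropy.Tree:
    """Root on the edge separating the outgroup from the ingroup.

    The outgroup must form one side of an edge of the unrooted tree;
    bootstrap supports are re-attached to the same bipartitions after
    rerooting.  The input tree is left untouched.
    """
    out_set = frozenset(outgroup)
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    unknown = out_set - all_leaves
    if unknown:
        raise RootingError(f"outgroup leaves not in tree: {sorted(unknown)}")
    if not out_set or out_set == all_leaves:
        raise RootingError("outgroup must be a proper non-empty leaf subset")
    supports = _support_map(tree)
    work = tree.clone(depth=1)
    target = None
    for node in work.preorder_node_iter():
        if node is work.seed_node:
            continue
        side = node_leaf_labels(node)
        if side == out_set or side == all_leaves - out_set:
            target = node
            break
    if target is None:
        raise RootingError(
            f"outgroup {sorted(out_set)} is not monophyletic in the "
            f"unrooted tree (no edge with this bipartition)"
        )
    edge = target.edge
    half = (edge.length or 0.0) / 2.0
    work.reroot_at_edge(edge, length1=half, length2=half, update_bipartitions=False)
    work.is_rooted = True
    _restore_supports(work, supports)
    return work


NOT_A_CLADE = None


def clade_support(tree: dendropy.Tree, leaves: Iterable[str]) -> float | None:
    """Support of the clade with exactly this leaf set, else ``None``.

    The full leaf set (the root) is not a clade of any internal edge and
    returns the not-a-clade sentinel.  A clade that exists but carries
    no support value returns ``nan``.
    """
    wanted = frozenset(leaves)
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    unknown = wanted - all_leaves
    if unknown:
        raise KeyError(f"unknown leaf label(s): {sorted(unknown)}")
    if wanted == all_leaves:
        return NOT_A_CLADE
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node_leaf_labels(node) == wanted:
            if node.is_leaf():
                return NOT_A_CLADE  # pendant edges carry no clade support
            support = node_support(node)
            return support if support is not None else float("nan")
    return NOT_A_CLADE
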