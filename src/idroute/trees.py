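"""Distance-based trees and split (bipartition) comparison.

The invasion-route pipeline turns a Jost's D distance matrix into an
unrooted BIONJ tree and scores it against the expected invasion topology
(the caterpillar FL -> 1 -> ... -> k) by the number of shared nontrivial
splits.  A fully resolved unrooted tree on n tips has n - 3 nontrivial
splits, so n - 3 is the maximum attainable score.

Also here: random-tree null generators (two flavours, see
:func:`random_tree`), majority-rule bootstrap consensus over resampled ID
alleles, and classical (Torgerson) multidimensional scaling.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa

from .fingerprint import FL_LABEL, FrequencyMatrix, jost_d_pair

__all__ = [
    "bionj",
    "tree_splits",
    "shared_splits",
    "expected_invasion_tree",
    "random_tree",
    "sample_null_shared_splits",
    "bootstrap_consensus",
    "classical_mds",
    "tree_from_splits",
]


# ---------------------------------------------------------------------------
# BIONJ (Gascuel 1997)
# ---------------------------------------------------------------------------


def _coerce_distance(D):
    if isinstance(D, DistanceMatrix):
        return list(D.ids), np.array(D.data, dtype=float)
    labels, arr = D
    return list(labels), np.array(arr, dtype=float)


def bionj(D) -> dendropy.Tree:
    """Build an unrooted tree with the BIONJ agglomeration.

    BIONJ uses the neighbor-joining selection criterion but reduces the
    distance matrix with a variance-weighted average: the reduction weight
    lambda is chosen to minimize the variance of the reduced matrix, with
    first-order variances V_ij proportional to D_ij.  Deterministic given D
    (ties broken by the lowest index pair); negative branch lengths are kept
    as computed.

    ``D`` is a ``skbio.DistanceMatrix`` or a ``(labels, square_array)``
    pair.
    """
    labels, d = _coerce_distance(D)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least three taxa")
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    d = 0.5 * (d + d.T)
    v = d.copy()  # first-order variances are proportional to distances

    tns = dendropy.TaxonNamespace([str(l) for l in labels])
    nodes = [dendropy.Node(taxon=tns.get_taxon(str(l))) for l in labels]
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        idx = np.array(active)
        sub = d[np.ix_(idx, idx)]
        s = sub.sum(axis=1)
        q = (r - 2) * sub - s[:, None] - s[None, :]
        np.fill_diagonal(q, np.inf)
        # argmin is row-major, i.e. the lowest (i, j) pair on exact ties
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, r)
        if ai > aj:
            ai, aj = aj, ai
        i, j = idx[ai], idx[aj]

        dij = d[i, j]
        li = 0.5 * dij + (s[ai] - s[aj]) / (2.0 * (r - 2))
        lj = dij - li

        vij = v[i, j]
        others = [k for k in active if k != i and k != j]
        if vij > 0 and others:
            lam = 0.5 + (v[j, others].sum() - v[i, others].sum()) / (2.0 * (r - 2) * vij)
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5

        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = float(li)
        parent.add_child(nodes[j])
        nodes[j].edge.length = float(lj)

        # reduction
        dk = lam * (d[i, :] - li) + (1 - lam) * (d[j, :] - lj)
        vk = lam * v[i, :] + (1 - lam) * v[j, :] - lam * (1 - lam) * vij
        d[i, :] = dk
        d[:, i] = dk
        d[i, i] = 0.0
        v[i, :] = vk
        v[:, i] = vk
        v[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    center = dendropy.Node()
    for k, lk in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[k])
        nodes[k].edge.length = float(lk)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


def _leaf_labels(tree: dendropy.Tree) -> list:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def tree_splits(tree: dendropy.Tree) -> set:
    """Nontrivial bipartitions of an (unrooted) tree as canonical
    frozensets of tip labels: each split is stored as the side *not*
    containing the lexicographically smallest tip."""
    labels = set(_leaf_labels(tree))
    n = len(labels)
    ref = min(labels)
    splits = set()
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
            continue
        cl = frozenset().union(*(below[ch] for ch in node.child_nodes()))
        below[node] = cl
        if node.parent_node is None:
            continue
        canon = labels - cl if ref in cl else cl
        if 2 <= len(canon) <= n - 2:
            splits.add(frozenset(canon))
    return splits


def shared_splits(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Number of nontrivial bipartitions shared by two trees on the same
    tip set."""
    l1, l2 = set(_leaf_labels(t1)), set(_leaf_labels(t2))
    if l1 != l2:
        raise ValueError("trees must share an identical tip set")
    return len(tree_splits(t1) & tree_splits(t2))


def expected_invasion_tree(labels: Sequence) -> dendropy.Tree:
    """Caterpillar (ladder) tree following the given invasion order, unit
    branch lengths.  Its splits are exactly the prefixes of the order of
    sizes 2 .. n-2."""
    labels = [str(l) for l in labels]
    if len(labels) < 4:
        raise ValueError("need at least four labels")
    tns = dendropy.TaxonNamespace(labels)
    node = dendropy.Node(taxon=tns.get_taxon(labels[0]))
    for lab in labels[1:]:
        parent = dendropy.Node()
        parent.add_child(node)
        node.edge.length = 1.0
        leaf = dendropy.Node(taxon=tns.get_taxon(lab))
        parent.add_child(leaf)
        leaf.edge.length = 1.0
        node = parent
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=node)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# random trees
# ---------------------------------------------------------------------------


def _recursive_split_clades(mask: int, k: int, bit_of: np.ndarray,
                            rng: np.random.Generator, out: list) -> None:
    """Recursively bipartition the label bitmask ``mask`` (k set bits) by
    assigning each label independently to one of two sides, redrawing when a
    side is empty; records every proper clade mask in ``out``."""
    if k == 1:
        return
    idx = bit_of[: k]
    while True:
        coins = rng.integers(0, 2, size=k)
        n1 = int(coins.sum())
        if 0 < n1 < k:
            break
    left = 0
    right = 0
    lbits = []
    rbits = []
    for b, c in zip(idx, coins):
        if c:
            left |= 1 << b
            lbits.append(b)
        else:
            right |= 1 << b
            rbits.append(b)
    out.append(left)
    out.append(right)
    _recursive_split_clades(left, len(lbits), np.array(lbits), rng, out)
    _recursive_split_clades(right, len(rbits), np.array(rbits), rng, out)


class _UNode:
    __slots__ = ("children", "leaf")

    def __init__(self, leaf=None):
        self.children = []
        self.leaf = leaf


def _uniform_addition_tree(n: int, rng: np.random.Generator) -> _UNode:
    """Stepwise random taxon addition onto a uniformly chosen edge: uniform
    over labeled unrooted binary topologies."""
    root = _UNode()
    for i in range(3):
        root.children.append(_UNode(leaf=i))
    edges = [(root, 0), (root, 1), (root, 2)]  # (parent, child slot)
    for leaf in range(3, n):
        parent, slot = edges[int(rng.integers(0, len(edges)))]
        old = parent.children[slot]
        mid = _UNode()
        mid.children = [old, _UNode(leaf=leaf)]
        parent.children[slot] = mid
        # (parent, slot) now denotes the edge parent-mid; the two new edges
        # are mid-old and mid-leaf
        edges.append((mid, 0))
        edges.append((mid, 1))
    return root


def _unode_clades(node: _UNode, out: list) -> int:
    if node.leaf is not None:
        return 1 << node.leaf
    mask = 0
    for ch in node.children:
        mask |= _unode_clades(ch, out)
    out.append(mask)
    return mask


def _canonical_splits(clades, n: int) -> set:
    full = (1 << n) - 1
    out = set()
    for m in clades:
        if m & 1:  # canonical side excludes label bit 0
            m = full & ~m
        k = m.bit_count()
        if 2 <= k <= n - 2:
            out.add(m)
    return out


def _topology_splits(labels_n: int, rng: np.random.Generator, method: str) -> set:
    if method == "recursive-split":
        clades: list = []
        _recursive_split_clades((1 << labels_n) - 1, labels_n,
                                np.arange(labels_n), rng, clades)
    elif method == "uniform-addition":
        root = _uniform_addition_tree(labels_n, rng)
        clades = []
        _unode_clades(root, clades)
    else:
        raise ValueError(f"unknown method {method!r}")
    return _canonical_splits(clades, labels_n)


def random_tree(
    labels: Sequence,
    rng: np.random.Generator,
    method: str = "recursive-split",
) -> dendropy.Tree:
    """Random unrooted binary tree on the given tips.

    ``"recursive-split"`` recursively partitions the label set by assigning
    each label independently to one of two sides (redrawing empty sides);
    this mirrors common recursive random-tree generators and is the default
    null.  ``"uniform-addition"`` is stepwise random addition onto a
    uniformly chosen edge and is uniform over labeled topologies.
    """
    labels = [str(l) for l in labels]
    n = len(labels)
    if n < 4:
        raise ValueError("need at least four labels")
    tns = dendropy.TaxonNamespace(labels)

    if method == "recursive-split":
        def build(members):
            if len(members) == 1:
                return dendropy.Node(taxon=tns.get_taxon(members[0]))
            while True:
                coins = rng.integers(0, 2, size=len(members))
                if 0 < coins.sum() < len(members):
                    break
            left = [m for m, c in zip(members, coins) if c]
            right = [m for m, c in zip(members, coins) if not c]
            node = dendropy.Node()
            node.add_child(build(left))
            node.add_child(build(right))
            return node

        seed = build(labels)
    elif method == "uniform-addition":
        root = _uniform_addition_tree(n, rng)

        def convert(un):
            if un.leaf is not None:
                return dendropy.Node(taxon=tns.get_taxon(labels[un.leaf]))
            node = dendropy.Node()
            for ch in un.children:
                node.add_child(convert(ch))
            return node

        seed = convert(root)
    else:
        raise ValueError(f"unknown method {method!r}")
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=seed)
    tree.is_rooted = False
    return tree


def sample_null_shared_splits(
    labels: Sequence,
    n_trees: int,
    rng: np.random.Generator,
    method: str = "recursive-split",
) -> np.ndarray:
    """Shared-split counts between ``n_trees`` random trees and the
    caterpillar over ``labels`` (the expected invasion tree).

    Fast bitmask path equivalent to calling :func:`random_tree` +
    :func:`shared_splits` per tree.
    """
    n = len(labels)
    if n < 4:
        raise ValueError("need at least four labels")
    # caterpillar splits = prefixes of the order, canonicalized on bit 0
    full = (1 << n) - 1
    cat = set()
    pref = 0
    for i in range(n - 2):
        pref |= 1 << i
        if i >= 1:
            cat.add(full & ~pref)  # prefix contains bit 0 -> take complement
    counts = np.empty(n_trees, dtype=np.int64)
    for t in range(n_trees):
        counts[t] = len(_topology_splits(n, rng, method) & cat)
    return counts


# ---------------------------------------------------------------------------
# consensus from bootstrapped ID alleles
# ---------------------------------------------------------------------------


def tree_from_splits(
    labels: Sequence,
    splits: dict,
) -> dendropy.Tree:
    """Assemble a (possibly multifurcating) tree from pairwise-compatible
    canonical splits.

    ``splits`` maps each split (frozenset of labels, not containing the
    reference = smallest label) to its support in [0, 1]; supports are
    stored as internal node labels.
    """
    labels = [str(l) for l in labels]
    tns = dendropy.TaxonNamespace(labels)
    items = sorted(splits.items(), key=lambda kv: len(kv[0]))
    nodes = {}
    for lab in labels:
        nodes[frozenset([lab])] = dendropy.Node(taxon=tns.get_taxon(lab))
    placed: dict = {}  # element set -> node, for assembled clades
    placed.update(nodes)
    for cl, support in items:
        node = dendropy.Node()
        node.label = f"{support:.2f}"
        # children: maximal already-built clades inside cl
        remaining = set(cl)
        for sub in sorted(placed, key=len, reverse=True):
            if sub <= remaining:
                node.add_child(placed[sub])
                remaining -= sub
                del placed[sub]
        if remaining:
            raise ValueError("splits are not pairwise compatible")
        placed[frozenset(cl)] = node
    root = dendropy.Node()
    for sub in sorted(placed, key=lambda s: sorted(s)):
        root.add_child(placed[sub])
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def bootstrap_consensus(
    matrix: FrequencyMatrix,
    B: int = 100,
    threshold: float = 0.5,
    rng: Optional[np.random.Generator] = None,
):
    """Majority-rule consensus of ``B`` BIONJ trees built from bootstrapped
    ID alleles.

    Each replicate resamples the ID allele columns with replacement (same
    count), recomputes the FL column as the complement (renormalizing the
    row when the resampled frequencies exceed 1), rebuilds the Jost's D
    matrix and the BIONJ tree.  Splits occurring in more than ``threshold``
    of the successful replicates are retained, annotated with their support
    fraction; everything else collapses into multifurcations.

    Returns ``(consensus_tree, support_by_split)``.
    """
    rng = rng if rng is not None else np.random.default_rng()
    samples = matrix.samples
    if len(samples) < 4:
        raise ValueError("need at least four samples")
    ids = matrix.id_table().to_numpy(dtype=float)
    n_ids = ids.shape[1]
    if n_ids < 2:
        raise ValueError("need at least two ID alleles to bootstrap")
    counts: dict = {}
    successful = 0
    skipped = 0
    for _b in range(B):
        take = rng.integers(0, n_ids, size=n_ids)
        boot = ids[:, take]
        fl = 1.0 - boot.sum(axis=1)
        rows = np.hstack([boot, fl[:, None]])
        neg = fl < 0
        if neg.any():
            rows[neg, -1] = 0.0
            rows[neg] /= rows[neg].sum(axis=1, keepdims=True)
        if np.allclose(rows, rows[0], atol=1e-12):
            skipped += 1
            continue
        n = len(samples)
        dm = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dm[i, j] = dm[j, i] = jost_d_pair(rows[i], rows[j])
        tree = bionj(([str(s) for s in samples], dm))
        successful += 1
        for sp in tree_splits(tree):
            counts[sp] = counts.get(sp, 0) + 1
    if skipped:
        warnings.warn(f"skipped {skipped} degenerate bootstrap replicates")
    if successful < B / 2:
        raise RuntimeError(
            f"only {successful}/{B} bootstrap replicates were usable"
        )
    majority = {
        sp: c / successful for sp, c in counts.items() if c / successful > threshold
    }
    tree = tree_from_splits([str(s) for s in samples], majority)
    return tree, majority


# ---------------------------------------------------------------------------
# classical MDS
# ---------------------------------------------------------------------------


def classical_mds(D, k: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) multidimensional scaling: double-center the
    squared distances, eigendecompose, and keep the top-k axes with
    positive eigenvalues.  Returns a samples x axes coordinate table
    centered at the origin; fewer than ``k`` axes are returned (with a
    warning) if fewer positive eigenvalues exist."""
    if not isinstance(D, DistanceMatrix):
        labels, arr = _coerce_distance(D)
        D = DistanceMatrix(np.asarray(arr, dtype=float), ids=[str(l) for l in labels])
    with warnings.catch_warnings():
        # Jost's D matrices are not Euclidean; moderately negative
        # eigenvalues are expected and the corresponding axes are discarded
        warnings.filterwarnings(
            "ignore", message=".*negative eigenvalues.*", category=RuntimeWarning)
        res = pcoa(D, method="eigh", number_of_dimensions=0)
    eig = res.eigvals.to_numpy()
    pos = int((eig > 1e-12).sum())
    kept = min(k, pos)
    if kept < k:
        warnings.warn(f"only {kept} positive eigenvalues; returning {kept} axes")
    coords = res.samples.iloc[:, :kept].copy()
    coords.columns = [f"MDS{i + 1}" for i in range(kept)]
    coords.index = list(D.ids)
    return coords
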