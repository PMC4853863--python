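"""UPGMA tree construction and Robinson-Foulds split distance.

Distances are one minus identity/100 (marker identity or AAI).  UPGMA
agglomerates with size-weighted arithmetic-mean linkage, places each merge at
half the cluster distance (so trees are ultrametric), breaks ties toward the
lexicographically smallest merged-label pair, and collapses internal edges of
(numerically) zero length into multifurcations — an all-equal distance matrix
therefore yields a star tree rather than an arbitrary resolution.

Split distance treats rooted trees as unrooted: the raw value counts
non-trivial bipartitions present in exactly one tree; the normalized value
divides by the total number of non-trivial bipartitions in both trees
(0/0 is defined as 0, i.e. two stars are identical).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .errors import IncompatibleTreesError, InsufficientDataError, InvalidMatrixError

_COLLAPSE_TOL = 1e-12


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise InvalidMatrixError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise InvalidMatrixError("matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise InvalidMatrixError("diagonal must be zero")
        if np.any(self.d < 0):
            raise InvalidMatrixError("distances must be nonnegative")


def identity_to_distance(
    values: dict[tuple[str, str], float], labels: list[str] | None = None
) -> DistanceMatrix:
    """Build d[i][j] = 1 - value/100 from per-pair percent values.

    ``values`` maps unordered genome pairs to percent identity or AAI; every
    pair among ``labels`` (default: all genomes appearing in the map) must be
    present, else the matrix is incomplete.
    """
    canon = {}
    for (a, b), v in values.items():
        if a == b:
            continue
        canon[(a, b) if a < b else (b, a)] = v
    if labels is None:
        labels = sorted({g for pair in canon for g in pair})
    n = len(labels)
    d = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            b = labels[j]
            key = (a, b) if a < b else (b, a)
            if key not in canon:
                raise InsufficientDataError(f"missing pair value for {key}")
            v = canon[key]
            if np.isnan(v):
                raise InsufficientDataError(f"missing pair value for {key}")
            d[i, j] = d[j, i] = 1.0 - v / 100.0
    return DistanceMatrix(labels=list(labels), d=d)


def upgma(dm: DistanceMatrix) -> dendropy.Tree:
    """Size-weighted UPGMA with deterministic smallest-label tie-breaking."""
    n = len(dm.labels)
    if n < 2:
        raise InvalidMatrixError("need at least two labels")
    # active clusters: key -> (smallest member label, size, height, newick)
    labels = list(dm.labels)
    dist: dict[frozenset, float] = {}
    clusters: dict[int, dict] = {
        i: {"label": labels[i], "size": 1, "height": 0.0, "node": (labels[i],)}
        for i in range(n)
    }
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((i, j))] = float(dm.d[i, j])

    newick_parts: dict[int, str] = {i: None for i in range(n)}
    # build nested structure as (children...) tuples with heights
    struct: dict[int, object] = {i: labels[i] for i in range(n)}
    heights: dict[int, float] = {i: 0.0 for i in range(n)}
    next_id = n
    while len(clusters) > 1:
        # find minimal distance; ties -> smallest (min label, max label)
        best = None
        for key, d in dist.items():
            i, j = sorted(key)
            la, lb = sorted((clusters[i]["label"], clusters[j]["label"]))
            cand = (d, la, lb, i, j)
            if best is None or cand[:3] < best[:3]:
                best = cand
        d, _, _, i, j = best
        h = d / 2.0
        new = next_id
        next_id += 1
        clusters[new] = {
            "label": min(clusters[i]["label"], clusters[j]["label"]),
            "size": clusters[i]["size"] + clusters[j]["size"],
            "height": h,
        }
        struct[new] = (struct[i], struct[j])
        heights[new] = h
        # average linkage update (size-weighted)
        for k in list(clusters):
            if k in (i, j, new):
                continue
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            ni, nj = clusters[i]["size"], clusters[j]["size"]
            dist[frozenset((new, k))] = (ni * dik + nj * djk) / (ni + nj)
        dist.pop(frozenset((i, j)))
        del clusters[i], clusters[j]

    root_id = next_id - 1

    # emit newick with edge lengths from height differences, collapsing
    # zero-length internal edges into multifurcations
    def emit(node, parent_height) -> list[str]:
        """Returns a list of newick fragments to splice into the parent."""
        if isinstance(node, str):
            return [f"{node}:{parent_height:.12g}"]
        # find this internal node's height: walk struct/heights via identity
        h = _height_of(node)
        edge = parent_height - h
        children = []
        for c in node:
            children.extend(emit(c, h))
        if edge <= _COLLAPSE_TOL:
            return children  # collapse zero-length internal edge into parent
        inner = ",".join(children)
        return [f"({inner}):{edge:.12g}"]

    height_by_struct = {}

    def _register(sid):
        s = struct[sid]
        if not isinstance(s, str):
            height_by_struct[id(s)] = heights[sid]

    for sid in struct:
        _register(sid)

    def _height_of(node):
        return height_by_struct[id(node)]

    root_struct = struct[root_id]
    root_h = heights[root_id]
    children = []
    for c in root_struct:
        children.extend(emit(c, root_h))
    text = f"({','.join(children)});"
    tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    return tree


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial splits of the unrooted tree, each canonicalized to the
    side not containing the lexicographically smallest leaf."""
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    n = len(leaves)
    ref = leaves[0]
    all_leaves = set(leaves)
    splits: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        clade = {l.taxon.label for l in node.leaf_iter()}
        if len(clade) < 2 or len(clade) > n - 2:
            continue
        side = all_leaves - clade if ref in clade else clade
        if 2 <= len(side) <= n - 2:
            splits.add(frozenset(side))
    return splits


def split_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> tuple[int, float]:
    """(raw, normalized) Robinson-Foulds split distance between two trees
    on the same leaf set."""
    l1 = sorted(l.taxon.label for l in t1.leaf_node_iter())
    l2 = sorted(l.taxon.label for l in t2.leaf_node_iter())
    if l1 != l2:
        raise IncompatibleTreesError(
            f"leaf sets differ: {len(l1)} vs {len(l2)} leaves"
        )
    s1 = tree_bipartitions(t1)
    s2 = tree_bipartitions(t2)
    raw = len(s1 ^ s2)
    total = len(s1) + len(s2)
    return raw, (raw / total if total else 0.0)


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-9) -> bool:
    depths = []
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    dmax = max(depths)
    if dmax == 0:
        return True
    return (dmax - min(depths)) <= rel_tol * dmax


def root_to_leaf_depths(tree: dendropy.Tree) -> dict[str, float]:
    out = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        out[leaf.taxon.label] = d
    return out
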