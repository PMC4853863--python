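"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's dynamic-programming and tree code:
alignment optima are found by exhaustive enumeration of alignments, and
split distances by direct bipartition-set comparison on nested-tuple tree
representations.
"""

from __future__ import annotations

import itertools
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def pair_score(x: str, y: str, scheme) -> float:
    if scheme.kind == "nucleotide":
        return scheme.match if (x == y and x != "N") else scheme.mismatch
    return float(_BLOSUM62[x, y])


def brute_force_global(a: str, b: str, scheme) -> float:
    """Maximum global alignment score by exhaustive enumeration.

    Gap convention: a gap of length k costs gap_open + (k-1) * gap_extend,
    applied per maximal gap run (end gaps included), matching the package's
    affine scoring.  States: 0 = last column was a substitution, 1 = gap in b
    (a consumed), 2 = gap in a (b consumed).
    """
    go, ge = scheme.gap_open, scheme.gap_extend

    best = [float("-inf")]

    def rec(i: int, j: int, state: int, score: float):
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, 0, score + pair_score(a[i], b[j], scheme))
        if i < len(a):
            cost = ge if state == 1 else go
            rec(i + 1, j, 1, score - cost)
        if j < len(b):
            cost = ge if state == 2 else go
            rec(i, j + 1, 2, score - cost)

    rec(0, 0, 0, 0.0)
    return best[0]


def brute_force_local(a: str, b: str, scheme) -> float:
    """Maximum local alignment score: best global score over all pairs of
    contiguous substrings, floored at zero (the empty alignment)."""
    best = 0.0
    for i0, i1 in itertools.combinations(range(len(a) + 1), 2):
        for j0, j1 in itertools.combinations(range(len(b) + 1), 2):
            s = brute_force_global(a[i0:i1], b[j0:j1], scheme)
            if s > best:
                best = s
    return best


def brute_force_global_max_identity(a: str, b: str, scheme) -> float:
    """Percent identity (identical columns / all columns) maximized over all
    score-optimal global alignments."""
    go, ge = scheme.gap_open, scheme.gap_extend
    results: list[tuple[float, int, int]] = []  # (score, identical, columns)

    def rec(i, j, state, score, ident, cols):
        if i == len(a) and j == len(b):
            results.append((score, ident, cols))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, 0, score + pair_score(a[i], b[j], scheme),
                ident + (1 if a[i] == b[j] else 0), cols + 1)
        if i < len(a):
            rec(i + 1, j, 1, score - (ge if state == 1 else go), ident, cols + 1)
        if j < len(b):
            rec(i, j + 1, 2, score - (ge if state == 2 else go), ident, cols + 1)

    rec(0, 0, 0, 0.0, 0, 0)
    top = max(r[0] for r in results)
    return max(
        100.0 * ident / cols for s, ident, cols in results if s == top and cols
    )


# ---------------------------------------------------------------------------
# trees

def enumerate_unrooted_5taxon_topologies(labels=("A", "B", "C", "D", "E")):
    """All 15 unrooted binary topologies on 5 labels as newick strings with
    unit branch lengths, built by inserting each new leaf into every edge of
    the smaller tree (nested-tuple rooted representations; the root has
    degree 2, equivalent to an unrooted tree)."""
    # represent as nested tuples; start from the unique 3-leaf unrooted tree
    def insert(tree, leaf):
        """Yield trees with ``leaf`` attached into every edge of ``tree``."""
        yield (tree, leaf)
        if isinstance(tree, tuple):
            left, right = tree
            for sub in insert(left, leaf):
                yield (sub, right)
            for sub in insert(right, leaf):
                yield (left, sub)

    trees = [((labels[0], labels[1]), labels[2])]
    for leaf in labels[3:]:
        trees = [t for base in trees for t in insert(base, leaf)]
    # dedupe by split set
    seen = {}
    for t in trees:
        key = frozenset(tuple_splits(t, set(labels)))
        seen.setdefault(key, t)
    return list(seen.values())


def tuple_leaves(tree) -> set:
    if isinstance(tree, tuple):
        return tuple_leaves(tree[0]) | tuple_leaves(tree[1])
    return {tree}


def tuple_splits(tree, all_leaves: set) -> set[frozenset]:
    """Non-trivial bipartitions of a nested-tuple tree (treated unrooted),
    canonicalized to the side not containing the smallest label."""
    ref = min(all_leaves)
    n = len(all_leaves)
    splits = set()

    def walk(node):
        if not isinstance(node, tuple):
            return
        for child in node:
            clade = tuple_leaves(child)
            if 2 <= len(clade) <= n - 2:
                side = all_leaves - clade if ref in clade else clade
                if 2 <= len(side) <= n - 2:
                    splits.add(frozenset(side))
            walk(child)

    walk(tree)
    return splits


def tuple_to_newick(tree, length=1.0) -> str:
    def fmt(node):
        if isinstance(node, tuple):
            return f"({fmt(node[0])},{fmt(node[1])}):{length}"
        return f"{node}:{length}"

    if isinstance(tree, tuple):
        return f"({fmt(tree[0])},{fmt(tree[1])});"
    raise ValueError("tree must be a tuple")


def brute_force_split_distance(t1, t2, labels: set) -> int:
    s1 = tuple_splits(t1, labels)
    s2 = tuple_splits(t2, labels)
    return len(s1 ^ s2)
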