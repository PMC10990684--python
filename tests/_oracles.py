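"""Independent brute-force oracles used by the test suite.

Everything here works on plain Python strings/sets and never calls the
vectorised implementation paths it is used to check.
"""

from __future__ import annotations

import itertools
import random

import dendropy
import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def string_kmers(read: str, k: int, canonical: bool = True) -> list[str]:
    """Sliding-window k-mers; windows containing non-ACGT are skipped."""
    out = []
    for i in range(len(read) - k + 1):
        w = read[i : i + k].upper()
        if any(c not in "ACGT" for c in w):
            continue
        out.append(min(w, revcomp(w)) if canonical else w)
    return out


def string_count(reads, k: int, min_count: int = 1, canonical: bool = True) -> set[str]:
    counts: dict[str, int] = {}
    for read in reads:
        for w in string_kmers(read, k, canonical):
            counts[w] = counts.get(w, 0) + 1
    return {w for w, c in counts.items() if c >= min_count}


def set_jaccard(a: set, b: set) -> float:
    return len(a & b) / len(a | b)


# ---------------------------------------------------------------------------
# trees


def random_binary_tree(labels, rng: random.Random, min_len=1, max_len=9):
    """Random unrooted binary topology with integer branch lengths.

    Returns (newick string, leaf-to-leaf path-length matrix) computed by
    explicit path traversal over the node graph — an additive matrix.
    """
    nodes = {lab: None for lab in labels}
    # build by random sequential joining (yields a uniform-ish binary shape)
    items = [(lab,) for lab in labels]
    parents: dict = {}
    lengths: dict = {}
    counter = itertools.count()
    while len(items) > 1:
        i, j = sorted(rng.sample(range(len(items)), 2))
        b = items.pop(j)
        a = items.pop(i)
        new = ("i%d" % next(counter),)
        for child in (a, b):
            parents[child] = new
            lengths[child] = rng.randint(min_len, max_len)
        items.append(new)
    root = items[0]

    def path_to_root(x):
        out = []
        while x in parents:
            out.append((x, lengths[x]))
            x = parents[x]
        return out

    n = len(labels)
    mat = np.zeros((n, n), dtype=float)
    paths = {lab: path_to_root((lab,)) for lab in labels}
    for ii in range(n):
        for jj in range(ii + 1, n):
            pa = paths[labels[ii]]
            pb = paths[labels[jj]]
            sa = {x for x, _ in pa}
            sb = {x for x, _ in pb}
            d = sum(l for x, l in pa if x not in sb) + sum(l for x, l in pb if x not in sa)
            mat[ii, jj] = mat[jj, ii] = d

    def to_newick(node):
        kids = [c for c in parents if parents[c] == node]
        if not kids:
            return node[0]
        return "(" + ",".join(f"{to_newick(c)}:{lengths[c]}" for c in kids) + ")"

    return to_newick(root) + ";", mat


def bipartitions(newick: str) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, as frozensets of the
    smaller-side-canonicalised leaf sets (brute-force, via dendropy parse only)."""
    t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    all_leaves = frozenset(l.taxon.label for l in t.leaf_node_iter())
    out = set()
    for node in t.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        out.add(frozenset((side, other)))
    return out


def rf_brute(newick_a: str, newick_b: str, n: int) -> float:
    ba, bb = bipartitions(newick_a), bipartitions(newick_b)
    return len(ba ^ bb) / (2.0 * (n - 3))
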