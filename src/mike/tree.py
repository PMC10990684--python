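"""Distance-based tree inference (NJ, BIONJ, UPGMA) and topology comparison.

Trees are held as :class:`dendropy.Tree` objects (aliased ``PhyloTree``),
which supplies Newick serialisation and bipartition encoding.  The three
agglomerations are implemented here directly on the numpy distance matrix:

* ``nj`` — Saitou & Nei neighbor joining with the standard Q-criterion and
  two-point branch-length formulas; output unrooted (trifurcating seed node).
* ``bionj`` — the same agglomeration order, but the reduced distances are a
  variance-weighted combination of the two joined rows (Gascuel's model,
  variances proportional to distances; weight lambda clamped to [0, 1]).
  With lambda fixed at 1/2 it degenerates exactly to NJ's update.
* ``upgma`` — average linkage; rooted, ultrametric output.

Ties in pair selection are broken by the lowest (i, j) index pair so runs
are deterministic across platforms.  Negative inferred branch lengths are
clamped to zero and counted (audit via module logger).

``rf_distance`` is the classical Robinson-Foulds symmetric difference of
non-trivial bipartitions, normalised by 2(n-3) — the maximum attainable for
two fully resolved unrooted trees; rooted inputs are unrooted first.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import dendropy
import numpy as np
from dendropy.calculate import treecompare

from .distance import DistanceMatrix

__all__ = [
    "PhyloTree",
    "nj",
    "bionj",
    "upgma",
    "rf_distance",
    "write_newick",
    "read_newick",
]

logger = logging.getLogger(__name__)

PhyloTree = dendropy.Tree


def _check_matrix(m: DistanceMatrix) -> None:
    if m.n < 3:
        raise ValueError(f"tree inference needs >= 3 taxa, got {m.n}")


def _leaf_nodes(labels, tns):
    nodes = []
    for lab in labels:
        taxon = tns.get_taxon(lab) or tns.new_taxon(lab)
        nodes.append(dendropy.Node(taxon=taxon))
    return nodes


def _clamp(length: float, audit: list) -> float:
    if length < 0:
        audit.append(length)
        return 0.0
    return float(length)


def _finish_unrooted(nodes, D, idx, audit, tns) -> PhyloTree:
    """Join the last three clusters onto one trifurcating seed node."""
    x, y, z = idx
    root = dendropy.Node()
    lx = 0.5 * (D[x, y] + D[x, z] - D[y, z])
    ly = 0.5 * (D[x, y] + D[y, z] - D[x, z])
    lz = 0.5 * (D[x, z] + D[y, z] - D[x, y])
    for node, ln in ((nodes[x], lx), (nodes[y], ly), (nodes[z], lz)):
        root.add_child(node)
        node.edge.length = _clamp(ln, audit)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def _argmin_pair(Q: np.ndarray) -> tuple[int, int]:
    """Lowest (i, j), i<j, attaining the minimum (row-major argmin on the upper triangle)."""
    n = Q.shape[0]
    masked = Q.copy()
    masked[np.tril_indices(n)] = np.inf
    flat = int(np.argmin(masked))
    return flat // n, flat % n


def _neighbor_join(m: DistanceMatrix, variance_weighted: bool) -> PhyloTree:
    _check_matrix(m)
    D = m.values.copy()
    V = D.copy()  # BIONJ variance matrix; unused when variance_weighted=False
    tns = dendropy.TaxonNamespace()
    nodes = _leaf_nodes(m.labels, tns)
    active = list(range(m.n))
    audit: list[float] = []
    while len(active) > 3:
        n = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=0)
        Q = (n - 2) * sub - r[:, None] - r[None, :]
        ai, aj = _argmin_pair(Q)
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (n - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = _clamp(li, audit)
        parent.add_child(nodes[j])
        nodes[j].edge.length = _clamp(lj, audit)
        others = [a for a in active if a != i and a != j]
        if variance_weighted:
            vij = V[i, j]
            if vij > 0 and others:
                lam = 0.5 + (V[j, others].sum() - V[i, others].sum()) / (
                    2 * (n - 2) * vij
                )
                lam = min(1.0, max(0.0, lam))
            else:
                lam = 0.5
            newD = lam * (D[i, others] - li) + (1 - lam) * (D[j, others] - lj)
            newV = lam * V[i, others] + (1 - lam) * V[j, others] - lam * (1 - lam) * vij
        else:
            newD = 0.5 * (D[i, others] + D[j, others] - dij)
            newV = newD  # ignored
        # reuse slot i for the merged cluster, retire slot j
        D[i, others] = newD
        D[others, i] = newD
        D[i, i] = 0.0
        V[i, others] = newV
        V[others, i] = newV
        V[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)
    tree = _finish_unrooted(nodes, D, active, audit, tns)
    if audit:
        logger.info(
            "clamped %d negative branch length(s) to 0 (most negative %.3g)",
            len(audit),
            min(audit),
        )
    return tree


def nj(m: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining; unrooted tree with n leaves."""
    return _neighbor_join(m, variance_weighted=False)


def bionj(m: DistanceMatrix) -> PhyloTree:
    """BIONJ: NJ agglomeration with variance-weighted matrix reduction."""
    return _neighbor_join(m, variance_weighted=True)


def upgma(m: DistanceMatrix) -> PhyloTree:
    """Average-linkage agglomeration; rooted ultrametric tree."""
    _check_matrix(m)
    D = m.values.copy()
    tns = dendropy.TaxonNamespace()
    nodes = _leaf_nodes(m.labels, tns)
    sizes = {i: 1 for i in range(m.n)}
    heights = {i: 0.0 for i in range(m.n)}
    active = list(range(m.n))
    audit: list[float] = []
    while len(active) > 1:
        sub = D[np.ix_(active, active)]
        ai, aj = _argmin_pair(sub)
        i, j = active[ai], active[aj]
        h = D[i, j] / 2.0
        parent = dendropy.Node()
        for child in (i, j):
            parent.add_child(nodes[child])
            nodes[child].edge.length = _clamp(h - heights[child], audit)
        others = [a for a in active if a != i and a != j]
        si, sj = sizes[i], sizes[j]
        merged = (si * D[i, others] + sj * D[j, others]) / (si + sj)
        D[i, others] = merged
        D[others, i] = merged
        nodes[i] = parent
        sizes[i] = si + sj
        heights[i] = h
        active.remove(j)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[active[0]]
    tree.is_rooted = True
    if audit:
        logger.info("clamped %d negative branch length(s) to 0", len(audit))
    return tree


def _labels(t: PhyloTree) -> set[str]:
    return {leaf.taxon.label for leaf in t.leaf_node_iter()}


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> float:
    """Normalised Robinson-Foulds distance in [0, 1] between two trees.

    Bipartitions present in exactly one tree, divided by 2(n-3); rooted
    inputs are compared as unrooted trees.  Leaf-label sets must agree.
    """
    l1, l2 = _labels(t1), _labels(t2)
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ; only in first: {sorted(l1 - l2)}, "
            f"only in second: {sorted(l2 - l1)}"
        )
    n = len(l1)
    if n < 4:
        raise ValueError(f"RF distance needs >= 4 leaves, got {n}")
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(
        data=t1.as_string(schema="newick"),
        schema="newick",
        taxon_namespace=tns,
        preserve_underscores=True,
    )
    b = dendropy.Tree.get(
        data=t2.as_string(schema="newick"),
        schema="newick",
        taxon_namespace=tns,
        preserve_underscores=True,
    )
    for t in (a, b):
        t.is_rooted = False
        t.collapse_basal_bifurcation()
        t.encode_bipartitions()
    sym = treecompare.symmetric_difference(a, b)
    return sym / (2.0 * (n - 3))


def write_newick(t: PhyloTree, path: Union[str, Path]) -> None:
    path = Path(path)
    newick = t.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(newick)


def read_newick(path: Union[str, Path]) -> PhyloTree:
    path = Path(path)
    try:
        return dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"{path}: Newick parse error: {exc}") from exc
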