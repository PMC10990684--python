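"""Jaccard -> evolutionary distance transform and labelled distance matrices.

For two equal-length genomes whose k-mer sets share W of roughly L k-mers
each, J = W / (2L - W), hence W/L = 2J/(J+1).  Under a Jukes-Cantor model
where each site mutates independently with per-site probability d, a k-mer
survives unchanged with probability (1-d)**k, and equating the two gives

    d = 1 - (2J / (J + 1)) ** (1/k)

which maps J=1 to d=0 and J=0 to d=1 and is strictly decreasing in between.
The matrix assembly applies the sketch estimator to every pair and this
transform to every estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .sketch import Sketch, estimate_jaccard

__all__ = [
    "DistanceMatrix",
    "jaccard_to_distance",
    "distance_matrix",
    "write_phylip",
    "read_phylip",
    "write_csv",
]

_SYM_TOL = 1e-6


@dataclass
class DistanceMatrix:
    """Symmetric labelled matrix of pairwise evolutionary distances."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise ValueError(f"duplicate labels: {dupes}")
        asym = np.abs(self.values - self.values.T)
        if asym.size and asym.max() > _SYM_TOL:
            i, j = np.unravel_index(int(np.argmax(asym)), asym.shape)
            raise ValueError(
                f"matrix not symmetric: d[{self.labels[i]}][{self.labels[j]}]="
                f"{self.values[i, j]} vs {self.values[j, i]}"
            )
        if np.abs(np.diag(self.values)).max(initial=0.0) > _SYM_TOL:
            raise ValueError("diagonal must be zero")
        # enforce exact symmetry / zero diagonal after tolerance check
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair) -> float:
        i, j = pair
        if isinstance(i, str):
            i = self.labels.index(i)
        if isinstance(j, str):
            j = self.labels.index(j)
        return float(self.values[i, j])


def jaccard_to_distance(J, k: int):
    """Per-site substitution probability d = 1 - (2J/(J+1))**(1/k).

    Accepts a scalar or ndarray in [0, 1]; J=0 yields d=1 (not infinity).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    arr = np.asarray(J, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError(f"Jaccard value outside [0, 1]: {J}")
    with np.errstate(divide="ignore"):
        d = 1.0 - (2.0 * arr / (arr + 1.0)) ** (1.0 / k)
    if np.isscalar(J) or arr.ndim == 0:
        return float(d)
    return d


def distance_matrix(sketches: Sequence[Sketch]) -> DistanceMatrix:
    """All-pairs sketch Jaccard estimates mapped to evolutionary distances."""
    if len(sketches) < 3:
        raise ValueError(f"need at least 3 sketches, got {len(sketches)}")
    labels = [s.label for s in sketches]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate sketch labels: {dupes}")
    k = sketches[0].split.k
    n = len(sketches)
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            jac = estimate_jaccard(sketches[i], sketches[j])
            d[i, j] = d[j, i] = jaccard_to_distance(jac, k)
    return DistanceMatrix(labels, d)


def write_phylip(m: DistanceMatrix, path: Union[str, Path]) -> None:
    """Square PHYLIP distance matrix, relaxed (whitespace-delimited) names."""
    path = Path(path)
    with open(path, "w", encoding="ascii") as fh:
        fh.write(f"{m.n}\n")
        width = max(10, max(len(l) for l in m.labels))
        for label, row in zip(m.labels, m.values):
            vals = "  ".join(f"{v:.6f}" for v in row)
            fh.write(f"{label:<{width}}  {vals}\n")


def read_phylip(path: Union[str, Path]) -> DistanceMatrix:
    path = Path(path)
    with open(path, "r", encoding="ascii") as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}: first line must be the taxon count") from None
    if len(lines) - 1 != n:
        raise ValueError(f"{path}: expected {n} rows, found {len(lines) - 1}")
    labels = []
    rows = []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != n + 1:
            raise ValueError(
                f"{path}: row {parts[0] if parts else '?'} has {len(parts) - 1} "
                f"values, expected {n} (matrix must be square)"
            )
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    values = np.array(rows)
    asym = np.abs(values - values.T)
    if asym.max(initial=0.0) > _SYM_TOL:
        i, j = np.unravel_index(int(np.argmax(asym)), asym.shape)
        raise ValueError(
            f"{path}: asymmetric at ({labels[i]}, {labels[j]}): "
            f"{values[i, j]} vs {values[j, i]}"
        )
    return DistanceMatrix(labels, values)


def write_csv(m: DistanceMatrix, path: Union[str, Path]) -> None:
    path = Path(path)
    with open(path, "w", encoding="ascii") as fh:
        fh.write("," + ",".join(m.labels) + "\n")
        for label, row in zip(m.labels, m.values):
            fh.write(label + "," + ",".join(f"{v:.6f}" for v in row) + "\n")
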