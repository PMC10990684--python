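"""Evaluation harness: the package's standard benchmark experiments.

Two experiments mirror the simulation-based evaluation design the package
is validated against:

* same-genome read-pair Jaccard — draw pairs of independent read sets from
  one genome at matched coverages, estimate Jaccard from sketches, and
  compare with the exact (sorted-set) Jaccard of the same filtered k-mer
  sets; summarised as an RMSE across pairs and the per-pair estimates.

* sketch-tree vs reference-tree — simulate a haploid lineage, sequence
  every leaf, run the full sketch -> distance -> BIONJ pipeline, and score
  its topology against the BIONJ tree built from the recorded true per-site
  divergences with the normalised Robinson-Foulds distance.

All randomness is derived arithmetically from one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distance import DistanceMatrix, distance_matrix, jaccard_to_distance
from .kmer_io import KmerParams, codes_from_matrix, kmer_set_from_codes
from .sketch import SplitParams, build_permutation, build_sketch, estimate_jaccard, exact_jaccard
from .simulate import SimGenome, evolve_haploid, make_ancestor, sample_read_matrix
from .tree import bionj, rf_distance

__all__ = [
    "JaccardPair",
    "same_genome_jaccard_pairs",
    "jaccard_rmse",
    "sketch_vs_reference_rf",
]

_MOD = 2**31


def _child_seed(master: int, tag: int) -> int:
    """Deterministic sub-seed; stays below 2**31."""
    return (int(master) * 1_000_003 + tag * 7919 + 17) % _MOD


@dataclass(frozen=True)
class JaccardPair:
    coverage: float
    exact: float
    estimate: float


def same_genome_jaccard_pairs(
    seed: int,
    L: int = 1_000_000,
    coverages: np.ndarray | None = None,
    read_len: int = 100,
    err_rate: float = 0.01,
    k: int = 21,
    min_count: int = 2,
    perm_seed: int = 42,
) -> list[JaccardPair]:
    """Sketch-estimated vs exact Jaccard for same-genome read-set pairs.

    For each coverage, two independent read sets are drawn from the same
    genome, k-mers are counted with the abundance filter, and both the
    sketch estimate and the exact sorted-set Jaccard of the filtered sets
    are recorded.
    """
    if coverages is None:
        coverages = np.linspace(10, 50, 10)
    ancestor = make_ancestor(L, 0.5, _child_seed(seed, 0))
    genome = SimGenome(ancestor[None, :], "source")
    params = KmerParams(k=k, min_count=min_count)
    split = SplitParams.from_k(k)
    perm = build_permutation(perm_seed, split.suffix_bases)
    out = []
    for i, cov in enumerate(coverages):
        sets = []
        for rep in (0, 1):
            reads = sample_read_matrix(
                genome, float(cov), read_len, err_rate,
                seed=_child_seed(seed, 100 + 2 * i + rep),
            )
            codes = codes_from_matrix(reads, k, params.canonical)
            sets.append(kmer_set_from_codes(codes, params, f"cov{i}_{rep}"))
        sketches = [build_sketch(s, split, perm, label=s.source_label) for s in sets]
        out.append(
            JaccardPair(
                coverage=float(cov),
                exact=exact_jaccard(*sets),
                estimate=estimate_jaccard(*sketches),
            )
        )
    return out


def jaccard_rmse(pairs: list[JaccardPair]) -> float:
    """RMSE of sketch estimates against the exact ground truth."""
    err = np.array([p.estimate - p.exact for p in pairs])
    return float(np.sqrt(np.mean(err**2)))


def sketch_vs_reference_rf(
    seed: int,
    n_leaves: int = 16,
    L: int = 500_000,
    rate: float = 1e-3,
    generations: int = 50,
    coverage: float = 20.0,
    read_len: int = 100,
    err_rate: float = 0.01,
    k: int = 21,
    min_count: int = 2,
    perm_seed: int = 42,
) -> float:
    """Normalised RF between the sketch-pipeline BIONJ tree and the BIONJ
    tree built from the lineage's recorded true per-site divergences."""
    lineage = evolve_haploid(
        L=L, rate=rate, generations=generations, n_offspring=n_leaves,
        seed=_child_seed(seed, 1),
    )
    params = KmerParams(k=k, min_count=min_count)
    split = SplitParams.from_k(k)
    perm = build_permutation(perm_seed, split.suffix_bases)
    sketches = []
    for i, genome in enumerate(lineage.genomes):
        reads = sample_read_matrix(
            genome, coverage, read_len, err_rate, seed=_child_seed(seed, 1000 + i)
        )
        kset = kmer_set_from_codes(codes_from_matrix(reads, k, True), params, genome.label)
        sketches.append(build_sketch(kset, split, perm, label=genome.label))
    estimated_tree = bionj(distance_matrix(sketches))
    reference_tree = bionj(lineage.true_div)
    return rf_distance(estimated_tree, reference_tree)
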