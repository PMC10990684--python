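"""Region-structured Jukes-Cantor genome evolution and Illumina-like reads.

The generator emulates the evaluation datasets used throughout the package:
an ancestral chromosome is tiled into conserved regions (never mutated) and
mutation regions (free to mutate); lineages descend from it by repeated
rounds of substitution under a Jukes-Cantor model (every site in a mutation
region flips independently with the per-generation rate, uniformly to one of
the three other bases).  Four lineage architectures are provided:

* haploid       — recorded bifurcating genealogy, n leaf genomes;
* autotetraploid— same genealogy; each generation two of the four
                  chromosome copies are drawn, mutated, and doubled into the
                  next 4-copy genome (unreduced-gamete style);
* allotetraploid— two tetraploid parental pools diverge from the ancestor,
                  then each generation both pools mutate and two hybrid
                  offspring (2 copies from each pool) are emitted, forming a
                  sister cherry on a time-ladder genealogy; 2n leaves;
* polyploid     — a scheduled cascade of whole-genome duplications (copy
                  doubling) and hybridisations (half the copies from each
                  parent), yielding genomes at ploidies 2/4/6/8/12/16.

Every run records the true genealogy as a tree and the realised pairwise
per-mutable-site divergence (copies averaged for polyploids).  Reads are
drawn uniformly from both strands of all copies with i.i.d. substitution
errors — the operative noise for k-mer sketching — and constant Phred
qualities.  Everything is reproducible bit-for-bit from a single seed.

Sequences are numpy uint8 arrays over {0,1,2,3} = {A,C,G,T} internally.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import dendropy
import numpy as np

from .distance import DistanceMatrix
from .kmer_io import CODE_TO_BASE

__all__ = [
    "RegionMap",
    "SimGenome",
    "SimLineage",
    "make_ancestor",
    "jc_mutate",
    "evolve_haploid",
    "evolve_autotetraploid",
    "evolve_allotetraploid",
    "evolve_polyploid",
    "simulate_reads",
    "sample_read_matrix",
    "true_distance_matrix",
    "write_genome_fasta",
    "write_reads_fastq",
    "seq_to_str",
    "str_to_seq",
]

ALLOWED_PLOIDIES = frozenset({1, 2, 4, 6, 8, 12, 16})

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def seq_to_str(seq: np.ndarray) -> str:
    return _BASE_BYTES[seq].tobytes().decode("ascii")


def str_to_seq(s: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    arr = lut[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
    if (arr > 3).any():
        raise ValueError("sequence contains non-ACGT characters")
    return arr


@dataclass
class RegionMap:
    """Conserved / mutable tiling of [0, L): ordered half-open intervals."""

    length: int
    intervals: list[tuple[int, int, str]]  # (start, end, "conserved"|"mutable")

    def __post_init__(self) -> None:
        pos = 0
        for start, end, tag in self.intervals:
            if start != pos or end <= start:
                raise ValueError("intervals must tile [0, L) exactly, in order")
            if tag not in ("conserved", "mutable"):
                raise ValueError(f"unknown region tag {tag!r}")
            pos = end
        if pos != self.length:
            raise ValueError("intervals must tile [0, L) exactly")
        mask = np.zeros(self.length, dtype=bool)
        for start, end, tag in self.intervals:
            if tag == "mutable":
                mask[start:end] = True
        self._mutable_mask = mask
        self._mutable_idx = np.flatnonzero(mask)

    @classmethod
    def alternating(
        cls, length: int, conserved_fraction: float = 0.5, block: int = 10_000
    ) -> "RegionMap":
        """Alternating conserved/mutable blocks; conserved first.

        Within each window of size `block`, the first conserved_fraction is
        conserved and the remainder mutable.
        """
        if not 0.0 <= conserved_fraction <= 1.0:
            raise ValueError("conserved_fraction must be in [0, 1]")
        intervals: list[tuple[int, int, str]] = []
        pos = 0
        while pos < length:
            end = min(pos + block, length)
            cut = pos + int(round((end - pos) * conserved_fraction))
            if cut > pos:
                intervals.append((pos, cut, "conserved"))
            if end > cut:
                intervals.append((cut, end, "mutable"))
            pos = end
        return cls(length, intervals)

    @classmethod
    def all_mutable(cls, length: int) -> "RegionMap":
        return cls(length, [(0, length, "mutable")])

    @property
    def mutable_mask(self) -> np.ndarray:
        return self._mutable_mask

    @property
    def mutable_idx(self) -> np.ndarray:
        return self._mutable_idx

    @property
    def n_mutable(self) -> int:
        return int(self._mutable_idx.size)

    @property
    def conserved_fraction(self) -> float:
        return 1.0 - self.n_mutable / self.length


@dataclass
class SimGenome:
    """One simulated genome: `ploidy` chromosome copies of equal length."""

    copies: np.ndarray  # (ploidy, L) uint8
    label: str
    lineage_id: str = ""
    generation: int = 0

    def __post_init__(self) -> None:
        self.copies = np.atleast_2d(np.asarray(self.copies, dtype=np.uint8))
        if self.ploidy not in ALLOWED_PLOIDIES:
            raise ValueError(
                f"ploidy {self.ploidy} not in {sorted(ALLOWED_PLOIDIES)}"
            )

    @property
    def ploidy(self) -> int:
        return int(self.copies.shape[0])

    @property
    def length(self) -> int:
        return int(self.copies.shape[1])


@dataclass
class SimLineage:
    """Simulated genomes plus the recorded genealogy and realised divergences."""

    genomes: list[SimGenome]
    true_tree: dendropy.Tree
    true_div: DistanceMatrix
    regions: RegionMap
    params: dict = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return [g.label for g in self.genomes]


def make_ancestor(L: int, gc_fraction: float = 0.5, seed: int = 0) -> np.ndarray:
    """i.i.d. ancestral chromosome with the requested GC content."""
    if L < 1:
        raise ValueError("L must be >= 1")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    return rng.choice(4, size=L, p=p).astype(np.uint8)


def jc_mutate(
    seq: np.ndarray,
    rate: float,
    regions: RegionMap,
    rng: Union[int, np.random.Generator],
) -> tuple[np.ndarray, int]:
    """Jukes-Cantor substitution round confined to mutable regions.

    Each mutable site independently substitutes with probability `rate`,
    uniformly to one of the three other bases.  Returns (new sequence,
    realised substitution count); the input is not modified.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if seq.shape[0] != regions.length:
        raise ValueError("sequence length does not match region map")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = seq.copy()
    if rate == 0.0 or regions.n_mutable == 0:
        return out, 0
    idx = regions.mutable_idx
    hit = idx[rng.random(idx.size) < rate]
    if hit.size:
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size, dtype=np.uint8)) % 4
    return out, int(hit.size)


# ---------------------------------------------------------------------------
# lineage bookkeeping


class _Branch:
    """A live lineage during simulation: chromosome copies + its tree node."""

    __slots__ = ("copies", "node", "subs")

    def __init__(self, copies: np.ndarray, node: dendropy.Node):
        self.copies = copies  # (ploidy, L)
        self.node = node
        self.subs = 0  # realised substitutions since this branch began


def _split_schedule(generations: int, n_leaves: int) -> set[int]:
    """Generations (0-based, before mutation of that generation) at which
    live lineages bifurcate; balanced doubling until n_leaves exist."""
    depth = max(1, math.ceil(math.log2(n_leaves)))
    return {int(math.floor(generations * i / depth)) for i in range(depth)}


def _finalise_tree(root: dendropy.Node, leaf_nodes, labels) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace()
    for node, label in zip(leaf_nodes, labels):
        node.taxon = tns.new_taxon(label)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = True
    return tree


def _pairwise_divergence(genomes: Sequence[SimGenome], regions: RegionMap) -> DistanceMatrix:
    """Copy-averaged Hamming fraction over mutable sites for all genome pairs."""
    idx = regions.mutable_idx
    n = len(genomes)
    d = np.zeros((n, n))
    muts = [g.copies[:, idx] for g in genomes]
    denom = max(1, idx.size)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = muts[i], muts[j]
            # mean over all copy pairs of per-site mismatch fraction
            total = 0.0
            for ai in range(a.shape[0]):
                total += np.count_nonzero(a[ai][None, :] != b, axis=1).sum()
            d[i, j] = d[j, i] = total / (a.shape[0] * b.shape[0] * denom)
    return DistanceMatrix([g.label for g in genomes], d)


def _default_regions(L: int, conserved_fraction: float, block: int) -> RegionMap:
    return RegionMap.alternating(L, conserved_fraction, block)


def _evolve_split_lineage(
    L: int,
    regions: Optional[RegionMap],
    rate: float,
    generations: int,
    n_offspring: int,
    seed: int,
    gc_fraction: float,
    conserved_fraction: float,
    block: int,
    ploidy: int,
    label_prefix: str,
    mutate_branch,
) -> SimLineage:
    """Shared driver for haploid and autotetraploid lineages.

    `mutate_branch(branch, rng)` advances one lineage one generation and
    returns the realised substitution count.
    """
    if n_offspring < 2:
        raise ValueError("n_offspring must be >= 2")
    if regions is None:
        regions = _default_regions(L, conserved_fraction, block)
    rng = np.random.default_rng(seed)
    ancestor = make_ancestor(regions.length, gc_fraction, rng.integers(2**31))
    root = dendropy.Node()
    first = _Branch(np.repeat(ancestor[None, :], ploidy, axis=0), root)
    branches = [first]
    splits = _split_schedule(generations, n_offspring)
    n_mut = regions.n_mutable
    for g in range(generations):
        if g in splits and len(branches) < n_offspring:
            _split_branches(branches, n_offspring, n_mut)
        for br in branches:
            br.subs += mutate_branch(br, rng, regions, rate)
    while len(branches) < n_offspring:  # degenerate schedules (generations small)
        _split_branches(branches, n_offspring, n_mut)
    labels = [f"{label_prefix}{i + 1:02d}" for i in range(len(branches))]
    for br in branches:
        br.node.edge.length = br.subs / max(1, n_mut) / ploidy
    tree = _finalise_tree(root, [br.node for br in branches], labels)
    genomes = [
        SimGenome(br.copies, label, lineage_id=label, generation=generations)
        for br, label in zip(branches, labels)
    ]
    div = _pairwise_divergence(genomes, regions)
    params = dict(
        mode=label_prefix.rstrip("_"),
        L=regions.length,
        rate=rate,
        generations=generations,
        n_offspring=n_offspring,
        seed=seed,
        ploidy=ploidy,
        conserved_fraction=regions.conserved_fraction,
    )
    return SimLineage(genomes, tree, div, regions, params)


def _split_branches(branches: list[_Branch], n_leaves: int, n_mutable: int) -> None:
    """Bifurcate lineages (in order) until the count doubles or reaches n_leaves."""
    target = min(2 * len(branches), n_leaves)
    i = 0
    while len(branches) < target:
        br = branches[i]
        left = dendropy.Node()
        right = dendropy.Node()
        # close this branch: its accumulated substitutions become the edge length
        ploidy = br.copies.shape[0]
        br.node.edge.length = br.subs / max(1, n_mutable) / ploidy
        old_node = br.node
        old_node.add_child(left)
        old_node.add_child(right)
        sibling = _Branch(br.copies.copy(), right)
        br.node = left
        br.subs = 0
        branches.append(sibling)
        i += 1


def _mutate_haploid(br: _Branch, rng, regions, rate) -> int:
    seq, n = jc_mutate(br.copies[0], rate, regions, rng)
    br.copies = seq[None, :]
    return n


def _tetraploid_step(copies: np.ndarray, rng, regions, rate) -> tuple[np.ndarray, int]:
    """One tetraploid generation: draw 2 of 4 copies, mutate each, double
    them (unreduced-gamete style) into the next 4-copy genome.  The doubling
    bottleneck keeps the copies of one lineage coherent over time."""
    pick = rng.choice(4, size=2, replace=False)
    m1, n1 = jc_mutate(copies[pick[0]], rate, regions, rng)
    m2, n2 = jc_mutate(copies[pick[1]], rate, regions, rng)
    return np.stack([m1, m2, m1.copy(), m2.copy()]), n1 + n2


def _mutate_autotetraploid(br: _Branch, rng, regions, rate) -> int:
    br.copies, n = _tetraploid_step(br.copies, rng, regions, rate)
    return n


def evolve_haploid(
    L: int = 500_000,
    regions: Optional[RegionMap] = None,
    rate: float = 1e-3,
    generations: int = 50,
    n_offspring: int = 8,
    seed: int = 0,
    gc_fraction: float = 0.5,
    conserved_fraction: float = 0.5,
    block: int = 10_000,
) -> SimLineage:
    """Haploid lineage: recorded balanced bifurcations, one copy per genome."""
    return _evolve_split_lineage(
        L, regions, rate, generations, n_offspring, seed, gc_fraction,
        conserved_fraction, block, ploidy=1, label_prefix="hap",
        mutate_branch=_mutate_haploid,
    )


def evolve_autotetraploid(
    L: int = 500_000,
    regions: Optional[RegionMap] = None,
    rate: float = 1e-3,
    generations: int = 50,
    n_offspring: int = 8,
    seed: int = 0,
    gc_fraction: float = 0.5,
    conserved_fraction: float = 0.5,
    block: int = 10_000,
) -> SimLineage:
    """Autotetraploid lineage: 4 copies; per generation 2 copies are sampled,
    mutated and doubled into the next genome."""
    return _evolve_split_lineage(
        L, regions, rate, generations, n_offspring, seed, gc_fraction,
        conserved_fraction, block, ploidy=4, label_prefix="auto",
        mutate_branch=_mutate_autotetraploid,
    )


def evolve_allotetraploid(
    L: int = 500_000,
    regions: Optional[RegionMap] = None,
    rate: float = 1e-3,
    generations: int = 8,
    n_offspring: int = 8,
    seed: int = 0,
    gc_fraction: float = 0.5,
    conserved_fraction: float = 0.5,
    block: int = 10_000,
    divergence_generations: Optional[int] = None,
) -> SimLineage:
    """Allotetraploid dataset: two tetraploid parental pools, 2n hybrid leaves.

    The pools first diverge from the common ancestor for
    `divergence_generations` rounds (default: `generations`).  Then for each
    of `n_offspring` generations both pools advance one tetraploid step, two
    chromosomes are chosen from each pool (paternal and maternal parents),
    and two hybrid offspring carrying those 2+2 copies are emitted, each with
    its own round of fresh mutations.  The two offspring of a generation
    share the parental chromosomes and form a sister cherry in the recorded
    time-ladder genealogy.
    """
    if n_offspring < 2:
        raise ValueError("n_offspring must be >= 2")
    if regions is None:
        regions = _default_regions(L, conserved_fraction, block)
    if divergence_generations is None:
        divergence_generations = max(generations, 1)
    rng = np.random.default_rng(seed)
    ancestor = make_ancestor(regions.length, gc_fraction, rng.integers(2**31))
    pools = [np.repeat(ancestor[None, :], 4, axis=0) for _ in range(2)]
    for _ in range(divergence_generations):
        for p in range(2):
            pools[p], _ = _tetraploid_step(pools[p], rng, regions, rate)
    # time-ladder genealogy: stem node per emission generation, cherry of 2 hybrids
    root = dendropy.Node()
    stem = root
    leaf_nodes: list[dendropy.Node] = []
    genomes: list[SimGenome] = []
    step = rate  # expected per-mutable-site divergence accrued per generation
    for g in range(n_offspring):
        for p in range(2):
            pools[p], _ = _tetraploid_step(pools[p], rng, regions, rate)
        cherry = dendropy.Node()
        stem.add_child(cherry)
        cherry.edge.length = step
        # one paternal + one maternal chromosome pair chosen per generation;
        # both offspring inherit the same four parental chromosomes and then
        # mutate independently, making them each other's closest relatives
        pick_a = rng.choice(4, size=2, replace=False)
        pick_b = rng.choice(4, size=2, replace=False)
        parental = np.concatenate([pools[0][pick_a], pools[1][pick_b]])
        for h in range(2):
            copies = np.stack(
                [jc_mutate(parental[c], rate, regions, rng)[0] for c in range(4)]
            )
            label = f"allo{2 * g + h + 1:02d}"
            leaf = dendropy.Node()
            leaf.edge.length = step
            cherry.add_child(leaf)
            leaf_nodes.append(leaf)
            genomes.append(
                SimGenome(copies, label, lineage_id=f"gen{g + 1}", generation=g + 1)
            )
        if g < n_offspring - 1:
            nxt = dendropy.Node()
            stem.add_child(nxt)
            nxt.edge.length = step
            stem = nxt
    tree = _finalise_tree(root, leaf_nodes, [g.label for g in genomes])
    div = _pairwise_divergence(genomes, regions)
    params = dict(
        mode="allotetraploid",
        L=regions.length,
        rate=rate,
        generations=generations,
        n_offspring=n_offspring,
        divergence_generations=divergence_generations,
        seed=seed,
        conserved_fraction=regions.conserved_fraction,
    )
    return SimLineage(genomes, tree, div, regions, params)


_DEFAULT_POLYPLOID_SCHEDULE = (
    ("wgd", "x2", "x4"),
    ("wgd", "x4", "x8"),
    ("hyb", ("x4", "x8"), "x6"),
    ("wgd", "x8", "x16"),
    ("wgd", "x6", "x12"),
)


def evolve_polyploid(
    L: int = 500_000,
    regions: Optional[RegionMap] = None,
    rate: float = 1e-3,
    generations: int = 50,
    seed: int = 0,
    gc_fraction: float = 0.5,
    conserved_fraction: float = 0.5,
    block: int = 10_000,
    schedule: Optional[Sequence[tuple]] = None,
) -> SimLineage:
    """Mixed-ploidy cascade: WGD doubles all copies, hybridisation takes half
    the copies from each of two even-ploidy parents.

    The default schedule starts from a diploid ancestor and emits genomes at
    ploidies 2, 4, 6, 8, 12 and 16.  Events are spread evenly over the
    generations; every live lineage mutates (all copies) every generation.
    Hybridisation of ploidies whose halves do not sum to an allowed ploidy
    is a configuration error.
    """
    if regions is None:
        regions = _default_regions(L, conserved_fraction, block)
    if schedule is None:
        schedule = _DEFAULT_POLYPLOID_SCHEDULE
    rng = np.random.default_rng(seed)
    ancestor = make_ancestor(regions.length, gc_fraction, rng.integers(2**31))

    root = dendropy.Node()
    lineages: dict[str, _Branch] = {"x2": _Branch(np.repeat(ancestor[None, :], 2, axis=0), root)}
    # validate schedule before running
    ploidy_of = {"x2": 2}
    for op, src, dst in schedule:
        if op == "wgd":
            if src not in ploidy_of:
                raise ValueError(f"WGD source {src!r} not yet created")
            ploidy_of[dst] = 2 * ploidy_of[src]
        elif op == "hyb":
            p1, p2 = src
            if p1 not in ploidy_of or p2 not in ploidy_of:
                raise ValueError(f"hybridisation parents {src!r} not yet created")
            a, b = ploidy_of[p1], ploidy_of[p2]
            if a % 2 or b % 2:
                raise ValueError(
                    f"cannot hybridise ploidies {a} and {b}: both must be even"
                )
            ploidy_of[dst] = a // 2 + b // 2
        else:
            raise ValueError(f"unknown event {op!r}")
        if ploidy_of[dst] not in ALLOWED_PLOIDIES:
            raise ValueError(
                f"event {op} {src}->{dst} yields unsupported ploidy {ploidy_of[dst]}"
            )

    n_events = len(schedule)
    event_gens = {
        int(math.floor(generations * (i + 1) / (n_events + 1))): i
        for i in range(n_events)
    }
    if len(event_gens) != n_events:
        raise ValueError("generations too small for the event schedule")

    def run_generation() -> None:
        for br in lineages.values():
            total = 0
            for c in range(br.copies.shape[0]):
                br.copies[c], ns = jc_mutate(br.copies[c], rate, regions, rng)
                total += ns
            br.subs += total

    for g in range(generations):
        if g in event_gens:
            op, src, dst = schedule[event_gens[g]]
            if op == "wgd":
                parent = lineages[src]
                node = dendropy.Node()
                parent.node.add_child(node)
                node.edge.length = 0.0
                lineages[dst] = _Branch(np.concatenate([parent.copies, parent.copies.copy()]), node)
            else:
                p1, p2 = (lineages[s] for s in src)
                h1 = p1.copies.shape[0] // 2
                h2 = p2.copies.shape[0] // 2
                take1 = rng.choice(p1.copies.shape[0], size=h1, replace=False)
                take2 = rng.choice(p2.copies.shape[0], size=h2, replace=False)
                node = dendropy.Node()
                # reticulation cannot be a tree edge; attach to the lower-ploidy parent
                first = p1 if p1.copies.shape[0] <= p2.copies.shape[0] else p2
                first.node.add_child(node)
                node.edge.length = 0.0
                lineages[dst] = _Branch(
                    np.concatenate([p1.copies[take1].copy(), p2.copies[take2].copy()]), node
                )
        run_generation()

    labels = sorted(lineages, key=lambda s: int(s[1:]))
    leaf_nodes = []
    for lab in labels:
        br = lineages[lab]
        if br.node.child_nodes():
            # internal lineages get a zero-length leaf tip for their final genome
            tip = dendropy.Node()
            br.node.add_child(tip)
            tip.edge.length = 0.0
            leaf_nodes.append(tip)
        else:
            leaf_nodes.append(br.node)
    tree = _finalise_tree(root, leaf_nodes, labels)
    genomes = [
        SimGenome(lineages[lab].copies.copy(), lab, lineage_id=lab, generation=generations)
        for lab in labels
    ]
    div = _pairwise_divergence(genomes, regions)
    params = dict(
        mode="polyploid",
        L=regions.length,
        rate=rate,
        generations=generations,
        seed=seed,
        conserved_fraction=regions.conserved_fraction,
        ploidies=[g.ploidy for g in genomes],
    )
    return SimLineage(genomes, tree, div, regions, params)


# ---------------------------------------------------------------------------
# read simulation


def sample_read_matrix(
    g: SimGenome,
    coverage: float,
    read_len: int = 100,
    err_rate: float = 0.01,
    seed: int = 0,
    chunk: int = 200_000,
) -> np.ndarray:
    """Uniform reads from both strands of all copies, as a (n_reads, read_len)
    uint8 matrix with substitution errors applied.

    The number of reads is ceil(coverage * L * ploidy / read_len), the
    stopping rule "total bases >= coverage * L * ploidy".
    """
    L = g.length
    if read_len > L:
        raise ValueError(f"read_len {read_len} exceeds genome length {L}")
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if not 0.0 <= err_rate < 1.0:
        raise ValueError("err_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_reads = math.ceil(coverage * L * g.ploidy / read_len)
    copy_idx = rng.integers(0, g.ploidy, size=n_reads)
    starts = rng.integers(0, L - read_len + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    reads = g.copies[copy_idx[:, None], starts[:, None] + np.arange(read_len)]
    rc = strands == 1
    if rc.any():
        reads[rc] = 3 - reads[rc][:, ::-1]
    if err_rate > 0:
        for lo in range(0, n_reads, chunk):
            block = reads[lo : lo + chunk]
            mask = rng.random(block.shape) < err_rate
            n_err = int(mask.sum())
            if n_err:
                block[mask] = (
                    block[mask] + rng.integers(1, 4, size=n_err, dtype=np.uint8)
                ) % 4
    return reads


def simulate_reads(
    g: SimGenome,
    coverage: float,
    read_len: int = 100,
    err_rate: float = 0.01,
    seed: int = 0,
) -> Iterator[tuple[str, str, str]]:
    """FASTQ records (id, sequence, quality) for one genome.

    Qualities are constant at the Phred score matching err_rate (Q40 when
    err_rate is 0), since the error model is a uniform substitution rate.
    """
    reads = sample_read_matrix(g, coverage, read_len, err_rate, seed)
    q = 40 if err_rate == 0 else min(40, max(2, round(-10 * math.log10(err_rate))))
    qual = chr(q + 33) * read_len
    for i in range(reads.shape[0]):
        yield f"{g.label}_r{i + 1}", seq_to_str(reads[i]), qual


def true_distance_matrix(lin: SimLineage) -> DistanceMatrix:
    """Realised per-mutable-site divergence between all genome pairs
    (copies averaged for polyploids); recomputed directly from sequences."""
    return _pairwise_divergence(lin.genomes, lin.regions)


# ---------------------------------------------------------------------------
# file output


def write_genome_fasta(g: SimGenome, path: Union[str, Path], width: int = 80) -> None:
    path = Path(path)
    with open(path, "w", encoding="ascii") as fh:
        for c in range(g.ploidy):
            fh.write(f">{g.label}_copy{c + 1}\n")
            s = seq_to_str(g.copies[c])
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_reads_fastq(
    g: SimGenome,
    path: Union[str, Path],
    coverage: float,
    read_len: int = 100,
    err_rate: float = 0.01,
    seed: int = 0,
) -> int:
    """Write simulated reads as FASTQ; returns the number of reads written."""
    n = 0
    with open(path, "w", encoding="ascii") as fh:
        for rid, seq, qual in simulate_reads(g, coverage, read_len, err_rate, seed):
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def write_manifest(lin: SimLineage, path: Union[str, Path], extra: dict | None = None) -> None:
    payload = dict(lin.params)
    payload["labels"] = lin.labels
    payload["ploidies"] = [g.ploidy for g in lin.genomes]
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="ascii")
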