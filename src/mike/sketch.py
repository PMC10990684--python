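"""Prefix-grouped one-permutation MinHash sketches of k-mer sets.

Each 2k-bit k-mer code is split into a prefix of ceil(k/2) bases and a
suffix of floor(k/2) bases.  K-mers sharing a prefix form a group; a single
random permutation pi of [1, 4**suffix_bases] (shared by every sample of a
run) assigns each suffix a rank, and the group's fingerprint is the minimum
rank among its present suffixes.  Conceptually this is the row-wise first
non-zero of a one-hot existence matrix multiplied by pi; it is computed here
as a sparse per-group minimum in one linear pass over the sorted codes.
Keeping one fingerprint per occupied prefix group reduces the universe from
4**k to 4**floor(k/2) while the probability that two samples agree on a
group's fingerprint equals the Jaccard similarity of that group's suffix
sets, which makes the fraction of agreeing groups an estimator of the global
Jaccard coefficient.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .kmer_io import SortedKmerSet

__all__ = [
    "SplitParams",
    "Permutation",
    "Sketch",
    "SketchError",
    "IncompatibleSketchError",
    "split_kmer",
    "build_permutation",
    "build_sketch",
    "estimate_jaccard",
    "exact_jaccard",
    "write_sketch",
    "read_sketch",
]

DEFAULT_PERM_SEED = 42
_FORMAT_VERSION = 1
_MAX_SUFFIX_BASES = 12  # permutation table of at most 4**12 = 16.7M entries


class SketchError(ValueError):
    pass


class IncompatibleSketchError(SketchError):
    """Two sketches were built with different (k, split, permutation seed)."""


@dataclass(frozen=True)
class SplitParams:
    """Prefix/suffix split of a k-mer; prefix takes the extra base for odd k."""

    k: int
    prefix_bases: int
    suffix_bases: int

    @classmethod
    def from_k(cls, k: int) -> "SplitParams":
        suffix = k // 2
        return cls(k=k, prefix_bases=k - suffix, suffix_bases=suffix)

    def __post_init__(self) -> None:
        if self.prefix_bases + self.suffix_bases != self.k:
            raise ValueError("prefix_bases + suffix_bases must equal k")
        if self.prefix_bases < 1 or self.suffix_bases < 0:
            raise ValueError("invalid split")


@dataclass
class Permutation:
    """Explicit bijection from suffix codes [0, 4**s - 1] onto ranks [1, 4**s].

    Rank 0 is reserved for "suffix absent", matching the first-non-zero
    selection rule.  The table is a Fisher-Yates shuffle drawn from numpy's
    PCG64 generator seeded with `seed`; identical (seed, suffix_bases) give
    identical tables on every platform.
    """

    seed: int
    suffix_bases: int
    table: np.ndarray

    @property
    def domain(self) -> int:
        return 4**self.suffix_bases


def build_permutation(seed: int, suffix_bases: int) -> Permutation:
    if suffix_bases > _MAX_SUFFIX_BASES:
        raise SketchError(
            f"suffix_bases={suffix_bases} would materialise a 4**{suffix_bases}-entry "
            f"table; maximum supported is {_MAX_SUFFIX_BASES}"
        )
    domain = 4**suffix_bases
    rng = np.random.Generator(np.random.PCG64(seed))
    table = rng.permutation(domain).astype(np.uint64) + np.uint64(1)
    return Permutation(seed=int(seed), suffix_bases=suffix_bases, table=table)


def split_kmer(code, split: SplitParams):
    """Split a code (scalar or ndarray) into (prefix, suffix) codes."""
    shift = np.uint64(2 * split.suffix_bases)
    if isinstance(code, np.ndarray):
        c = code.astype(np.uint64)
        return c >> shift, c & np.uint64(4**split.suffix_bases - 1)
    c = int(code)
    return c >> int(shift), c & (4**split.suffix_bases - 1)


@dataclass
class Sketch:
    """Per-prefix-group minhash fingerprints of one sample."""

    split: SplitParams
    perm_seed: int
    prefixes: np.ndarray  # sorted uint64 prefix codes of occupied groups
    fingerprints: np.ndarray  # uint64 in [1, 4**suffix_bases], parallel to prefixes
    label: str = ""

    def __post_init__(self) -> None:
        self.prefixes = np.asarray(self.prefixes, dtype=np.uint64)
        self.fingerprints = np.asarray(self.fingerprints, dtype=np.uint64)
        if self.prefixes.shape != self.fingerprints.shape:
            raise SketchError("prefixes and fingerprints must be parallel arrays")
        if self.prefixes.size and not np.all(self.prefixes[1:] > self.prefixes[:-1]):
            raise SketchError("prefixes must be strictly increasing")
        if self.fingerprints.size and int(self.fingerprints.min()) < 1:
            raise SketchError("fingerprints must be >= 1")

    @property
    def n_groups(self) -> int:
        return int(self.prefixes.size)

    def compatible_with(self, other: "Sketch") -> bool:
        return self.split == other.split and self.perm_seed == other.perm_seed


def build_sketch(
    kmers: SortedKmerSet,
    split: SplitParams | None = None,
    perm: Permutation | None = None,
    label: str = "",
) -> Sketch:
    """One linear pass over sorted codes: group by prefix, keep min permuted suffix."""
    k = kmers.params.k
    if split is None:
        split = SplitParams.from_k(k)
    elif split.k != k:
        raise SketchError(f"split.k={split.k} does not match k-mer set k={k}")
    if perm is None:
        perm = build_permutation(DEFAULT_PERM_SEED, split.suffix_bases)
    elif perm.suffix_bases != split.suffix_bases:
        raise SketchError("permutation domain does not match suffix length")
    codes = kmers.codes
    if codes.size == 0:
        empty = np.empty(0, dtype=np.uint64)
        return Sketch(split, perm.seed, empty, empty.copy(), label or kmers.source_label)
    pre, suf = split_kmer(codes, split)
    # sorted codes => equal prefixes are contiguous runs
    starts = np.flatnonzero(np.concatenate(([True], pre[1:] != pre[:-1])))
    fingerprints = np.minimum.reduceat(perm.table[suf], starts)
    return Sketch(split, perm.seed, pre[starts], fingerprints, label or kmers.source_label)


def estimate_jaccard(a: Sketch, b: Sketch) -> float:
    """Jaccard estimate: matching fingerprints over the union of occupied groups.

    A group occupied in only one sketch counts in the denominator only;
    groups empty in both sketches are ignored (no densification).
    """
    if not a.compatible_with(b):
        raise IncompatibleSketchError(
            f"incompatible sketches: ({a.split}, seed={a.perm_seed}) vs "
            f"({b.split}, seed={b.perm_seed})"
        )
    if a.n_groups == 0 and b.n_groups == 0:
        raise SketchError("Jaccard undefined: both sketches are empty")
    common, ia, ib = np.intersect1d(a.prefixes, b.prefixes, return_indices=True)
    matches = int(np.count_nonzero(a.fingerprints[ia] == b.fingerprints[ib]))
    union = a.n_groups + b.n_groups - common.size
    return matches / union


def exact_jaccard(a: SortedKmerSet, b: SortedKmerSet) -> float:
    """Ground-truth Jaccard |a & b| / |a | b| by sorted-set intersection."""
    if a.params.k != b.params.k:
        raise SketchError(f"k mismatch: {a.params.k} vs {b.params.k}")
    if a.n_kmers == 0 and b.n_kmers == 0:
        raise SketchError("Jaccard undefined: both k-mer sets are empty")
    inter = np.intersect1d(a.codes, b.codes, assume_unique=True).size
    union = a.n_kmers + b.n_kmers - inter
    return inter / union


def write_sketch(s: Sketch, path: Union[str, Path]) -> None:
    """Versioned text format: header lines, then `prefix<TAB>fingerprint` rows."""
    path = Path(path)
    body = "".join(
        f"{int(p)}\t{int(f)}\n" for p, f in zip(s.prefixes, s.fingerprints)
    )
    crc = zlib.crc32(body.encode("ascii")) & 0xFFFFFFFF
    with open(path, "w", encoding="ascii") as fh:
        fh.write(f"#mike-sketch\tversion={_FORMAT_VERSION}\n")
        fh.write(
            f"#k={s.split.k}\tprefix_bases={s.split.prefix_bases}"
            f"\tsuffix_bases={s.split.suffix_bases}\tperm_seed={s.perm_seed}"
            f"\tprng=pcg64\tlabel={s.label}\tn_groups={s.n_groups}\tcrc32={crc:08x}\n"
        )
        fh.write(body)


def read_sketch(path: Union[str, Path]) -> Sketch:
    path = Path(path)
    with open(path, "r", encoding="ascii") as fh:
        magic = fh.readline().rstrip("\n")
        if not magic.startswith("#mike-sketch"):
            raise SketchError(f"{path}: not a mike sketch file")
        fields = dict(
            kv.split("=", 1) for kv in magic.split("\t")[1:] if "=" in kv
        )
        if int(fields.get("version", -1)) != _FORMAT_VERSION:
            raise SketchError(f"{path}: unsupported sketch version {fields.get('version')}")
        header = fh.readline().rstrip("\n")
        meta = dict(kv.split("=", 1) for kv in header.lstrip("#").split("\t") if "=" in kv)
        try:
            k = int(meta["k"])
            prefix_bases = int(meta["prefix_bases"])
            suffix_bases = int(meta["suffix_bases"])
            perm_seed = int(meta["perm_seed"])
            n_groups = int(meta["n_groups"])
            crc_expect = int(meta["crc32"], 16)
        except (KeyError, ValueError) as exc:
            raise SketchError(f"{path}: malformed sketch header") from exc
        body = fh.read()
    if (zlib.crc32(body.encode("ascii")) & 0xFFFFFFFF) != crc_expect:
        raise SketchError(f"{path}: checksum mismatch (truncated or corrupted file)")
    lines = body.splitlines()
    if len(lines) != n_groups:
        raise SketchError(f"{path}: expected {n_groups} rows, found {len(lines)}")
    if lines:
        data = np.array(
            [ln.split("\t") for ln in lines], dtype=np.uint64
        )
        prefixes, fingerprints = data[:, 0], data[:, 1]
    else:
        prefixes = np.empty(0, dtype=np.uint64)
        fingerprints = np.empty(0, dtype=np.uint64)
    split = SplitParams(k=k, prefix_bases=prefix_bases, suffix_bases=suffix_bases)
    return Sketch(split, perm_seed, prefixes, fingerprints, meta.get("label", ""))
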