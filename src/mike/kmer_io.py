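"""Canonical 2-bit k-mer extraction, counting and KMC text-dump interop.

DNA bases are encoded two bits per base (A=00, C=01, G=10, T=11) with the
first base of a k-mer in the highest-order position, so the integer order of
codes coincides with the lexicographic order of the decoded strings.  A
sample's k-mer content is held as a :class:`SortedKmerSet`: the strictly
increasing array of distinct canonical codes that survived an abundance
filter.  Counting is fully vectorised: reads are packed into a padded byte
matrix and codes for all windows are produced by a rolling 2-bit shift, which
keeps million-read inputs tractable in pure numpy.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

import numpy as np

__all__ = [
    "KmerParams",
    "SortedKmerSet",
    "AmbiguousBaseError",
    "KmerFormatError",
    "encode_kmer",
    "decode_kmer",
    "revcomp_code",
    "canonical_code",
    "extract_kmers",
    "count_kmers",
    "read_kmc_dump",
]

# 256-entry base -> 2-bit lookup; 255 marks anything that is not ACGT/acgt.
_INVALID = np.uint8(255)
BASE_TO_CODE = np.full(256, _INVALID, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    BASE_TO_CODE[ord(_b)] = _i
    BASE_TO_CODE[ord(_b.lower())] = _i
CODE_TO_BASE = "ACGT"


class AmbiguousBaseError(ValueError):
    """Raised when a k-mer contains a base outside {A, C, G, T}."""


class KmerFormatError(ValueError):
    """Raised on malformed sequence or dump input."""


@dataclass(frozen=True)
class KmerParams:
    """Parameters governing k-mer extraction.

    k is capped at 31 so a k-mer fits a single 64-bit code; min_count is the
    abundance threshold below which a distinct k-mer is discarded (removes
    most sequencing-error k-mers); canonical folds each k-mer with its
    reverse complement because read data is unstranded.
    """

    k: int = 21
    min_count: int = 2
    canonical: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 31:
            raise ValueError(f"k must be in [1, 31], got {self.k}")
        if self.min_count < 1:
            raise ValueError(f"min_count must be >= 1, got {self.min_count}")


@dataclass
class SortedKmerSet:
    """Distinct canonical k-mer codes of one sample, strictly ascending."""

    params: KmerParams
    codes: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint64)
        if self.codes.size and not np.all(self.codes[1:] > self.codes[:-1]):
            raise ValueError("codes must be strictly increasing")
        if self.codes.size and int(self.codes[-1]) >= 4 ** self.params.k:
            raise ValueError("code exceeds 4**k")

    @property
    def n_kmers(self) -> int:
        return int(self.codes.size)

    def __len__(self) -> int:
        return self.n_kmers


def encode_kmer(seq: str) -> int:
    """Encode a DNA string as a 2-bit-per-base integer (first base high)."""
    code = 0
    for ch in seq:
        b = BASE_TO_CODE[ord(ch)]
        if b == _INVALID:
            raise AmbiguousBaseError(f"ambiguous base {ch!r} in k-mer {seq!r}")
        code = (code << 2) | int(b)
    return code


def decode_kmer(code: int, k: int) -> str:
    """Inverse of :func:`encode_kmer`."""
    if code < 0 or code >= 4**k:
        raise ValueError(f"code {code} out of range for k={k}")
    return "".join(CODE_TO_BASE[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))


def revcomp_code(code, k: int):
    """Reverse complement of a 2-bit code (scalar int or uint64 ndarray)."""
    if isinstance(code, np.ndarray):
        c = code.astype(np.uint64, copy=True)
        rc = np.zeros_like(c)
        three = np.uint64(3)
        two = np.uint64(2)
        for _ in range(k):
            rc = (rc << two) | (three - (c & three))
            c >>= two
        return rc
    c = int(code)
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (3 - (c & 3))
        c >>= 2
    return rc


def canonical_code(code, k: int):
    """min(code, revcomp(code)); idempotent, strand-symmetric."""
    rc = revcomp_code(code, k)
    if isinstance(code, np.ndarray):
        return np.minimum(code.astype(np.uint64), rc)
    return min(int(code), int(rc))


def _reads_to_matrix(reads: Sequence[str]) -> np.ndarray:
    """Pack variable-length reads into a byte matrix padded with the invalid code."""
    if not reads:
        return np.empty((0, 0), dtype=np.uint8)
    width = max(len(r) for r in reads)
    mat = np.full((len(reads), width), _INVALID, dtype=np.uint8)
    for i, r in enumerate(reads):
        if r:
            mat[i, : len(r)] = BASE_TO_CODE[np.frombuffer(r.encode("ascii"), dtype=np.uint8)]
    return mat


def codes_from_matrix(mat: np.ndarray, k: int, canonical: bool = True) -> np.ndarray:
    """All valid k-mer window codes of a (reads x positions) 2-bit matrix.

    Cells > 3 (ambiguous bases / padding) invalidate every window that
    overlaps them.  Rolling update: one pass over columns, vectorised over
    reads.  Output order is column-major over windows; callers that need
    per-read window order should pass a single row.
    """
    n, width = mat.shape
    if n == 0 or width < k:
        return np.empty(0, dtype=np.uint64)
    mask = np.uint64(4**k - 1)
    shift = np.uint64(2 * (k - 1))
    two = np.uint64(2)
    three = np.uint64(3)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    run = np.zeros(n, dtype=np.int32)
    chunks = []
    for j in range(width):
        col = mat[:, j]
        bad = col > 3
        b = np.where(bad, 0, col).astype(np.uint64)
        fwd = ((fwd << two) | b) & mask
        rev = (rev >> two) | ((three - b) << shift)
        run = np.where(bad, 0, run + 1)
        if j >= k - 1:
            ok = run >= k
            if ok.any():
                c = fwd[ok]
                if canonical:
                    c = np.minimum(c, rev[ok])
                chunks.append(c)
    if not chunks:
        return np.empty(0, dtype=np.uint64)
    return np.concatenate(chunks)


def codes_from_sequence(arr: np.ndarray, k: int, canonical: bool = True) -> np.ndarray:
    """All valid window codes of one long 2-bit sequence, in window order.

    Vectorised over positions (k shifted-slice OR passes), so it stays fast
    for megabase genomes where the column-rolling matrix path would not.
    """
    L = arr.size
    if L < k:
        return np.empty(0, dtype=np.uint64)
    n = L - k + 1
    bad = arr > 3
    b = np.where(bad, 0, arr).astype(np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        codes |= b[j : j + n] << np.uint64(2 * (k - 1 - j))
    if bad.any():
        csum = np.concatenate(([0], np.cumsum(bad)))
        ok = (csum[k:] - csum[:n]) == 0
    else:
        ok = slice(None)
    codes = codes[ok]
    if canonical:
        rc = np.zeros(n, dtype=np.uint64)
        three = np.uint64(3)
        for j in range(k):
            rc |= (three - b[j : j + n]) << np.uint64(2 * j)
        codes = np.minimum(codes, rc[ok])
    return codes


def extract_kmers(read: str, params: KmerParams) -> np.ndarray:
    """Canonical codes of every clean window of one read, in window order."""
    if not read:
        return np.empty(0, dtype=np.uint64)
    arr = BASE_TO_CODE[np.frombuffer(read.encode("ascii"), dtype=np.uint8)]
    return codes_from_sequence(arr, params.k, params.canonical)


def _is_gzip(path: Path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == b"\x1f\x8b"


def _open_text(path: Path) -> io.TextIOBase:
    if _is_gzip(path):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, "rt", encoding="ascii")


def _iter_sequences(path: Path) -> Iterator[str]:
    """Yield sequences from a FASTA or FASTQ file (plain or gzip), sniffed by content."""
    from Bio import SeqIO

    with _open_text(path) as fh:
        head = ""
        while True:
            head = fh.readline()
            if head == "":
                return
            if head.strip():
                break
        fmt = None
        first = head.lstrip()[0]
        if first == ">":
            fmt = "fasta"
        elif first == "@":
            fmt = "fastq"
        else:
            raise KmerFormatError(
                f"{path}: not recognisable as FASTA or FASTQ (first record starts with {first!r})"
            )
        stream = io.StringIO(head + fh.read())
        try:
            for rec in SeqIO.parse(stream, fmt):
                yield str(rec.seq)
        except ValueError as exc:
            raise KmerFormatError(f"{path}: {exc}") from exc


ReadsInput = Union[str, Path, Iterable[str]]


def count_kmers(
    reads: ReadsInput,
    params: KmerParams = KmerParams(),
    label: str = "",
    batch_size: int = 100_000,
) -> SortedKmerSet:
    """Count canonical k-mers of a sample and keep those with count >= min_count.

    `reads` is a FASTA/FASTQ path (optionally gzipped) or any iterable of
    sequence strings.  Windows containing ambiguous bases are skipped.
    """
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        if not path.exists():
            raise KmerFormatError(f"no such file: {path}")
        seq_iter: Iterable[str] = _iter_sequences(path)
        if not label:
            label = path.name
    else:
        seq_iter = reads

    chunks = []
    batch: list[str] = []
    for seq in seq_iter:
        batch.append(seq)
        if len(batch) >= batch_size:
            chunks.append(codes_from_matrix(_reads_to_matrix(batch), params.k, params.canonical))
            batch = []
    if batch:
        chunks.append(codes_from_matrix(_reads_to_matrix(batch), params.k, params.canonical))
    codes = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.uint64)
    return kmer_set_from_codes(codes, params, label)


def kmer_set_from_codes(
    codes: np.ndarray, params: KmerParams, label: str = ""
) -> SortedKmerSet:
    """Aggregate a flat array of (already canonical) codes into a filtered sorted set."""
    if codes.size == 0:
        return SortedKmerSet(params, np.empty(0, dtype=np.uint64), label)
    uniq, counts = np.unique(codes, return_counts=True)
    return SortedKmerSet(params, uniq[counts >= params.min_count], label)


def read_kmc_dump(
    path: Union[str, Path], params: KmerParams | None = None, label: str = ""
) -> SortedKmerSet:
    """Parse a KMC text dump (`KMER<TAB>COUNT` per line) into a SortedKmerSet.

    k is inferred from the first k-mer; rows below min_count are dropped and
    the output is sorted regardless of input order.  With canonical=true,
    counts of a k-mer and its reverse complement are pooled before filtering.
    """
    path = Path(path)
    if not path.exists():
        raise KmerFormatError(f"no such file: {path}")
    kmers: list[str] = []
    counts: list[int] = []
    k = None
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise KmerFormatError(f"{path}:{lineno}: expected KMER<TAB>COUNT, got {line!r}")
            kmer, cnt = parts
            if k is None:
                k = len(kmer)
            elif len(kmer) != k:
                raise KmerFormatError(
                    f"{path}:{lineno}: k-mer length {len(kmer)} differs from first ({k})"
                )
            try:
                c = int(cnt)
            except ValueError:
                raise KmerFormatError(f"{path}:{lineno}: non-integer count {cnt!r}") from None
            kmers.append(kmer)
            counts.append(c)
    if k is None:
        p = params or KmerParams()
        return SortedKmerSet(p, np.empty(0, dtype=np.uint64), label or path.name)
    p = params or KmerParams(k=k)
    if p.k != k:
        raise KmerFormatError(f"{path}: dump k={k} does not match requested k={p.k}")
    mat = _reads_to_matrix(kmers)
    if (mat > 3).any():
        bad = int(np.argmax((mat > 3).any(axis=1)))
        raise KmerFormatError(f"{path}: non-ACGT k-mer at record {bad + 1}")
    codes = codes_from_matrix(mat, k, canonical=False)  # one window per row
    if p.canonical:
        codes = canonical_code(codes, k)
    cnt_arr = np.asarray(counts, dtype=np.int64)
    order = np.argsort(codes, kind="stable")
    codes = codes[order]
    cnt_arr = cnt_arr[order]
    uniq, start = np.unique(codes, return_index=True)
    pooled = np.add.reduceat(cnt_arr, start)
    return SortedKmerSet(p, uniq[pooled >= p.min_count], label or path.name)
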