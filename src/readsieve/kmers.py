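"""Canonical k-mer extraction, 2-bit encoding and hashing.

A k-mer (k <= 32) is packed into a single 64-bit word at 2 bits per base
(A=0, C=1, G=2, T=3, leftmost base in the most-significant occupied bits),
so lexicographic comparison of two equal-length k-mer strings under the
A<C<G<T order is exactly integer comparison of their encodings.  The
*canonical* form of a k-mer is the lexicographically smaller of the k-mer
and its reverse complement; both strands of a duplex therefore map to the
same canonical value.

Positions ("windows") of a read whose k bases include an ambiguous
character, or — when a quality threshold q > 0 is given — a base with
Phred quality below q, yield no k-mer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence, Union

import numpy as np

__all__ = [
    "CanonicalKmer",
    "KmerStream",
    "canonicalize",
    "decode_kmer",
    "encode_kmer",
    "extract_kmers",
    "hash_kmer",
    "hash_kmers",
    "revcomp",
]

MAX_K = 32

_U64 = np.uint64
_MASK64 = (1 << 64) - 1

# base -> 2-bit code; everything else (incl. IUPAC ambiguity codes) is invalid
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCATGCA")


class AmbiguousBaseError(ValueError):
    """Sequence contains a character outside {A, C, G, T}."""


class KmerParameterError(ValueError):
    """k is outside the supported range 1..32."""


def _check_k(k: int) -> None:
    if not 1 <= k <= MAX_K:
        raise KmerParameterError(f"k must be in 1..{MAX_K}, got {k}")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case-preserving complement)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_kmer(seq: str) -> int:
    """Pack an ACGT string (len <= 32) into an integer, 2 bits per base."""
    _check_k(len(seq))
    value = 0
    for ch in seq.upper():
        code = _CODE[ord(ch)]
        if code == 255:
            raise AmbiguousBaseError(f"non-ACGT character {ch!r}")
        value = (value << 2) | int(code)
    return value


def decode_kmer(value: int, k: int) -> str:
    """Inverse of :func:`encode_kmer`."""
    _check_k(k)
    return "".join(_BASES[(value >> (2 * (k - 1 - i))) & 3] for i in range(k))


def _revcomp_value(value: int, k: int) -> int:
    """Reverse complement on the 2-bit encoding."""
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | ((value & 3) ^ 3)
        value >>= 2
    return rc


@dataclass(frozen=True)
class CanonicalKmer:
    """A canonical k-mer: 2-bit packed ``value`` and its length ``k``."""

    value: int
    k: int

    def __post_init__(self) -> None:
        _check_k(self.k)

    def __str__(self) -> str:
        return decode_kmer(self.value, self.k)


def canonicalize(seq: str) -> CanonicalKmer:
    """Canonical form of ``seq``: min(seq, revcomp(seq)) lexicographically.

    Comparison is done on the 2-bit encodings, which orders strings
    identically to A<C<G<T string comparison.
    """
    fwd = encode_kmer(seq)
    rev = _revcomp_value(fwd, len(seq))
    return CanonicalKmer(min(fwd, rev), len(seq))


# ---------------------------------------------------------------------------
# hashing — a single well-mixed hash H, Murmur3 fmix64 finalizer
# ---------------------------------------------------------------------------

def _fmix64(x: int) -> int:
    x &= _MASK64
    x ^= x >> 33
    x = (x * 0xFF51AFD7ED558CCD) & _MASK64
    x ^= x >> 33
    x = (x * 0xC4CEB9FE1A85EC53) & _MASK64
    x ^= x >> 33
    return x


DEFAULT_SEED = 0x5EED_CAFE


def hash_kmer(kmer: Union[CanonicalKmer, int], m: int, seed: int = DEFAULT_SEED) -> int:
    """Map a canonical k-mer to a position in ``[0, m)``.

    Deterministic for fixed (kmer, m, seed) and identical across platforms:
    pure 64-bit integer mixing, no byte-order or word-size dependence.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    value = kmer.value if isinstance(kmer, CanonicalKmer) else int(kmer)
    return _fmix64(value ^ _fmix64(seed)) % m


def hash_kmers(values: np.ndarray, m: int, seed: int = DEFAULT_SEED) -> np.ndarray:
    """Vectorised :func:`hash_kmer` over a uint64 array of canonical values."""
    if m < 1:
        raise ValueError("m must be >= 1")
    x = values.astype(_U64) ^ _U64(_fmix64(seed))
    with np.errstate(over="ignore"):
        x ^= x >> _U64(33)
        x *= _U64(0xFF51AFD7ED558CCD)
        x ^= x >> _U64(33)
        x *= _U64(0xC4CEB9FE1A85EC53)
        x ^= x >> _U64(33)
    return (x % _U64(m)).astype(np.int64)


# ---------------------------------------------------------------------------
# window extraction
# ---------------------------------------------------------------------------

@dataclass
class KmerStream:
    """Ordered canonical k-mers of a read with their 0-based start offsets.

    Windows containing an ambiguous base, or (when ``q > 0``) a base of
    quality below ``q``, are absent.  ``starts`` is strictly increasing.
    """

    read_id: str
    k: int
    read_length: int
    starts: np.ndarray  # int64, 0-based window starts
    values: np.ndarray  # uint64 canonical encodings, parallel to starts

    def __len__(self) -> int:
        return len(self.starts)

    def items(self) -> Iterator[tuple[int, CanonicalKmer]]:
        for s, v in zip(self.starts, self.values):
            yield int(s), CanonicalKmer(int(v), self.k)


class MalformedRecordError(ValueError):
    """Quality string present but of a different length than the sequence."""


def _qual_array(quals: Union[str, Sequence[int], np.ndarray]) -> np.ndarray:
    if isinstance(quals, str):
        return np.frombuffer(quals.encode("ascii"), dtype=np.uint8).astype(np.int64) - 33
    return np.asarray(quals, dtype=np.int64)


def extract_kmers(
    read_seq: str,
    quals: Optional[Union[str, Sequence[int], np.ndarray]] = None,
    *,
    k: int,
    q: int = 0,
    read_id: str = "",
) -> KmerStream:
    """All admissible canonical k-mers of a read, left to right.

    ``quals`` may be a Phred+33 string or a sequence of integer scores;
    with ``quals`` absent or ``q == 0`` no quality masking occurs.
    """
    _check_k(k)
    n = len(read_seq)
    if quals is not None and len(quals) != n:
        raise MalformedRecordError(
            f"quality length {len(quals)} != sequence length {n} for read {read_id!r}"
        )
    if n < k:
        empty = np.empty(0, dtype=np.int64)
        return KmerStream(read_id, k, n, empty, empty.astype(_U64))

    codes = _CODE[np.frombuffer(read_seq.encode("ascii"), dtype=np.uint8)]
    valid = codes != 255
    if q > 0 and quals is not None:
        valid &= _qual_array(quals) >= q

    # a window is admissible iff all k of its bases are valid
    ok = (
        np.convolve(valid.astype(np.int64), np.ones(k, dtype=np.int64), mode="valid")
        == k
    )
    starts = np.nonzero(ok)[0].astype(np.int64)
    if len(starts) == 0:
        return KmerStream(read_id, k, n, starts, starts.astype(_U64))

    codes64 = np.where(valid, codes, 0).astype(_U64)
    shifts = (_U64(2) * np.arange(k - 1, -1, -1, dtype=_U64))
    win = np.lib.stride_tricks.sliding_window_view(codes64, k)[starts]
    with np.errstate(over="ignore"):
        fwd = (win << shifts).sum(axis=1, dtype=_U64)
        rev = ((win ^ _U64(3)) << shifts[::-1]).sum(axis=1, dtype=_U64)
    values = np.minimum(fwd, rev)
    return KmerStream(read_id, k, n, starts, values)
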