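"""Succinct k-mer -> gene-set index for a gene panel.

The index is a triple ``<BF, P, I>``:

* ``BF`` — an m-bit Bloom filter with a *single* hash H holding every
  canonical k-mer of every panel gene;
* ``I`` — the concatenation, in set-bit order, of the per-bit lists of
  IDs of the genes whose k-mers hash to that bit;
* ``P`` — a bit vector of length ``|I|`` with a 1 at the last element of
  each list, so the list for the v-th set bit of BF is delimited by the
  (v-1)-th and v-th 1s of P.

Construction is three passes over the panel k-mers: (1) populate BF;
(2) for each gene in ID order append its ID to the list of each of its
k-mers' bits (each bit once per gene, so lists are strictly increasing
and duplicate-free); (3) concatenate the lists into I and mark the list
ends in P.

A query for a k-mer whose BF bit is clear is a definitive miss.  A hit
returns the list for that bit, which is a superset of the true gene set:
hash collisions between distinct k-mers can add spurious genes but never
remove true ones.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np

from .bitvector import RankSelectBits
from .kmers import (
    DEFAULT_SEED,
    MAX_K,
    CanonicalKmer,
    KmerParameterError,
    extract_kmers,
    hash_kmers,
)

__all__ = [
    "GenePanel",
    "PanelIndex",
    "build_index",
    "build_exact_oracle",
    "load_index",
    "save_index",
]

logger = logging.getLogger(__name__)

DEFAULT_BLOOM_BITS = 1 << 33  # 1 GB, the tool's stock operating point


class PanelError(ValueError):
    """Invalid gene panel (empty, duplicate names, empty sequence)."""


class IndexFormatError(ValueError):
    """Corrupt or incompatible on-disk index."""


@dataclass
class GenePanel:
    """Ordered gene records; IDs are 0..n-1 in input order."""

    records: List[Tuple[str, str]]
    gene_map: Dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise PanelError("gene panel is empty")
        self.gene_map = {}
        for name, seq in self.records:
            if name in self.gene_map:
                raise PanelError(f"duplicate gene name {name!r}")
            if not seq:
                raise PanelError(f"gene {name!r} has an empty sequence")
            self.gene_map[name] = len(self.gene_map)

    @property
    def names(self) -> List[str]:
        return [name for name, _ in self.records]

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_fasta(cls, path) -> "GenePanel":
        from .io import read_fasta

        return cls(list(read_fasta(path)))


@dataclass
class PanelIndex:
    """The built ``<BF, P, I>`` triple plus its parameters and name table."""

    bf: RankSelectBits
    p: RankSelectBits
    ids: np.ndarray  # I: int32 gene IDs
    k: int
    m: int
    seed: int
    gene_names: List[str]
    # 0-based list boundaries derived from P: list v is ids[bounds[v]:bounds[v+1]]
    _bounds: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ends = np.array(
            [self.p.select1(j) for j in range(1, self.p.ones_count + 1)],
            dtype=np.int64,
        )
        self._bounds = np.concatenate([[0], ends + 1])

    @property
    def ones_count(self) -> int:
        return self.bf.ones_count

    def query(self, kmer: Union[CanonicalKmer, int]) -> List[int]:
        """Gene IDs whose k-mer set (apparently) contains ``kmer``.

        Empty when the Bloom bit is clear.  Otherwise, with the hit at the
        v-th set bit of BF (v = rank1(BF, h) + 1 since BF[h] = 1), the
        answer is the v-th delimited segment of I.
        """
        value = kmer.value if isinstance(kmer, CanonicalKmer) else int(kmer)
        h = int(hash_kmers(np.array([value], dtype=np.uint64), self.m, self.seed)[0])
        if not self.bf[h]:
            return []
        v0 = self.bf.rank1(h)  # 0-based segment ordinal
        return self.ids[self._bounds[v0] : self._bounds[v0 + 1]].tolist()

    def query_many(self, values: np.ndarray) -> List[np.ndarray]:
        """Vectorised membership + segment lookup for an array of values."""
        h = hash_kmers(np.asarray(values, dtype=np.uint64), self.m, self.seed)
        hit = self.bf.get_many(h)
        out: List[np.ndarray] = [_EMPTY_IDS] * len(h)
        if hit.any():
            idx = np.nonzero(hit)[0]
            v0 = self.bf.rank1_many(h[idx])
            for i, v in zip(idx, v0):
                out[i] = self.ids[self._bounds[v] : self._bounds[v + 1]]
        return out


_EMPTY_IDS = np.empty(0, dtype=np.int32)


def _gene_bit_positions(seq: str, k: int, m: int, seed: int) -> np.ndarray:
    """Deduplicated BF positions of one gene's canonical k-mers."""
    stream = extract_kmers(seq, None, k=k, q=0)
    if len(stream) == 0:
        return np.empty(0, dtype=np.int64)
    return np.unique(hash_kmers(stream.values, m, seed))


def build_index(
    panel: GenePanel,
    k: int,
    m: int = DEFAULT_BLOOM_BITS,
    seed: int = DEFAULT_SEED,
) -> PanelIndex:
    """Build the ``<BF, P, I>`` index for a panel.

    Genes shorter than k keep their ID (the name table stays stable) but
    contribute no k-mers; a warning is logged for each.
    """
    if not 1 <= k <= MAX_K:
        raise KmerParameterError(f"k must be in 1..{MAX_K}, got {k}")
    if m < 1:
        raise ValueError("m must be >= 1")

    per_gene: List[np.ndarray] = []
    for name, seq in panel.records:
        pos = _gene_bit_positions(seq, k, m, seed)
        if len(pos) == 0:
            logger.warning("gene %s is shorter than k=%d; it contributes no k-mers", name, k)
        per_gene.append(pos)

    # pass 1: populate the Bloom filter
    bf = RankSelectBits(m)
    for pos in per_gene:
        bf.set_bits(pos)
    bf.freeze()
    ell = bf.ones_count

    # pass 2: append each gene's ID to the list of each of its set bits.
    # Genes are scanned in ID order and each bit appears once per gene, so a
    # stable sort by bit ordinal yields strictly increasing, duplicate-free
    # lists directly.
    ordinals = np.concatenate(
        [bf.rank1_many(pos) for pos in per_gene if len(pos)]
        or [np.empty(0, dtype=np.int64)]
    )
    gene_ids = np.concatenate(
        [np.full(len(pos), gid, dtype=np.int32) for gid, pos in enumerate(per_gene) if len(pos)]
        or [np.empty(0, dtype=np.int32)]
    )
    order = np.argsort(ordinals, kind="stable")
    ids = gene_ids[order]

    # pass 3: concatenate lists into I; P marks each cumulative list end
    seg_lengths = np.bincount(ordinals, minlength=ell)
    ends = np.cumsum(seg_lengths)
    p = RankSelectBits(int(ends[-1]) if ell else 0)
    if ell:
        p.set_bits(ends - 1)
    p.freeze()

    logger.info(
        "indexed %d genes: %d distinct BF bits, |I|=%d, load factor %.3g",
        len(panel), ell, len(ids), ell / m,
    )
    return PanelIndex(bf=bf, p=p, ids=ids, k=k, m=m, seed=seed, gene_names=panel.names)


def build_exact_oracle(panel: GenePanel, k: int) -> Dict[int, List[int]]:
    """Exact dictionary canonical-kmer-value -> sorted gene IDs (test scale)."""
    oracle: Dict[int, set] = {}
    for gid, (_, seq) in enumerate(panel.records):
        stream = extract_kmers(seq, None, k=k, q=0)
        for v in np.unique(stream.values):
            oracle.setdefault(int(v), set()).add(gid)
    return {v: sorted(g) for v, g in oracle.items()}


# ---------------------------------------------------------------------------
# persistence: magic, version, params, name table, the three vectors
# ---------------------------------------------------------------------------

_MAGIC = b"RSVI"
_VERSION = 1
_HEADER = struct.Struct("<4sHHqqqqqq")  # magic, version, k, m, seed, n_genes, |I|, BF words, P bits


def save_index(index: PanelIndex, path) -> None:
    names_blob = b"\n".join(n.encode("utf-8") for n in index.gene_names)
    with open(path, "wb") as fh:
        fh.write(
            _HEADER.pack(
                _MAGIC, _VERSION, index.k, index.m, index.seed,
                len(index.gene_names), len(index.ids),
                len(index.bf.words), index.p.nbits,
            )
        )
        fh.write(struct.pack("<q", len(names_blob)))
        fh.write(names_blob)
        fh.write(index.bf.words.tobytes())
        fh.write(index.p.words.tobytes())
        fh.write(np.ascontiguousarray(index.ids, dtype=np.int32).tobytes())


def _read_exact(fh, n: int) -> bytes:
    buf = fh.read(n)
    if len(buf) != n:
        raise IndexFormatError("truncated index file")
    return buf


def load_index(path, expect_k: int | None = None) -> PanelIndex:
    """Load an index; ``expect_k`` (when given) must match the stored k."""
    with open(path, "rb") as fh:
        try:
            magic, version, k, m, seed, n_genes, n_ids, bf_words, p_bits = _HEADER.unpack(
                _read_exact(fh, _HEADER.size)
            )
        except struct.error as exc:
            raise IndexFormatError(str(exc)) from exc
        if magic != _MAGIC:
            raise IndexFormatError("not an index file (bad magic)")
        if version != _VERSION:
            raise IndexFormatError(f"unsupported index version {version}")
        if expect_k is not None and k != expect_k:
            raise IndexFormatError(f"index built with k={k}, expected k={expect_k}")
        (names_len,) = struct.unpack("<q", _read_exact(fh, 8))
        names = _read_exact(fh, names_len).decode("utf-8").split("\n") if names_len else []
        if len(names) != n_genes:
            raise IndexFormatError("gene-name table does not match header")
        bf = RankSelectBits.from_words(
            np.frombuffer(_read_exact(fh, 8 * bf_words), dtype=np.uint64).copy(), m
        )
        p_words = (p_bits + 63) // 64
        p = RankSelectBits.from_words(
            np.frombuffer(_read_exact(fh, 8 * p_words), dtype=np.uint64).copy(), p_bits
        )
        ids = np.frombuffer(_read_exact(fh, 4 * n_ids), dtype=np.int32).copy()
        if fh.read(1):
            raise IndexFormatError("trailing bytes after index payload")
    return PanelIndex(bf=bf.freeze(), p=p.freeze(), ids=ids, k=k, m=m, seed=seed, gene_names=names)
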