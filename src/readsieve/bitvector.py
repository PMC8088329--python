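"""Bit vector with rank/select support on numpy uint64 words.

Conventions (all 0-based):

* ``rank1(i)`` — number of set bits at positions strictly before ``i``
  (i.e. in the prefix ``[0, i)``); defined for ``0 <= i <= len``.
* ``select1(j)`` — 0-based position of the j-th set bit, ``j`` counted
  from 1; defined for ``1 <= j <= ones_count``.

These satisfy ``select1(rank1(p) + 1) == p`` for every set-bit position
``p``.  Rank uses a per-word cumulative popcount table (O(1) per query);
select binary-searches that table and scans one word.
"""

from __future__ import annotations

import numpy as np

__all__ = ["RankSelectBits"]

_U64 = np.uint64
_ONE = _U64(1)


class RankSelectBits:
    """Fixed-length mutable bit sequence; rank/select after :meth:`freeze`."""

    def __init__(self, nbits: int):
        if nbits < 0:
            raise ValueError("nbits must be >= 0")
        self.nbits = int(nbits)
        self._words = np.zeros((self.nbits + 63) // 64, dtype=_U64)
        self._cum: np.ndarray | None = None  # ones strictly before each word

    # -- construction ------------------------------------------------------

    def set_bits(self, positions: np.ndarray) -> None:
        """Set bits at the given positions (duplicates allowed)."""
        pos = np.asarray(positions, dtype=np.int64)
        if len(pos) == 0:
            return
        if pos.min() < 0 or pos.max() >= self.nbits:
            raise IndexError("bit position out of range")
        np.bitwise_or.at(
            self._words, pos >> 6, _ONE << (pos.astype(_U64) & _U64(63))
        )
        self._cum = None

    def freeze(self) -> "RankSelectBits":
        """Build the rank acceleration table; call after the last mutation."""
        counts = np.bitwise_count(self._words).astype(np.int64)
        self._cum = np.concatenate([[0], np.cumsum(counts)])
        return self

    # -- queries -----------------------------------------------------------

    @property
    def ones_count(self) -> int:
        if self._cum is None:
            self.freeze()
        return int(self._cum[-1])

    def __len__(self) -> int:
        return self.nbits

    def __getitem__(self, i: int) -> int:
        if not 0 <= i < self.nbits:
            raise IndexError(i)
        return int((self._words[i >> 6] >> _U64(i & 63)) & _ONE)

    def get_many(self, positions: np.ndarray) -> np.ndarray:
        """Vectorised bit test; returns a bool array."""
        pos = np.asarray(positions, dtype=np.int64)
        return (
            (self._words[pos >> 6] >> (pos.astype(_U64) & _U64(63))) & _ONE
        ).astype(bool)

    def rank1(self, i: int) -> int:
        """Number of 1s in the prefix [0, i)."""
        if self._cum is None:
            self.freeze()
        if not 0 <= i <= self.nbits:
            raise IndexError(i)
        w, b = i >> 6, i & 63
        r = int(self._cum[w])
        if b:
            r += int(np.bitwise_count(self._words[w] << _U64(64 - b)))
        return r

    def rank1_many(self, positions: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`rank1` over an array of prefix bounds."""
        if self._cum is None:
            self.freeze()
        pos = np.asarray(positions, dtype=np.int64)
        w = pos >> 6
        b = pos.astype(_U64) & _U64(63)
        part = np.zeros(len(pos), dtype=np.int64)
        inb = b > 0  # w < len(words) wherever a partial word contributes
        if inb.any():
            part[inb] = np.bitwise_count(
                self._words[w[inb]] << (_U64(64) - b[inb])
            ).astype(np.int64)
        return self._cum[w] + part

    def select1(self, j: int) -> int:
        """0-based position of the j-th set bit (j >= 1)."""
        if self._cum is None:
            self.freeze()
        if not 1 <= j <= self.ones_count:
            raise IndexError(f"select1({j}) undefined: {self.ones_count} ones")
        w = int(np.searchsorted(self._cum, j, side="left")) - 1
        word = int(self._words[w])
        n = j - int(self._cum[w])  # n-th set bit within this word
        for _ in range(n - 1):
            word &= word - 1
        return (w << 6) + ((word & -word).bit_length() - 1)

    # -- persistence helpers ------------------------------------------------

    @property
    def words(self) -> np.ndarray:
        return self._words

    @classmethod
    def from_words(cls, words: np.ndarray, nbits: int) -> "RankSelectBits":
        bv = cls.__new__(cls)
        bv.nbits = int(nbits)
        bv._words = np.ascontiguousarray(words, dtype=_U64)
        if len(bv._words) != (bv.nbits + 63) // 64:
            raise ValueError("word count does not match nbits")
        bv._cum = None
        return bv
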