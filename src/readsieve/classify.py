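"""Assign reads to panel genes by shared-base counting.

For a read s and gene g, a base of s is *shared* with g when some k-mer
of s containing that base also occurs in g (on either strand).  The
shared-base count |SHARED(s, g)| is accumulated in a single left-to-right
scan of the read's k-mers: for each gene g returned by the index at
window start i (0-based), the new bases contributed are
``min(k, i + k - pos_g)`` where ``pos_g`` is the exclusive end of the
last window of g seen so far (sentinel -1 before any hit, which makes the
first contribution exactly k); ``pos_g`` is then set to ``i + k``.

A gene g is a putative origin of s when |SHARED(s, g)| / |s| >= tau and
no other gene has a strictly larger shared count.  In *multiple* mode all
tied maximal genes are reported; in *single* mode a read with more than
one candidate is reported with none.
"""

from __future__ import annotations

import multiprocessing
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .index import PanelIndex
from .io import FastqRead, read_fastq
from .kmers import KmerStream, extract_kmers

__all__ = ["ReadAssignment", "assign", "classify_reads", "classify_sample", "shared_counts"]


@dataclass
class ReadAssignment:
    """Per-read result: the genes meeting the assignment criterion."""

    read_id: str
    read_length: int
    assigned: List[Tuple[int, int]]  # (gene_id, shared_bases), gene_id ascending
    mode: str  # "multiple" | "single"

    @property
    def gene_ids(self) -> List[int]:
        return [g for g, _ in self.assigned]


def shared_counts(stream: KmerStream, index: PanelIndex) -> Dict[int, int]:
    """|SHARED(read, g)| for every gene g hit by the read's k-mers.

    Genes never hit are absent.  Counts equal the cardinality of the
    union of read bases covered by matching windows.
    """
    if stream.k != index.k:
        raise ValueError(f"stream k={stream.k} does not match index k={index.k}")
    card: Dict[int, int] = {}
    pos: Dict[int, int] = {}
    k = index.k
    if len(stream) == 0:
        return card
    gene_lists = index.query_many(stream.values)
    for i, genes in zip(stream.starts, gene_lists):
        if len(genes) == 0:
            continue
        i = int(i)
        end = i + k
        for g in genes:
            g = int(g)
            p = pos.get(g, -1)
            card[g] = card.get(g, 0) + min(k, end - p)
            pos[g] = end
    return card


def assign(
    cards: Dict[int, int],
    read_length: int,
    tau: float,
    mode: str = "multiple",
    read_id: str = "",
) -> ReadAssignment:
    """Apply the assignment criterion to a read's shared-base counts.

    Candidates are the genes with the maximal count c* provided
    c*/read_length >= tau; the denominator is the full read length even
    when quality masking removed windows.  Single mode drops reads with
    more than one candidate.
    """
    if not 0 < tau <= 1:
        raise ValueError("tau must be in (0, 1]")
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    if mode not in ("multiple", "single"):
        raise ValueError(f"unknown mode {mode!r}")
    candidates: List[Tuple[int, int]] = []
    if cards:
        c_star = max(cards.values())
        if c_star / read_length >= tau:
            candidates = sorted((g, c) for g, c in cards.items() if c == c_star)
    if mode == "single" and len(candidates) > 1:
        candidates = []
    return ReadAssignment(read_id, read_length, candidates, mode)


def _classify_one(
    read: FastqRead, index: PanelIndex, tau: float, q: int, mode: str
) -> ReadAssignment:
    stream = extract_kmers(
        read.sequence, read.quality if q > 0 else None, k=index.k, q=q, read_id=read.name
    )
    cards = shared_counts(stream, index)
    return assign(cards, max(len(read.sequence), 1), tau, mode, read_id=read.name)


# worker state for fork-based pools
_WORKER: dict = {}


def _init_worker(index, tau, q, mode):  # pragma: no cover - exercised via pool
    _WORKER.update(index=index, tau=tau, q=q, mode=mode)


def _work_batch(batch):  # pragma: no cover - exercised via pool
    w = _WORKER
    return [_classify_one(r, w["index"], w["tau"], w["q"], w["mode"]) for r in batch]


def classify_reads(
    reads: Iterable[FastqRead],
    index: PanelIndex,
    tau: float = 0.6,
    q: int = 10,
    mode: str = "multiple",
    threads: int = 1,
    batch_size: int = 2000,
) -> List[ReadAssignment]:
    """Classify an iterable of reads; deterministic for any thread count.

    With ``threads > 1`` batches are dispatched to forked workers and the
    results concatenated in submission order, so the output is identical
    to the sequential run.
    """
    if threads <= 1:
        return [_classify_one(r, index, tau, q, mode) for r in reads]
    reads = list(reads)
    batches = [reads[i : i + batch_size] for i in range(0, len(reads), batch_size)]
    ctx = multiprocessing.get_context("fork")
    with ctx.Pool(threads, initializer=_init_worker, initargs=(index, tau, q, mode)) as pool:
        out: List[ReadAssignment] = []
        for chunk in pool.map(_work_batch, batches):
            out.extend(chunk)
    return out


@dataclass
class SampleResult:
    """Classification of a whole sample plus the per-gene read grouping."""

    assignments: List[ReadAssignment]
    gene_names: List[str]
    paired: bool
    n_mate1: int = 0  # assignments[:n_mate1] are mate-1 reads when paired

    def assignment_rows(self) -> List[Tuple[str, str, int, int, str]]:
        """Sorted (read_id, gene_name, shared_bases, read_length, ratio) rows."""
        rows = []
        for a in self.assignments:
            for g, c in a.assigned:
                rows.append(
                    (a.read_id, self.gene_names[g], c, a.read_length,
                     f"{c / a.read_length:.4f}")
                )
        rows.sort(key=lambda r: (r[0], r[1]))
        return rows

    def per_gene_read_ids(self) -> Dict[str, List[str]]:
        """The gene assignment: gene name -> reads assigned to it."""
        groups: Dict[str, List[str]] = {name: [] for name in self.gene_names}
        for a in self.assignments:
            for g in a.gene_ids:
                groups[self.gene_names[g]].append(a.read_id)
        return groups

    def assigned_read_ids(self) -> set:
        return {a.read_id for a in self.assignments if a.assigned}


def classify_sample(
    fastq1,
    index: PanelIndex,
    fastq2=None,
    tau: float = 0.6,
    q: int = 10,
    mode: str = "multiple",
    threads: int = 1,
    pairing_policy: str = "union",
    strict: bool = False,
) -> SampleResult:
    """Classify a FASTQ sample (single-end, or a mate pair of files).

    Mates are classified independently.  ``pairing_policy`` only affects
    which reads downstream output retains: "union" keeps both mates when
    either is assigned, "separate" treats mates as independent reads.
    """
    if pairing_policy not in ("union", "separate"):
        raise ValueError(f"unknown pairing policy {pairing_policy!r}")
    assignments = classify_reads(read_fastq(fastq1, strict=strict), index, tau, q, mode, threads)
    n1 = len(assignments)
    if fastq2 is not None:
        assignments += classify_reads(read_fastq(fastq2, strict=strict), index, tau, q, mode, threads)
    return SampleResult(assignments, index.gene_names, paired=fastq2 is not None, n_mate1=n1)
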