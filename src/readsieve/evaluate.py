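"""Precision/recall scoring of read assignments against simulated truth.

Per read, with its single true origin gene known:

* an assignment to the origin gene (when the origin is in the panel)
  counts one true positive;
* every assignment to a panel gene that is not the origin counts one
  false positive — this covers both a misassigned panel-origin read and
  a captured read whose origin lies outside the panel;
* a panel-origin read with no assignment to its origin counts one false
  negative (at most one per read).

A read assigned to both its origin and another gene therefore yields a
true positive *and* a false positive; a read assigned only to wrong
genes yields a false positive *and* a false negative.

precision = tp / (tp + fp) (undefined -> None), recall = tp / (tp + fn).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Set

from .classify import ReadAssignment
from .simulate import SimTruth

__all__ = ["EvalReport", "evaluate", "evaluate_table"]


class EvalDataError(ValueError):
    """Assignment refers to a read absent from the truth table."""


@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> Optional[float]:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def recall(self) -> Optional[float]:
        d = self.tp + self.fn
        return self.tp / d if d else None

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
        }


def _score(
    assigned_by_read: Dict[str, Set[str]], truth: SimTruth, panel: Set[str]
) -> EvalReport:
    tp = fp = fn = 0
    for rid in assigned_by_read:
        if rid not in truth.origin:
            raise EvalDataError(f"assignment references unknown read {rid!r}")
    for rid, origin in truth.origin.items():
        assigned = assigned_by_read.get(rid, set())
        bad = assigned - {origin}
        fp += len(bad)
        if origin in panel:
            if origin in assigned:
                tp += 1
            else:
                fn += 1
    return EvalReport(tp, fp, fn)


def evaluate(
    assignments: Iterable[ReadAssignment],
    truth: SimTruth,
    panel: Iterable[str],
    gene_names: Optional[List[str]] = None,
) -> EvalReport:
    """Score ReadAssignment objects (gene IDs resolved via ``gene_names``)."""
    panel = set(panel)
    by_read: Dict[str, Set[str]] = {}
    for a in assignments:
        names = {gene_names[g] for g in a.gene_ids} if gene_names else set(a.gene_ids)
        if names - panel:
            raise EvalDataError(
                f"read {a.read_id!r} assigned to genes outside the panel: {sorted(names - panel)}"
            )
        if names:
            by_read.setdefault(a.read_id, set()).update(names)
    return _score(by_read, truth, panel)


def evaluate_table(
    rows: List[List[str]], truth: SimTruth, panel: Iterable[str]
) -> EvalReport:
    """Score an assignment TSV (read_id, gene_name, ...) against truth."""
    by_read: Dict[str, Set[str]] = {}
    for row in rows:
        by_read.setdefault(row[0], set()).add(row[1])
    return _score(by_read, truth, set(panel))
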