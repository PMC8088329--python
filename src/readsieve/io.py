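"""FASTA/FASTQ readers and TSV/JSON writers.

Sequence parsing is delegated to pysam's FastxFile, which is transparent
to gzip compression.  FASTA record names are truncated at the first
whitespace.  FASTQ qualities are Phred+33.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, List, Optional, Tuple

import pysam

__all__ = ["FastqRead", "read_fasta", "read_fastq", "write_fastq", "open_text"]


class InputFormatError(ValueError):
    """Malformed or empty input file."""


@dataclass
class FastqRead:
    name: str
    sequence: str
    quality: Optional[str]  # Phred+33 string, None for FASTA input

    def to_fastq(self) -> str:
        qual = self.quality if self.quality is not None else "I" * len(self.sequence)
        return f"@{self.name}\n{self.sequence}\n+\n{qual}\n"


def read_fasta(path) -> Iterator[Tuple[str, str]]:
    """Yield (name, sequence) from a (possibly gzipped) FASTA file."""
    n = 0
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            n += 1
            yield rec.name, rec.sequence
    if n == 0:
        raise InputFormatError(f"no records in FASTA file {path}")


def read_fastq(path, strict: bool = False) -> Iterator[FastqRead]:
    """Yield reads from a (possibly gzipped) FASTQ file.

    Records whose quality string length mismatches the sequence are
    skipped with a warning, or abort when ``strict``.
    """
    import logging

    log = logging.getLogger(__name__)
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            qual = rec.quality
            if qual is not None and len(qual) != len(rec.sequence):
                msg = f"read {rec.name!r}: quality/sequence length mismatch"
                if strict:
                    raise InputFormatError(msg)
                log.warning("%s; skipped", msg)
                continue
            yield FastqRead(rec.name, rec.sequence, qual)


def open_text(path, mode: str = "rt"):
    """Open a path for text I/O, gzip-transparent by extension."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def write_fastq(reads: List[FastqRead], path) -> None:
    with open_text(path, "wt") as fh:
        for r in reads:
            fh.write(r.to_fastq())


def write_tsv(rows: List[tuple], header: Tuple[str, ...], path) -> None:
    with open_text(path, "wt") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")


def read_tsv(path) -> Tuple[List[str], List[List[str]]]:
    with open_text(path, "rt") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise InputFormatError(f"empty TSV file {path}")
    header = lines[0].split("\t")
    return header, [ln.split("\t") for ln in lines[1:]]


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
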