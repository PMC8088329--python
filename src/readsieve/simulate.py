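"""Synthetic gene loci, transcripts and error-bearing RNA-Seq reads.

The generator emulates the structure the classifier is built for:

* a set of gene loci, each an i.i.d. random DNA sequence partitioned into
  exons separated by introns (optionally with a segment planted in two
  loci to emulate paralogy);
* one transcript per gene, the concatenation of its exons — so introns
  are spliced out and reads can span exon junctions;
* single-end (default 100 bp) reads drawn from transcripts of both panel
  and non-panel genes, from either strand, with i.i.d. substitution
  errors and Phred-style quality strings that include occasional
  low-quality dips.

The ground-truth origin gene of every read is recorded separately from
the FASTQ; read names carry no information about the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .index import GenePanel

__all__ = ["SimConfig", "SimTruth", "Simulation", "simulate", "simulate_panel", "simulate_reads"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {65: 84, 67: 71, 71: 67, 84: 65}


class ConfigError(ValueError):
    """Infeasible simulation configuration."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic sample.

    Defaults reproduce a desk-scale version of the benchmark setting:
    50 gene loci of roughly 2 kb with 2-5 exons each, a 10-gene panel,
    50,000 single-end 100 bp reads with 0.2% substitution errors and
    Phred-style qualities.
    """

    n_genes: int = 50
    panel_size: int = 10
    exons_per_gene: Tuple[int, int] = (2, 5)
    exon_length_range: Tuple[int, int] = (150, 600)
    intron_length_range: Tuple[int, int] = (50, 200)
    n_reads: int = 50_000
    read_length: int = 100
    substitution_error_rate: float = 0.002
    quality_mean: float = 36.0
    quality_sd: float = 3.0
    low_quality_rate: float = 0.01  # per-base chance of a quality dip below 10
    expression_sigma: float = 1.0  # log-normal spread of per-transcript weights
    shared_segment_length: int = 0  # plant a common segment in genes 0 and 1
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.panel_size <= self.n_genes:
            raise ConfigError("panel_size must be in 1..n_genes")
        lo, hi = self.exons_per_gene
        if lo < 1 or hi < lo:
            raise ConfigError("invalid exons_per_gene range")
        if self.exon_length_range[0] < self.read_length and lo == 1:
            # single-exon transcripts must still be longer than a read
            raise ConfigError("exon length below read length with a single exon")
        if self.exon_length_range[0] * lo < self.read_length:
            raise ConfigError("minimum transcript length below read length")
        for p in (self.substitution_error_rate, self.low_quality_rate):
            if not 0 <= p <= 1:
                raise ConfigError("probabilities must be in [0, 1]")
        if self.shared_segment_length and self.n_genes < 2:
            raise ConfigError("planted sharing needs at least two genes")


@dataclass
class Gene:
    name: str
    locus: str
    exons: List[Tuple[int, int]]  # 0-based half-open locus coordinates

    @property
    def transcript(self) -> str:
        return "".join(self.locus[a:b] for a, b in self.exons)


@dataclass
class SimTruth:
    """read_id -> origin gene name (exactly one origin per read)."""

    origin: Dict[str, str]
    junctions: Dict[str, int] = field(default_factory=dict)  # exon junctions spanned


@dataclass
class Simulation:
    genes: List[Gene]
    panel_names: List[str]
    reads: List[Tuple[str, str, str]]  # (read_id, sequence, quality Phred+33)
    truth: SimTruth
    config: SimConfig

    def full_panel(self) -> GenePanel:
        return GenePanel([(g.name, g.locus) for g in self.genes])

    def panel(self) -> GenePanel:
        by_name = {g.name: g for g in self.genes}
        return GenePanel([(n, by_name[n].locus) for n in self.panel_names])


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode("ascii")


def simulate_panel(config: SimConfig) -> Tuple[List[Gene], List[str]]:
    """Generate gene loci with exon/intron structure and pick the panel."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes: List[Gene] = []
    width = len(str(config.n_genes - 1))
    for i in range(config.n_genes):
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(*config.exon_length_range, size=n_exons, endpoint=True)
        if config.shared_segment_length and i < 2:
            # the planted segment goes into the first exon, which must fit it
            exon_lens[0] = max(int(exon_lens[0]), config.shared_segment_length)
        intron_lens = rng.integers(*config.intron_length_range, size=n_exons - 1, endpoint=True)
        exons: List[Tuple[int, int]] = []
        pos = 0
        for j, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if j < n_exons - 1:
                pos += int(intron_lens[j])
        genes.append(Gene(f"gene_{i:0{width}d}", _random_dna(rng, pos), exons))

    if config.shared_segment_length:
        seg = _random_dna(rng, config.shared_segment_length)
        for g in genes[:2]:
            a, b = g.exons[0]
            if b - a < config.shared_segment_length:
                raise ConfigError("shared segment longer than first exon")
            g.locus = g.locus[:a] + seg + g.locus[a + len(seg):]

    panel_idx = rng.choice(config.n_genes, size=config.panel_size, replace=False)
    panel_names = [genes[i].name for i in sorted(panel_idx)]
    return genes, panel_names


def _revcomp_bytes(arr: np.ndarray) -> np.ndarray:
    out = arr[::-1].copy()
    for a, b in ((65, 84), (67, 71)):
        ia, ib = out == a, out == b
        out[ia], out[ib] = b, a
    return out


def simulate_reads(
    genes: List[Gene], config: SimConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[List[Tuple[str, str, str]], SimTruth]:
    """Sample reads from transcripts with substitution errors and qualities.

    Transcript abundances are log-normal; start positions are uniform on
    the transcript; strand is uniform.  Error positions are independent
    of the simulated quality dips.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n, L = config.n_reads, config.read_length
    transcripts = [np.frombuffer(g.transcript.encode(), dtype=np.uint8) for g in genes]
    # cumulative exon lengths give junction positions in transcript coordinates
    junction_pos = [np.cumsum([b - a for a, b in g.exons])[:-1] for g in genes]

    weights = rng.lognormal(0.0, config.expression_sigma, len(genes))
    weights /= weights.sum()
    gene_choice = rng.choice(len(genes), size=n, p=weights)
    # all randomness is drawn upfront so the stream consumed does not depend
    # on outcomes (e.g. the same seed with error rate 0 yields the same
    # fragments, differing only in the substituted bases)
    t_room = np.array([len(t) - L + 1 for t in transcripts])
    starts = np.floor(rng.random(n) * t_room[gene_choice]).astype(np.int64)
    flip = rng.random(n) < 0.5
    err_mask = rng.random((n, L)) < config.substitution_error_rate
    err_offsets = rng.integers(1, 4, size=(n, L), dtype=np.int64)
    quals = np.clip(
        np.rint(rng.normal(config.quality_mean, config.quality_sd, (n, L))), 2, 40
    ).astype(np.int64)
    dips = rng.random((n, L)) < config.low_quality_rate
    quals[dips] = rng.integers(2, 10, size=(n, L), dtype=np.int64)[dips]
    qual_bytes = (quals + 33).astype(np.uint8)

    reads: List[Tuple[str, str, str]] = []
    origin: Dict[str, str] = {}
    junctions: Dict[str, int] = {}
    width = len(str(n - 1))
    for r in range(n):
        gi = int(gene_choice[r])
        start = int(starts[r])
        seq = transcripts[gi][start : start + L].copy()
        if flip[r]:
            seq = _revcomp_bytes(seq)
        err = np.nonzero(err_mask[r])[0]
        if len(err):  # substitute with one of the three other bases
            codes = np.searchsorted(_BASES, seq[err])
            seq[err] = _BASES[(codes + err_offsets[r, err]) % 4]
        rid = f"read_{r:0{width}d}"
        reads.append((rid, seq.tobytes().decode("ascii"), qual_bytes[r].tobytes().decode("ascii")))
        origin[rid] = genes[gi].name
        junctions[rid] = int(
            np.count_nonzero((junction_pos[gi] > start) & (junction_pos[gi] < start + L))
        )
    return reads, SimTruth(origin, junctions)


def simulate(config: SimConfig) -> Simulation:
    """Full bundle: loci + panel + reads + truth, deterministic under seed."""
    genes, panel_names = simulate_panel(config)
    reads, truth = simulate_reads(genes, config)
    return Simulation(genes, panel_names, reads, truth, config)


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_simulation(sim: Simulation, outdir) -> Dict[str, Path]:
    """Write panel/genes FASTA, reads FASTQ, truth TSV and a config echo."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "panel_fasta": outdir / "panel.fasta",
        "genes_fasta": outdir / "genes.fasta",
        "reads_fastq": outdir / "reads.fastq",
        "truth_tsv": outdir / "truth.tsv",
        "config_yaml": outdir / "config.yaml",
    }
    by_name = {g.name: g for g in sim.genes}
    with open(paths["panel_fasta"], "w") as fh:
        for n in sim.panel_names:
            fh.write(f">{n}\n{by_name[n].locus}\n")
    with open(paths["genes_fasta"], "w") as fh:
        for g in sim.genes:
            fh.write(f">{g.name}\n{g.locus}\n")
    with open(paths["reads_fastq"], "w") as fh:
        for rid, seq, qual in sim.reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    with open(paths["truth_tsv"], "w") as fh:
        fh.write("read_id\torigin_gene\tn_junctions\n")
        for rid, _, _ in sim.reads:
            fh.write(f"{rid}\t{sim.truth.origin[rid]}\t{sim.truth.junctions[rid]}\n")
    with open(paths["config_yaml"], "w") as fh:
        cfg = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(sim.config).items()}
        yaml.safe_dump(cfg | {"panel": sim.panel_names}, fh)
    return paths
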