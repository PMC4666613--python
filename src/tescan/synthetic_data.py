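"""Synthetic toy world — genome, repeats, reads, peaks — with known truth.

The generator emulates the data underlying a repeat-element
regulatory study: a consensus library with one class carrying a
tandem array of Myb-like sites at its 5' end; genomic copies of each
class with per-copy divergence separated by random flank sequence;
ChIP read sets drawn with a per-class enrichment factor over a
matched uniform Input; RNA read sets from gene/element transcripts
with a genotype-dependent fold change on the motif-bearing class;
and peak calls marking a stated fraction of motif-bearing instances
plus gene promoters.  Every stochastic step derives its own RNG
stream from one master seed, so identical (config, seed) gives
byte-identical outputs.

Sampling model: a read belongs to the segment containing its start
base, and weights are defined over valid start positions — Input
reads start uniformly, ChIP starts are weighted by the class
enrichment factor inside instances (weight 1 elsewhere), so the
expected ChIP read fraction in class c is e_c * S_c / sum(weights)
with S_c the class's valid-start count.  RNA reads start uniformly
inside transcript units (instances and gene spans) weighted by the
genotype multiplier.  Reads are single-end and error-free; per-copy
divergence already stresses the mapping logic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .consensus_quant import ConsensusLibrary, revcomp
from .io_formats import (
    AlignmentRecord,
    GeneModel,
    GenomicInterval,
    write_fasta,
)
from .motif_tandem import IUPAC, scan_consensus

CHROM = "chrT"
_STREAM = {"library": 1, "genome": 2, "chip": 3, "input": 4, "rna": 5, "peaks": 6}


class ConfigurationError(ValueError):
    pass


def _default_enrichment() -> dict:
    return {"LTR01": 7.0}


def _default_rna_fold() -> dict:
    return {("LTR01", "het"): 1.33}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic world.

    ``chip_enrichment`` maps class id -> enrichment factor e (>= 0;
    unlisted classes get 1).  ``rna_fold`` maps (class id, genotype)
    -> expression multiplier (unlisted pairs get 1); by default only
    the motif-bearing class responds to the het genotype, mirroring a
    dosage effect confined to elements with the binding sites.
    """

    n_classes: int = 6
    class_length_range: tuple = (400, 800)
    motif_class_id: str = "LTR01"
    motif: str = "AACTGYCW"  # Myb consensus AACTG(C/T)C(A/T)
    n_tandem_sites: int = 4
    instances_per_class: int = 10
    per_copy_divergence: float = 0.02
    flank_length: int = 20_000
    n_genes: int = 8
    chip_enrichment: dict = field(default_factory=_default_enrichment)
    rna_fold: dict = field(default_factory=_default_rna_fold)
    read_length: int = 50
    depth: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ConfigurationError("depth must be > 0")
        if self.read_length > self.class_length_range[0]:
            raise ConfigurationError("read_length exceeds minimum class length")
        if self.flank_length < 0:
            raise ConfigurationError("flank_length must be >= 0")
        if any(e < 0 for e in self.chip_enrichment.values()):
            raise ConfigurationError("enrichment factors must be >= 0")
        if any(f < 0 for f in self.rna_fold.values()):
            raise ConfigurationError("rna fold multipliers must be >= 0")
        bad = set(self.motif.upper()) - set(IUPAC)
        if bad:
            raise ConfigurationError(f"invalid motif codes {sorted(bad)}")
        if self.n_tandem_sites > 0:
            room = self.class_length_range[0] // 4
            if len(self.motif) * self.n_tandem_sites > room:
                raise ConfigurationError(
                    "motif array wider than the 5' quarter of the shortest class"
                )

    @property
    def class_ids(self) -> list:
        return [f"LTR{i + 1:02d}" for i in range(self.n_classes)]

    def enrichment_of(self, class_id: str) -> float:
        return self.chip_enrichment.get(class_id, 1.0)

    def rna_fold_of(self, class_id: str, genotype: str) -> float:
        return self.rna_fold.get((class_id, genotype), 1.0)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "class_length_range" in raw:
            raw["class_length_range"] = tuple(raw["class_length_range"])
        if "rna_fold" in raw:
            raw["rna_fold"] = {
                (k.split(":")[0], k.split(":")[1]): v
                for k, v in raw["rna_fold"].items()
            }
        return cls(**raw)


@dataclass
class TruthTable:
    """Ground truth of the generated world; every class appears once."""

    class_enrichment: dict  # class id -> true ChIP enrichment factor
    planted_sites: dict  # class id -> list of (offset, strand)
    chance_sites: dict  # class id -> list of (offset, strand) not planted
    rna_fold: dict  # (class id, genotype) -> multiplier
    motif_class_id: str = ""
    motif: str = ""

    def __post_init__(self) -> None:
        for d in (self.planted_sites, self.chance_sites):
            if set(d) != set(self.class_enrichment):
                raise ValueError("every library class must appear exactly once")

    def to_json(self, path) -> None:
        payload = {
            "class_enrichment": self.class_enrichment,
            "planted_sites": self.planted_sites,
            "chance_sites": self.chance_sites,
            "rna_fold": {f"{c}:{g}": v for (c, g), v in self.rna_fold.items()},
            "motif_class_id": self.motif_class_id,
            "motif": self.motif,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class SimRead:
    """A simulated read with its true origin."""

    read_id: str
    sequence: str
    start: int  # genomic (or transcript-unit) start, forward strand
    strand: str
    origin: str  # class id, gene id, or "flank"

    def to_alignment(self, mapq: int = 42) -> AlignmentRecord:
        return AlignmentRecord(
            read_id=self.read_id,
            ref=CHROM,
            start=self.start,
            length=len(self.sequence),
            strand=self.strand,
            mapq=mapq,
        )


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAM[stream]])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _realize_motif(rng: np.random.Generator, motif: str) -> str:
    return "".join(
        IUPAC[c][rng.integers(0, len(IUPAC[c]))] for c in motif.upper()
    )


def make_consensus_library(config: SimulationConfig):
    """Random consensus per class; the designated class carries
    ``n_tandem_sites`` same-strand motif copies, non-overlapping, in
    its 5' quarter.

    Returns (library, planted_sites) where planted_sites maps each
    class to its list of (offset, strand); only the motif class has a
    non-empty list.  Chance background matches elsewhere are possible
    and are recorded separately in the TruthTable.
    """
    rng = _rng(config, "library")
    lo, hi = config.class_length_range
    w = len(config.motif)
    seqs: dict = {}
    planted: dict = {}
    for cid in config.class_ids:
        length = int(rng.integers(lo, hi + 1))
        seq = list(_random_seq(rng, length))
        sites = []
        if cid == config.motif_class_id and config.n_tandem_sites > 0:
            n = config.n_tandem_sites
            region = length // 4
            if n * w > region:
                raise ConfigurationError(
                    f"motif array does not fit the 5' quarter of {cid}"
                )
            # a tandem array: short spacers (0-12 bp) between sites, so
            # successive start-to-start gaps stay small, as in a real
            # tandem binding-site array
            max_spacer = min(12, max(0, (region - n * w) // max(n - 1, 1)))
            spacers = (
                rng.integers(0, max_spacer + 1, size=n - 1) if n > 1 else []
            )
            array_len = n * w + int(np.sum(spacers))
            lead = int(rng.integers(0, region - array_len + 1))
            start = lead
            for i in range(n):
                seq[start : start + w] = _realize_motif(rng, config.motif)
                sites.append((start, "+"))
                if i < n - 1:
                    start += w + int(spacers[i])
        seqs[cid] = "".join(seq)
        planted[cid] = sites
    return ConsensusLibrary(seqs), planted


def _chance_sites(library: ConsensusLibrary, motif: str, planted: dict) -> dict:
    chance = {}
    for cid, seq in library.sequences.items():
        known = set(planted.get(cid, []))
        hits = scan_consensus(seq, motif, seq_id=cid)
        chance[cid] = [
            (h.offset, h.strand) for h in hits if (h.offset, h.strand) not in known
        ]
    return chance


def make_genome(config: SimulationConfig, library: ConsensusLibrary):
    """Lay out diverged instance copies separated by random flanks.

    Each class gets ``instances_per_class`` copies (forward strand),
    each base substituted independently at ``per_copy_divergence``;
    copies are shuffled and separated by ``flank_length`` of random
    sequence (one flank before each instance and one after the last,
    so instance lengths plus flanks tile the genome exactly).  Genes
    are placed inside flanks, except the first, whose TSS sits inside
    a motif-bearing instance and reads through into the flank.
    """
    rng = _rng(config, "genome")
    order = [
        (cid, k)
        for cid in config.class_ids
        for k in range(config.instances_per_class)
    ]
    rng.shuffle(order)
    parts = []
    rows = []
    pos = 0
    flank_spans = []
    for cid, k in order:
        flank_spans.append((pos, pos + config.flank_length))
        parts.append(_random_seq(rng, config.flank_length))
        pos += config.flank_length
        seq = library.sequences[cid]
        copy = np.array(list(seq))
        mut = rng.random(len(seq)) < config.per_copy_divergence
        if mut.any():
            shifts = rng.integers(1, 4, size=int(mut.sum()))
            alphabet = "ACGT"
            idx = np.flatnonzero(mut)
            for j, sh in zip(idx, shifts):
                copy[j] = alphabet[(alphabet.index(copy[j]) + sh) % 4]
        parts.append("".join(copy))
        rows.append(
            {
                "chrom": CHROM,
                "start": pos,
                "end": pos + len(seq),
                "strand": "+",
                "class_id": cid,
            }
        )
        pos += len(seq)
    flank_spans.append((pos, pos + config.flank_length))
    parts.append(_random_seq(rng, config.flank_length))
    pos += config.flank_length
    genome = "".join(parts)
    instances = pd.DataFrame(rows)

    genes = []
    motif_rows = instances[instances["class_id"] == config.motif_class_id]
    if config.n_genes > 0 and len(motif_rows):
        # gene 1: TSS inside a motif-bearing instance, transcribed into
        # the downstream flank (an element acting as alternative promoter)
        first = motif_rows.iloc[0]
        tss = int(first.start) + 10
        tes = min(tss + 3000, len(genome) - 1)
        genes.append(
            GeneModel(
                gene_id="gene01",
                chrom=CHROM,
                tss=tss,
                tes=tes,
                strand="+",
                exons=((tss, tss + 200), (tes - 200, tes)),
            )
        )
    margin = 2000
    usable = [
        (s, e) for s, e in flank_spans if e - s >= 2 * margin + 6000
    ]
    i = 0
    while len(genes) < config.n_genes and usable:
        s, e = usable[i % len(usable)]
        span_len = int(rng.integers(2000, 5001))
        lo = s + margin
        hi = e - margin - span_len
        if hi <= lo:
            i += 1
            continue
        start = int(rng.integers(lo, hi))
        strand = "+" if rng.random() < 0.5 else "-"
        tss, tes = (start, start + span_len) if strand == "+" else (
            start + span_len,
            start,
        )
        genes.append(
            GeneModel(
                gene_id=f"gene{len(genes) + 1:02d}",
                chrom=CHROM,
                tss=tss,
                tes=tes,
                strand=strand,
                exons=((start, start + 200), (start + span_len - 200, start + span_len)),
            )
        )
        i += 1
    return genome, instances, genes


def _sample_segments(
    rng: np.random.Generator,
    genome: str,
    segments: Sequence[tuple],
    weights: np.ndarray,
    origins: Sequence[str],
    depth: int,
    read_length: int,
    prefix: str,
) -> list:
    """Draw reads: pick a segment by weight * valid-start count, then a
    uniform start within it.  Segment starts are clipped so reads fit
    the genome."""
    max_start = len(genome) - read_length
    counts = np.array(
        [max(0, min(e, max_start + 1) - s) for s, e in segments], dtype=float
    )
    w = weights * counts
    if w.sum() <= 0:
        raise ValueError("no sequence available to sample reads from")
    probs = w / w.sum()
    choice = rng.choice(len(segments), size=depth, p=probs)
    offsets = rng.random(depth)
    strands = rng.random(depth) < 0.5
    reads = []
    for i in range(depth):
        s, e = segments[choice[i]]
        n_starts = int(min(e, max_start + 1) - s)
        start = s + int(offsets[i] * n_starts)
        seq = genome[start : start + read_length]
        strand = "+" if strands[i] else "-"
        if strand == "-":
            seq = revcomp(seq)
        reads.append(
            SimRead(
                read_id=f"{prefix}_{i:07d}",
                sequence=seq,
                start=start,
                strand=strand,
                origin=origins[choice[i]],
            )
        )
    return reads


def simulate_reads(
    config: SimulationConfig,
    library: ConsensusLibrary,
    genome: str,
    instances: pd.DataFrame,
    mode: str,
    genotype: str = "wt",
    genes: Optional[Sequence[GeneModel]] = None,
) -> list:
    """Draw exactly ``config.depth`` labelled reads in one mode.

    input: uniform starts over the genome.  chip: starts weighted by
    the class enrichment factor inside instances.  rna: starts
    uniform within transcript units (instances and gene spans),
    weighted by the genotype multiplier of the unit's class.
    """
    if mode not in {"chip", "input", "rna"}:
        raise ValueError(f"unknown mode {mode!r}")
    if genotype not in {"wt", "het"}:
        raise ValueError(f"unknown genotype {genotype!r}")
    if not genome:
        raise ValueError("empty genome")
    rng = _rng(config, mode)
    if mode == "rna":
        rng = np.random.default_rng(
            [config.seed, _STREAM["rna"], 0 if genotype == "wt" else 1]
        )
    rl = config.read_length

    if mode in {"chip", "input"}:
        segments, weights, origins = [], [], []
        pos = 0
        for row in instances.itertuples(index=False):
            if row.start > pos:
                segments.append((pos, row.start))
                weights.append(1.0)
                origins.append("flank")
            segments.append((row.start, row.end))
            weights.append(
                config.enrichment_of(row.class_id) if mode == "chip" else 1.0
            )
            origins.append(row.class_id)
            pos = row.end
        if pos < len(genome):
            segments.append((pos, len(genome)))
            weights.append(1.0)
            origins.append("flank")
    else:
        segments, weights, origins = [], [], []
        for row in instances.itertuples(index=False):
            if row.end - row.start < rl:
                continue
            segments.append((row.start, row.end - rl + 1))
            weights.append(config.rna_fold_of(row.class_id, genotype))
            origins.append(row.class_id)
        for g in genes or ():
            if g.span_end - g.span_start < rl:
                continue
            segments.append((g.span_start, g.span_end - rl + 1))
            weights.append(1.0)
            origins.append(g.gene_id)
    prefix = mode if mode != "rna" else f"rna_{genotype}"
    return _sample_segments(
        rng,
        genome,
        segments,
        np.asarray(weights, dtype=float),
        origins,
        config.depth,
        rl,
        prefix,
    )


def expected_read_fraction(
    config: SimulationConfig,
    genome_length: int,
    instances: pd.DataFrame,
    class_id: str,
    mode: str = "chip",
) -> float:
    """Closed-form expected fraction of reads starting in class
    instances under the stated sampling weights (the binomial oracle's
    mean)."""
    max_starts = genome_length - config.read_length + 1
    total = 0.0
    target = 0.0
    covered = 0
    for row in instances.itertuples(index=False):
        n = max(0, min(row.end, max_starts) - row.start)
        e = config.enrichment_of(row.class_id) if mode == "chip" else 1.0
        total += e * n
        covered += n
        if row.class_id == class_id:
            target += e * n
    total += max_starts - covered  # flank starts at weight 1
    return target / total


def emit_truth_peaks(
    config: SimulationConfig,
    instances: pd.DataFrame,
    genes: Sequence[GeneModel],
    fraction_bound: float,
    seed: int,
    peak_pad: int = 100,
    promoter_halfwidth: int = 200,
) -> list:
    """Mark a fraction of motif-bearing instances, plus gene
    promoters, as peaks (a stand-in for a peak caller's output).

    peak count = round(fraction_bound * eligible instances) + one
    promoter peak per gene.  Deterministic per seed; BED-expressible.
    """
    if not (0 <= fraction_bound <= 1):
        raise ValueError("fraction_bound must lie in [0, 1]")
    rng = np.random.default_rng([seed, _STREAM["peaks"]])
    eligible = instances[instances["class_id"] == config.motif_class_id]
    k = int(round(fraction_bound * len(eligible)))
    chosen = sorted(rng.choice(len(eligible), size=k, replace=False)) if k else []
    peaks = []
    for n, i in enumerate(chosen):
        row = eligible.iloc[int(i)]
        peaks.append(
            GenomicInterval(
                chrom=row.chrom,
                start=max(0, int(row.start) - peak_pad),
                end=int(row.end) + peak_pad,
                name=f"instance_peak_{n + 1}",
                score=100.0,
            )
        )
    for g in genes:
        peaks.append(
            GenomicInterval(
                chrom=g.chrom,
                start=max(0, g.tss - promoter_halfwidth),
                end=g.tss + promoter_halfwidth,
                name=f"promoter_peak_{g.gene_id}",
                score=50.0,
            )
        )
    return peaks


@dataclass
class World:
    """A fully generated synthetic dataset plus its ground truth."""

    config: SimulationConfig
    library: ConsensusLibrary
    truth: TruthTable
    genome: str
    instances: pd.DataFrame
    genes: list

    def reads(self, mode: str, genotype: str = "wt") -> list:
        return simulate_reads(
            self.config,
            self.library,
            self.genome,
            self.instances,
            mode,
            genotype=genotype,
            genes=self.genes,
        )

    def write(self, outdir) -> None:
        from pathlib import Path

        from .io_formats import write_gene_table, write_repeat_instances

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.library.to_fasta(outdir / "library.fa")
        write_fasta({CHROM: self.genome}, outdir / "genome.fa")
        write_repeat_instances(self.instances, outdir / "instances.tsv")
        write_gene_table(self.genes, outdir / "genes.tsv")
        self.truth.to_json(outdir / "truth.json")


def generate_world(config: Optional[SimulationConfig] = None) -> World:
    """Generate the complete toy world for a config (defaults match
    the study conditions the package is tested under)."""
    config = config or SimulationConfig()
    library, planted = make_consensus_library(config)
    chance = _chance_sites(library, config.motif, planted)
    genome, instances, genes = make_genome(config, library)
    truth = TruthTable(
        class_enrichment={cid: config.enrichment_of(cid) for cid in config.class_ids},
        planted_sites=planted,
        chance_sites=chance,
        rna_fold=dict(config.rna_fold),
        motif_class_id=config.motif_class_id,
        motif=config.motif,
    )
    return World(
        config=config,
        library=library,
        truth=truth,
        genome=genome,
        instances=instances,
        genes=genes,
    )
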