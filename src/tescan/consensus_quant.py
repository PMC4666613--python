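"""Quantification of read libraries against a repeat consensus library.

One FASTA entry per repeat class (RepBase style) serves as the mapping
reference; per-class read counts are converted to RPKM and a ChIP
library is compared to its matched Input as a fold change per class.
A class is reported as enriched when the tissue expresses it (Input
RPKM above a floor, default 10) and the fold change over Input meets a
threshold (default 1.25).

The aligner here is a deliberately simple surrogate for a short-read
mapper: exact k-mer seeding plus ungapped extension under a mismatch
budget, with a deterministic tie rule (ties across classes go to the
lexicographically smallest class id at mapq 0).  Multi-mapped reads
still count toward their assigned class for quantification; the MAPQ
uniqueness filter is applied only in genomic element profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AlignmentRecord, read_fasta, write_fasta

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ConsensusLibrary:
    """Ordered set of (class id, consensus sequence)."""

    sequences: dict

    def __post_init__(self) -> None:
        if len(self.sequences) == 0:
            raise ValueError("empty consensus library")
        for cid, seq in self.sequences.items():
            if len(seq) < 1:
                raise ValueError(f"class {cid!r} has empty sequence")

    @classmethod
    def from_fasta(cls, path) -> "ConsensusLibrary":
        return cls(read_fasta(path))

    def to_fasta(self, path) -> None:
        write_fasta(self.sequences, path)

    @property
    def class_ids(self) -> list:
        return list(self.sequences)

    @property
    def lengths(self) -> dict:
        return {cid: len(s) for cid, s in self.sequences.items()}

    def __contains__(self, cid: str) -> bool:
        return cid in self.sequences

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass
class CountTable:
    """Per-class aligned read counts plus total library size.

    ``library_size`` is the total number of reads in the input file,
    mapped or not — the denominator of RPKM.
    """

    counts: dict
    library_size: int

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative count")
        if sum(self.counts.values()) > self.library_size:
            raise ValueError("mapped counts exceed library size")


def _read_pairs(reads) -> Iterable:
    """Accept (id, seq) tuples or objects with read_id/sequence attrs."""
    for r in reads:
        if isinstance(r, tuple):
            yield r
        else:
            yield r.read_id, r.sequence


def align_to_consensus(
    reads,
    library: ConsensusLibrary,
    seed_k: int = 16,
    max_mismatches: int = 5,
) -> list:
    """Place each read at its best ungapped position in the library.

    Exact k-mer seeds (non-overlapping, so any read with fewer
    mismatches than seeds has at least one exact seed) propose
    candidate placements on either strand; the candidate with the
    fewest mismatches wins.  mapq surrogate: 42 for a unique best, 0
    for a tied best (the read is assigned to the lexicographically
    smallest class at its smallest offset), otherwise scaled by the
    best-vs-second-best mismatch gap.  Reads with no placement within
    the mismatch budget are dropped.
    """
    if len(library) == 0:  # pragma: no cover - guarded by dataclass
        raise ValueError("empty library")

    index: dict = {}
    for cid, seq in library.sequences.items():
        for pos in range(len(seq) - seed_k + 1):
            index.setdefault(seq[pos : pos + seed_k], []).append((cid, pos))

    out = []
    for read_id, seq in _read_pairs(reads):
        if len(seq) < seed_k:
            raise ValueError(f"read {read_id} shorter than seed_k={seed_k}")
        candidates = set()
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            offsets = list(range(0, len(oriented) - seed_k + 1, seed_k))
            for off in offsets:
                for cid, pos in index.get(oriented[off : off + seed_k], ()):
                    start = pos - off
                    ref = library.sequences[cid]
                    if start < 0 or start + len(oriented) > len(ref):
                        continue
                    candidates.add((cid, start, strand))
        scored = []
        for cid, start, strand in candidates:
            oriented = seq if strand == "+" else revcomp(seq)
            ref = library.sequences[cid]
            mm = sum(
                1
                for a, b in zip(oriented, ref[start : start + len(oriented)])
                if a != b
            )
            if mm <= max_mismatches:
                scored.append((mm, cid, start, strand))
        if not scored:
            continue
        scored.sort(key=lambda t: (t[0], t[1], t[2]))
        best = scored[0]
        if len(scored) == 1:
            mapq = 42
        elif scored[1][0] == best[0]:
            mapq = 0
        else:
            mapq = min(42, 7 * (scored[1][0] - best[0]))
        out.append(
            AlignmentRecord(
                read_id=read_id,
                ref=best[1],
                start=best[2],
                length=len(seq),
                strand=best[3],
                mapq=mapq,
            )
        )
    return out


def count_reads(
    alignments: Iterable[AlignmentRecord],
    library: ConsensusLibrary,
    library_size: int,
) -> CountTable:
    """Tally aligned reads per class; unknown references are rejected."""
    counts = {cid: 0 for cid in library.class_ids}
    for rec in alignments:
        if rec.ref not in counts:
            raise KeyError(f"alignment reference {rec.ref!r} not in library")
        counts[rec.ref] += 1
    return CountTable(counts=counts, library_size=library_size)


def rpkm(counts: CountTable, library: ConsensusLibrary) -> dict:
    """Reads per kilobase of consensus per million library reads.

    rpkm_c = count_c / ((length_c/1000) * (library_size/1e6))
    """
    lengths = library.lengths
    out = {}
    for cid, n in counts.counts.items():
        if cid not in lengths:
            raise KeyError(f"class {cid!r} in counts but not in library")
        out[cid] = n / ((lengths[cid] / 1_000) * (counts.library_size / 1_000_000))
    return out


def enrichment_table(
    treatment: CountTable,
    control: CountTable,
    library: ConsensusLibrary,
    min_rpkm: float = 10.0,
    fold_threshold: float = 1.25,
    pseudo: float = 0.01,
) -> pd.DataFrame:
    """Per-class fold enrichment of treatment (ChIP) over control (Input).

    ``expressed`` requires control RPKM > min_rpkm (the tissue-
    expression filter, applied to the Input library); ``enriched``
    additionally requires fold_change >= fold_threshold.  ``pseudo``
    (RPKM units) guards zero-control classes.  Sorted by fold_change
    descending.
    """
    rpkm_t = rpkm(treatment, library)
    rpkm_c = rpkm(control, library)
    lengths = library.lengths
    rows = []
    for cid in library.class_ids:
        rt, rc = rpkm_t[cid], rpkm_c[cid]
        fold = (rt + pseudo) / (rc + pseudo)
        expressed = rc > min_rpkm
        rows.append(
            {
                "class_id": cid,
                "length": lengths[cid],
                "count_t": treatment.counts[cid],
                "count_c": control.counts[cid],
                "rpkm_t": rt,
                "rpkm_c": rc,
                "fold_change": fold,
                "expressed": expressed,
                "enriched": expressed and fold >= fold_threshold,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        "fold_change", ascending=False, kind="mergesort"
    )
    return df.reset_index(drop=True)


def profile_consensus(
    alignments: Iterable[AlignmentRecord],
    library: ConsensusLibrary,
    class_id: str,
    flank_pad: int = 0,
) -> np.ndarray:
    """Per-base read depth along one consensus entry.

    The track covers the consensus (length L) plus ``flank_pad`` on
    each side (alignment overhangs are clipped to the track); track
    position i corresponds to consensus coordinate i - flank_pad.
    """
    if class_id not in library:
        raise KeyError(f"unknown class {class_id!r}")
    length = library.lengths[class_id]
    track = np.zeros(length + 2 * flank_pad, dtype=float)
    for rec in alignments:
        if rec.ref != class_id:
            continue
        lo = max(0, rec.start + flank_pad)
        hi = min(len(track), rec.end + flank_pad)
        if hi > lo:
            track[lo:hi] += 1
    return track
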