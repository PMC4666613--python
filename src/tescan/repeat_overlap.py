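"""Interval overlap arithmetic between peaks, repeat instances and
second-factor peak sets.

Overlap means >= min_bp shared bases under half-open coordinates, so
adjacent intervals ([100,200) vs [200,300)) do not overlap.  Strand
is ignored throughout: ChIP peaks are unstranded.  The pair
enumeration is a sorted sweep, O((n+m) log(n+m) + hits).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .io_formats import GenomicInterval


@dataclass
class OverlapSummary:
    """Directional peak-vs-peak overlap counts."""

    n_a: int
    n_b: int
    n_a_hit: int
    n_b_hit: int

    @property
    def frac_a(self) -> float:
        return self.n_a_hit / self.n_a if self.n_a else 0.0

    @property
    def frac_b(self) -> float:
        return self.n_b_hit / self.n_b if self.n_b else 0.0


def overlap_pairs(
    set_a: Sequence[GenomicInterval],
    set_b: Sequence[GenomicInterval],
    min_bp: int = 1,
) -> list:
    """All (i, j) index pairs with >= min_bp overlapping bases.

    Sweep over start/end events per chromosome keeping active sets of
    both inputs; each overlap is tested once when the later interval
    opens.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    events = []  # (pos, kind, side, index); ends sort before starts at same pos
    for idx, iv in enumerate(set_a):
        events.append((iv.chrom, iv.start, 1, "a", idx))
        events.append((iv.chrom, iv.end, 0, "a", idx))
    for idx, iv in enumerate(set_b):
        events.append((iv.chrom, iv.start, 1, "b", idx))
        events.append((iv.chrom, iv.end, 0, "b", idx))
    events.sort(key=lambda e: (e[0], e[1], e[2]))
    active = {"a": set(), "b": set()}
    current_chrom = None
    pairs = []
    for chrom, pos, kind, side, idx in events:
        if chrom != current_chrom:
            active = {"a": set(), "b": set()}
            current_chrom = chrom
        if kind == 0:
            active[side].discard(idx)
            continue
        other = "b" if side == "a" else "a"
        iv = (set_a if side == "a" else set_b)[idx]
        for jdx in active[other]:
            jv = (set_a if other == "a" else set_b)[jdx]
            if iv.overlap_length(jv) >= min_bp:
                pairs.append((idx, jdx) if side == "a" else (jdx, idx))
        active[side].add(idx)
    pairs.sort()
    return pairs


def class_overlap_summary(
    peaks: Sequence[GenomicInterval],
    instances: pd.DataFrame,
    min_bp: int = 1,
) -> pd.DataFrame:
    """Per repeat class: how many genomic instances a peak touches.

    An instance counts as overlapping when at least one peak shares
    >= min_bp bases with it.  Fractions are reported both to 0.1%
    (``percent``) and as a rounded integer percent (``percent_int``),
    the form the per-class bound fractions are usually quoted in.
    """
    ivs = [
        GenomicInterval(row.chrom, int(row.start), int(row.end), name=str(i))
        for i, row in enumerate(instances.itertuples(index=False))
    ]
    hit = set(j for _, j in overlap_pairs(peaks, ivs, min_bp=min_bp))
    class_ids = list(instances["class_id"])
    per_class_n = defaultdict(int)
    per_class_hit = defaultdict(int)
    for j, cid in enumerate(class_ids):
        per_class_n[cid] += 1
        if j in hit:
            per_class_hit[cid] += 1
    rows = []
    for cid in dict.fromkeys(class_ids):
        n, h = per_class_n[cid], per_class_hit[cid]
        frac = h / n if n else 0.0
        rows.append(
            {
                "class_id": cid,
                "n_instances": n,
                "n_overlapping": h,
                "fraction": frac,
                "percent": round(100 * frac, 1),
                "percent_int": int(round(100 * frac)),
            }
        )
    return pd.DataFrame(rows)


def peak_peak_summary(
    peaks_a: Sequence[GenomicInterval],
    peaks_b: Sequence[GenomicInterval],
    min_bp: int = 1,
) -> OverlapSummary:
    """Directional overlap between two peak sets.

    For each direction, the count of peaks hit by >= 1 peak of the
    other set; the two fractions need not be symmetric (a peak can
    hit several).
    """
    pairs = overlap_pairs(peaks_a, peaks_b, min_bp=min_bp)
    return OverlapSummary(
        n_a=len(peaks_a),
        n_b=len(peaks_b),
        n_a_hit=len({i for i, _ in pairs}),
        n_b_hit=len({j for _, j in pairs}),
    )
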