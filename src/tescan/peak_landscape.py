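"""Peak classification and anchored read-density profiles.

Peaks are classified against gene annotation into promoter (summit
within a window of a TSS, default 2 kb), intragenic or intergenic —
an exclusive, promoter-first partition.  Read densities are profiled
as length-normalized metagene/element profiles with fixed-width
flanks, and as anchor x bin matrices (e.g. a 6 kb window centred on
TSSs at 50 bp bins) that can be clustered by k-means for heat-plot
style displays.

A read contributes to the single bin containing its midpoint, which
avoids double counting across bins.  Densities are reads per base so
bins of different genomic width are comparable.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import AlignmentRecord, GeneModel, GenomicInterval, logger


@dataclass
class DensityMatrix:
    """Anchor x bin matrix of read counts (midpoint-binned)."""

    anchor_ids: list
    bin_width: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.anchor_ids):
            raise ValueError("values must be (n_anchors, n_bins)")
        if (self.values < 0).any():
            raise ValueError("negative densities")

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


@dataclass
class ClusterAssignment:
    """anchor -> cluster label in 1..K, with a display ordering."""

    labels: dict
    k: int
    order: list

    def __post_init__(self) -> None:
        if not (1 <= self.k <= len(self.labels)):
            raise ValueError("need 1 <= K <= number of anchors")
        if set(self.labels.values()) - set(range(1, self.k + 1)):
            raise ValueError("labels must lie in 1..K")


def classify_peaks(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    promoter_window: int = 2000,
) -> dict:
    """Partition peaks into promoter / intragenic / intergenic.

    A peak's position is its midpoint (the summit surrogate for BED3
    input).  Promoter: within +/- promoter_window of any TSS; else
    intragenic if inside any gene span; else intergenic.  Counts and
    percentages (summing to 100) are returned along with per-peak
    labels.
    """
    tss_by_chrom = defaultdict(list)
    span_by_chrom = defaultdict(list)
    for g in genes:
        tss_by_chrom[g.chrom].append(g.tss)
        span_by_chrom[g.chrom].append((g.span_start, g.span_end))
    labels = []
    for pk in peaks:
        mid = pk.midpoint
        if any(abs(mid - t) <= promoter_window for t in tss_by_chrom[pk.chrom]):
            labels.append("promoter")
        elif any(s <= mid < e for s, e in span_by_chrom[pk.chrom]):
            labels.append("intragenic")
        else:
            labels.append("intergenic")
    counts = {
        cat: labels.count(cat) for cat in ("promoter", "intragenic", "intergenic")
    }
    total = len(peaks)
    percent = {
        cat: (100.0 * n / total if total else 0.0) for cat, n in counts.items()
    }
    return {"labels": labels, "counts": counts, "percent": percent, "total": total}


def _midpoints_by_chrom(alignments: Iterable[AlignmentRecord]) -> dict:
    mids = defaultdict(list)
    for rec in alignments:
        mids[rec.ref].append(rec.midpoint)
    return {c: np.sort(np.array(v, dtype=np.int64)) for c, v in mids.items()}


def _scaled_profile(
    mids_by_chrom: dict,
    regions: Sequence[tuple],
    flank: int,
    body_bins: int,
    flank_bin: int = 50,
) -> np.ndarray:
    """Mean per-base density over regions: fixed flank bins + scaled body.

    ``regions`` are (chrom, start, end, strand) half-open spans.
    Minus-strand regions are reversed so bin 0 is always the 5' flank
    edge.  Returns a (n_flank_bins + body_bins + n_flank_bins,) mean
    density (reads per bp) across regions.
    """
    n_flank_bins = flank // flank_bin
    n_bins = 2 * n_flank_bins + body_bins
    acc = np.zeros(n_bins)
    n_used = 0
    for chrom, start, end, strand in regions:
        if end <= start:
            logger.warning("skipping zero-length region on %s", chrom)
            continue
        body_len = end - start
        prof = np.zeros(n_bins)
        mids = mids_by_chrom.get(chrom, np.array([], dtype=np.int64))
        lo, hi = start - flank, end + flank
        sel = mids[(mids >= lo) & (mids < hi)]
        for m in sel:
            if m < start:  # upstream flank (reference orientation)
                b = (m - lo) // flank_bin
                width = flank_bin
            elif m >= end:
                b = n_flank_bins + body_bins + (m - end) // flank_bin
                width = flank_bin
            else:
                b = n_flank_bins + (m - start) * body_bins // body_len
                width = body_len / body_bins
            prof[int(b)] += 1.0 / width
        if strand == "-":
            prof = prof[::-1]
        acc += prof
        n_used += 1
    return acc / max(n_used, 1)


def metagene_profile(
    alignments: Iterable[AlignmentRecord],
    genes: Sequence[GeneModel],
    flank: int = 2000,
    body_bins: int = 100,
    flank_bin: int = 50,
) -> np.ndarray:
    """Average read density along gene bodies plus fixed flanks.

    Gene bodies are length-normalized to ``body_bins`` bins; the 5'
    and 3' flanks use fixed ``flank_bin`` bp bins.  Minus-strand genes
    are reversed before averaging.  Output is mean density (reads/bp)
    per bin across genes; zero-span genes are skipped with a log line.
    """
    mids = _midpoints_by_chrom(alignments)
    regions = [(g.chrom, g.span_start, g.span_end, g.strand) for g in genes]
    return _scaled_profile(mids, regions, flank, body_bins, flank_bin)


def element_profile(
    alignments: Sequence[AlignmentRecord],
    instances,
    flank: int = 2000,
    body_bins: int = 100,
    flank_bin: int = 50,
    mapq_min: int = 20,
) -> tuple:
    """Paired element-anchored profiles: all reads vs mapq > mapq_min.

    ``instances`` is a repeat-instance DataFrame (chrom, start, end,
    strand, class_id).  The element body is scaled to ``body_bins``
    as in metagene_profile.  Returns (all_track, filtered_track); the
    filtered track uses only reads with mapq strictly above mapq_min,
    the uniqueness stratification used at young repeats.
    """
    if len(instances) == 0:
        raise ValueError("no instances given")
    alignments = list(alignments)
    regions = [
        (row.chrom, int(row.start), int(row.end), row.strand)
        for row in instances.itertuples(index=False)
    ]
    all_mids = _midpoints_by_chrom(alignments)
    filt_mids = _midpoints_by_chrom(
        r for r in alignments if r.mapq > mapq_min
    )
    track_all = _scaled_profile(all_mids, regions, flank, body_bins, flank_bin)
    track_filt = _scaled_profile(filt_mids, regions, flank, body_bins, flank_bin)
    return track_all, track_filt


def anchored_matrix(
    alignments: Iterable[AlignmentRecord],
    anchors: Sequence[tuple],
    half_window: int = 3000,
    bin_width: int = 50,
) -> DensityMatrix:
    """Read-midpoint counts in fixed bins around anchor points.

    ``anchors`` are (id, chrom, position) tuples; the window is
    [pos - half_window, pos + half_window) at ``bin_width`` bp bins,
    so a read whose midpoint sits exactly on the anchor lands in bin
    n_bins/2.  Windows running off a chromosome edge simply collect
    zero counts in the out-of-range bins.
    """
    if half_window % bin_width:
        raise ValueError("half_window must be divisible by bin_width")
    n_bins = 2 * half_window // bin_width
    mids = _midpoints_by_chrom(alignments)
    ids = [a[0] for a in anchors]
    values = np.zeros((len(anchors), n_bins))
    for i, (_, chrom, pos) in enumerate(anchors):
        m = mids.get(chrom, np.array([], dtype=np.int64))
        lo = pos - half_window
        sel = m[(m >= lo) & (m < pos + half_window)]
        if len(sel):
            idx = (sel - lo) // bin_width
            np.add.at(values[i], idx, 1.0)
    return DensityMatrix(anchor_ids=ids, bin_width=bin_width, values=values)


def subsample(
    alignments: Sequence[AlignmentRecord], n: int, seed: int
) -> list:
    """Uniform sample of exactly n alignments without replacement.

    Matches the depth-matching step used before density comparisons
    across libraries.  Deterministic for a given seed; input order of
    the kept records is preserved.
    """
    alignments = list(alignments)
    if n > len(alignments):
        raise ValueError(f"cannot subsample {n} from {len(alignments)}")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(alignments), size=n, replace=False))
    return [alignments[i] for i in keep]


def cluster_matrix(matrix: DensityMatrix, k: int, seed: int = 0) -> ClusterAssignment:
    """k-means clustering of row-normalized density rows.

    Rows are scaled by their own maximum (zero rows untouched) so the
    clustering responds to profile shape, not total signal; Euclidean
    k-means with ``n_init=100`` restarts at a fixed seed.  Display
    order: by cluster, then descending raw row sum.
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    if k > len(matrix.anchor_ids):
        raise ValueError("K exceeds number of rows")
    from sklearn.cluster import KMeans

    vals = matrix.values
    row_max = vals.max(axis=1, keepdims=True)
    normed = np.where(row_max > 0, vals / np.where(row_max > 0, row_max, 1), vals)
    km = KMeans(n_clusters=k, n_init=100, random_state=seed)
    raw = km.fit_predict(normed)
    labels = {aid: int(raw[i]) + 1 for i, aid in enumerate(matrix.anchor_ids)}
    sums = vals.sum(axis=1)
    order = [
        matrix.anchor_ids[i]
        for i in sorted(
            range(len(raw)), key=lambda i: (raw[i], -sums[i], matrix.anchor_ids[i])
        )
    ]
    return ClusterAssignment(labels=labels, k=k, order=order)
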