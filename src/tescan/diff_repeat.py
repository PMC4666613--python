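"""Two-group (wildtype vs heterozygote) expression comparison of
repeat classes and genes from count tables.

Counts are normalized to rates per million library reads; fold change
is the ratio of group means (with a pseudo-rate guard).  Significance
uses a pooled exact binomial test: under the null the pooled feature
count splits between the groups proportionally to the summed library
sizes, and the two-sided p-value sums all outcome probabilities no
larger than the observed one (the "minlike" convention).  This is a
declared simplification of a negative-binomial model: it is exact for
pure counting noise but anticonservative under biological
overdispersion, which output headers note.

Raw p-values are Benjamini-Hochberg adjusted, and differential
results can be joined with ChIP enrichment to flag classes both bound
(ChIP fold over Input above a floor) and de-repressed (RNA ratio
above a floor).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import logger

OVERDISPERSION_NOTE = (
    "# two_group_test: pooled exact binomial; assumes no biological "
    "overdispersion (anticonservative when replicates overdisperse)"
)


@dataclass
class GroupedCounts:
    """Feature x sample count matrix with group labels and library sizes."""

    counts: pd.DataFrame  # features x samples, non-negative ints
    groups: dict  # sample -> "wt" | "het"
    library_sizes: dict  # sample -> total reads

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        for s in self.counts.columns:
            if s not in self.groups:
                raise ValueError(f"sample {s!r} has no group label")
            if self.library_sizes.get(s, 0) <= 0:
                raise ValueError(f"sample {s!r} needs a positive library size")

    def samples_in(self, group: str) -> list:
        return [s for s in self.counts.columns if self.groups[s] == group]


def normalize(grouped: GroupedCounts) -> pd.DataFrame:
    """Counts per million library reads, per sample."""
    sizes = pd.Series(
        {s: grouped.library_sizes[s] for s in grouped.counts.columns}, dtype=float
    )
    return grouped.counts / (sizes / 1_000_000)


def group_means(grouped: GroupedCounts, normalized: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean normalized rate per feature for each group."""
    return pd.DataFrame(
        {
            g: normalized[grouped.samples_in(g)].mean(axis=1)
            for g in ("wt", "het")
        }
    )


def class_ratio(
    grouped: GroupedCounts,
    group_a: str = "wt",
    group_b: str = "het",
    pseudo: float = 0.5,
) -> pd.DataFrame:
    """Fold change of group_b over group_a on the normalized scale.

    fold_change = (mean_b + pseudo) / (mean_a + pseudo), with
    mean_intensity = mean_a * mean_b as the product-scale expression
    for MA-style displays.  ``pseudo`` is in normalized counts per
    million.
    """
    normalized = normalize(grouped)
    mean_a = normalized[grouped.samples_in(group_a)].mean(axis=1)
    mean_b = normalized[grouped.samples_in(group_b)].mean(axis=1)
    if mean_a.isna().any() or mean_b.isna().any():
        raise ValueError("both groups must be non-empty")
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": (mean_b + pseudo) / (mean_a + pseudo),
            "mean_intensity": mean_a * mean_b,
        }
    )


def two_group_test(grouped: GroupedCounts) -> pd.Series:
    """Exact pooled binomial two-sided p-value per feature.

    The pooled count n splits Binomial(n, pi) between groups under
    the null, pi = summed het library size / summed total; the
    two-sided p sums P(X = k) over all k with P(X = k) <= P(observed).
    Features with zero pooled count get p = 1.
    """
    wt, het = grouped.samples_in("wt"), grouped.samples_in("het")
    if not wt or not het:
        raise ValueError("need at least one sample per group")
    size_het = sum(grouped.library_sizes[s] for s in het)
    size_all = size_het + sum(grouped.library_sizes[s] for s in wt)
    pi = size_het / size_all
    pooled = grouped.counts.sum(axis=1).astype(int)
    obs_het = grouped.counts[het].sum(axis=1).astype(int)
    pvals = np.ones(len(pooled))
    for i, (n, k) in enumerate(zip(pooled.values, obs_het.values)):
        if n == 0:
            continue
        pvals[i] = _binom_minlike(int(n), int(k), pi)
    return pd.Series(pvals, index=grouped.counts.index, name="p_raw")


def _binom_minlike(n: int, k: int, pi: float) -> float:
    """Two-sided minlike binomial p: sum of P(X=j) over all j with
    P(X=j) <= P(X=k).  The pmf is evaluated on a window of +/- 20
    standard deviations around the mean (always containing k); mass
    outside is below 1e-20 and its terms are smaller than any pmf
    value inside, so the truncation error is negligible."""
    sd = np.sqrt(n * pi * (1 - pi))
    lo = max(0, int(np.floor(n * pi - 20 * sd)))
    hi = min(n, int(np.ceil(n * pi + 20 * sd)))
    lo, hi = min(lo, k), max(hi, k)
    support = np.arange(lo, hi + 1)
    pmf = stats.binom.pmf(support, n, pi)
    p_obs = pmf[k - lo]
    return min(1.0, float(pmf[pmf <= p_obs * (1 + 1e-9)].sum()))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def differential_table(
    grouped: GroupedCounts,
    direction: str = "het_over_wt",
    pseudo: float = 0.5,
) -> pd.DataFrame:
    """Full differential result: fold change, raw and BH-adjusted p.

    ``direction`` selects het/wt (default, up-regulation in mutants
    reads as fold > 1) or wt/het for the inverted axis.
    """
    if direction == "het_over_wt":
        ratios = class_ratio(grouped, "wt", "het", pseudo=pseudo)
    elif direction == "wt_over_het":
        ratios = class_ratio(grouped, "het", "wt", pseudo=pseudo)
    else:
        raise ValueError("direction must be het_over_wt or wt_over_het")
    p_raw = two_group_test(grouped)
    return pd.DataFrame(
        {
            "fold_change": ratios["fold_change"],
            "mean_intensity": ratios["mean_intensity"],
            "p_raw": p_raw,
            "p_adjusted": bh_adjust(p_raw.values),
        }
    )


def joint_chip_rna(
    enrichment: pd.DataFrame,
    diff: pd.DataFrame,
    chip_fold_min: float = 3.0,
    rna_fold_min: float = 1.3,
) -> pd.DataFrame:
    """Inner-join ChIP enrichment with RNA differential results.

    A class is flagged when its ChIP fold over Input exceeds
    ``chip_fold_min`` and its RNA fold change is at least
    ``rna_fold_min`` — bound and de-repressed.  Classes present in
    only one table are dropped with a log line.  Output is
    scatter-ready: chip_fold on X, rna_fold on Y.
    """
    chip = enrichment.set_index("class_id")["fold_change"].rename("chip_fold")
    rna = diff["fold_change"].rename("rna_fold")
    joined = pd.concat([chip, rna], axis=1, join="inner")
    dropped = (set(chip.index) | set(rna.index)) - set(joined.index)
    if dropped:
        logger.info("joint_chip_rna: dropped unshared classes: %s", sorted(dropped))
    joined["flagged"] = (joined["chip_fold"] > chip_fold_min) & (
        joined["rna_fold"] >= rna_fold_min
    )
    return joined.reset_index().rename(columns={"index": "class_id"})
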