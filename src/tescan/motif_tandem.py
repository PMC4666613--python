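"""Motif scanning, tandem-site detection and MAST-style E-values.

A motif is either a degenerate IUPAC consensus (e.g. the Myb binding
consensus AACTGYCW = AACTG(C/T)C(A/T)) or a position weight matrix.
PWM hits are scored in bits (log2 likelihood ratio against a
background base composition); per-position p-values come from the
exact distribution of the integerized score under the background,
computed by dynamic programming.  A sequence's p-value is the
probability that at least one of its m scanned positions (both
strands) reaches the best observed score, p_seq = 1 - (1 - p_best)^m,
and its E-value is p_seq times the number of sequences searched —
the expected count of sequences scoring as well under the null.

Tandem arrays — runs of same-strand hits with small start-to-start
gaps, like the four Myb sites at the 5' end of the RLTR10B LTR — are
detected per sequence, and motif presence can be tested for
enrichment between two element clusters with an exact Fisher test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Motif:
    """Degenerate consensus and/or PWM with a background model.

    ``pwm`` is a (width, 4) matrix of per-position base probabilities
    in A,C,G,T order; columns (positions) each sum to 1.  ``background``
    sums to 1.  ``pseudocount`` is added per cell before taking logs.
    """

    pwm: Optional[np.ndarray] = None
    consensus: Optional[str] = None
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        if self.pwm is None and self.consensus is None:
            raise ValueError("motif needs a PWM or a consensus string")
        if self.consensus is not None:
            self.consensus = self.consensus.upper()
            bad = set(self.consensus) - set(IUPAC)
            if bad:
                raise ValueError(f"invalid IUPAC codes: {sorted(bad)}")
        if self.pwm is not None:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.ndim != 2 or self.pwm.shape[1] != 4:
                raise ValueError("pwm must be (width, 4)")
            sums = self.pwm.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise ValueError("pwm positions must each sum to 1")
        self.background = np.asarray(self.background, dtype=float)
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")
        if self.width < 1:
            raise ValueError("motif width must be >= 1")

    @property
    def width(self) -> int:
        if self.pwm is not None:
            return self.pwm.shape[0]
        return len(self.consensus)

    @classmethod
    def from_iupac(cls, consensus: str, **kw) -> "Motif":
        """Motif from a degenerate consensus; also derives a flat PWM
        (uniform over the allowed bases at each position)."""
        pwm = np.zeros((len(consensus), 4))
        for i, code in enumerate(consensus.upper()):
            allowed = IUPAC[code]
            for b in allowed:
                pwm[i, _BASE_INDEX[b]] = 1.0 / len(allowed)
        return cls(pwm=pwm, consensus=consensus, **kw)

    @classmethod
    def from_counts(cls, counts, pseudocount: float = 0.01, **kw) -> "Motif":
        """Motif from a JASPAR-style 4 x width count matrix (rows A,C,G,T)."""
        counts = np.asarray(counts, dtype=float)
        if counts.shape[0] != 4:
            raise ValueError("count matrix must have 4 rows (A,C,G,T)")
        pwm = (counts / counts.sum(axis=0)).T
        return cls(pwm=pwm, pseudocount=pseudocount, **kw)

    @classmethod
    def from_jaspar_file(cls, path, **kw) -> "Motif":
        """Read a plain-text 4-row count matrix (optionally with
        'A [ ... ]' style row labels, as JASPAR .pfm files use)."""
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(">"):
                    continue
                cleaned = (
                    line.replace("[", " ").replace("]", " ").replace(",", " ")
                )
                parts = cleaned.split()
                if parts and parts[0].upper() in set("ACGT"):
                    parts = parts[1:]
                rows.append([float(x) for x in parts])
        if len(rows) != 4:
            raise ValueError(f"expected 4 matrix rows, got {len(rows)}")
        return cls.from_counts(np.array(rows), **kw)

    def log_odds(self) -> np.ndarray:
        """(width, 4) log2 likelihood-ratio matrix in bits, with the
        pseudocount added per cell (then renormalized) before logs."""
        if self.pwm is None:
            raise ValueError("consensus-only motif has no PWM")
        p = self.pwm + self.pseudocount
        p /= p.sum(axis=1, keepdims=True)
        return np.log2(p / self.background[None, :])


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence.  ``offset`` is the 0-based start of the
    hit's span on the forward strand regardless of hit strand."""

    seq_id: str
    offset: int
    strand: str
    score: float = 0.0
    p_position: float = 1.0


@dataclass
class SequenceMotifResult:
    seq_id: str
    best_hit: Optional[MotifHit]
    p_sequence: float
    e_value: float
    tandem_count: int
    tandem_in_5prime: bool
    significant: bool = False


# ---------------------------------------------------------------------------
# Degenerate-consensus scanning


def _matches(seq: str, consensus: str) -> bool:
    return all(s in IUPAC[c] for s, c in zip(seq, consensus))


def scan_consensus(
    sequence: str,
    consensus,
    both_strands: bool = True,
    seq_id: str = "",
) -> list:
    """All exact degenerate-consensus matches in a sequence.

    Reverse-strand hits are reported with forward-strand offsets.
    """
    if isinstance(consensus, Motif):
        if consensus.consensus is None:
            raise ValueError("motif has no consensus string")
        consensus = consensus.consensus
    consensus = consensus.upper()
    bad = set(consensus) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC codes: {sorted(bad)}")
    sequence = sequence.upper()
    w = len(consensus)
    rc = revcomp(consensus)
    hits = []
    for off in range(len(sequence) - w + 1):
        window = sequence[off : off + w]
        if _matches(window, consensus):
            hits.append(MotifHit(seq_id, off, "+"))
        if both_strands and _matches(window, rc):
            hits.append(MotifHit(seq_id, off, "-"))
    return hits


# ---------------------------------------------------------------------------
# Exact PWM score distribution


@dataclass
class ScoreDistribution:
    """Exact distribution of the integerized PWM score under background.

    Scores are integerized at ``resolution`` bits (each log-odds cell
    rounded to the nearest multiple); the distribution is the exact
    convolution of the per-position score distributions, so scanning
    must use the same integer matrix (``int_matrix``) for p-values to
    be exact.
    """

    int_matrix: np.ndarray  # (width, 4) integer scores
    resolution: float
    offset: int  # support[i] corresponds to integer score i + offset
    probs: np.ndarray
    survival: np.ndarray  # survival[i] = P(score_int >= i + offset)

    def pvalue_int(self, int_score: int) -> float:
        """P(background window score >= int_score)."""
        i = int_score - self.offset
        if i < 0:
            return 1.0
        if i >= len(self.survival):
            return 0.0
        return float(self.survival[i])

    def pvalue(self, score_bits: float) -> float:
        return self.pvalue_int(int(round(score_bits / self.resolution)))


def pwm_score_distribution(
    motif: Motif, score_resolution: float = 0.01
) -> ScoreDistribution:
    """Exact null distribution of the PWM score by dynamic programming.

    Convolves, position by position, the distribution of the
    integerized per-base score under the background composition.
    """
    lod = motif.log_odds()
    int_matrix = np.rint(lod / score_resolution).astype(np.int64)
    lo = int(int_matrix.min(axis=1).sum())
    hi = int(int_matrix.max(axis=1).sum())
    probs = np.zeros(hi - lo + 1)
    # start with a point mass, offset bookkeeping in `cur_lo`
    probs[:1] = 1.0
    cur_lo, cur_len = 0, 1
    bg = np.asarray(motif.background)
    for pos in range(motif.width):
        nxt = np.zeros_like(probs)
        smin = int(int_matrix[pos].min())
        new_lo = cur_lo + smin
        for b in range(4):
            s = int(int_matrix[pos, b])
            shift = s - smin
            nxt[shift : shift + cur_len] += bg[b] * probs[:cur_len]
        cur_len = cur_len + int(int_matrix[pos].max()) - smin
        probs = nxt
        cur_lo = new_lo
    probs = probs[:cur_len]
    survival = np.cumsum(probs[::-1])[::-1]
    return ScoreDistribution(
        int_matrix=int_matrix,
        resolution=score_resolution,
        offset=cur_lo,
        probs=probs,
        survival=np.minimum(survival, 1.0),
    )


def _int_scores(sequence: str, dist: ScoreDistribution) -> np.ndarray:
    """Integerized window scores at every offset of one strand."""
    w = dist.int_matrix.shape[0]
    n = len(sequence) - w + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    idx = np.array([_BASE_INDEX.get(b, -1) for b in sequence], dtype=np.int64)
    scores = np.zeros(n, dtype=np.int64)
    penalty = int(dist.int_matrix.min()) - 1  # non-ACGT base: below support
    for pos in range(w):
        col = idx[pos : pos + n]
        valid = col >= 0
        scores[valid] += dist.int_matrix[pos, col[valid]]
        scores[~valid] += penalty
    return scores


def scan_pwm(
    sequence: str,
    motif: Motif,
    p_threshold: float = 1e-3,
    dist: Optional[ScoreDistribution] = None,
    both_strands: bool = True,
    seq_id: str = "",
) -> list:
    """PWM hits with per-position p-value <= p_threshold, both strands.

    Scores are bits; reverse-strand hits are reported at their
    forward-strand offsets.  A sequence shorter than the motif yields
    no hits.
    """
    if not (0 < p_threshold <= 1):
        raise ValueError("p_threshold must be in (0, 1]")
    if dist is None:
        dist = pwm_score_distribution(motif)
    sequence = sequence.upper()
    w = motif.width
    hits = []
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        seq = sequence if strand == "+" else revcomp(sequence)
        scores = _int_scores(seq, dist)
        for j, s in enumerate(scores):
            p = dist.pvalue_int(int(s))
            if p <= p_threshold:
                off = j if strand == "+" else len(sequence) - w - j
                hits.append(
                    MotifHit(seq_id, off, strand, float(s) * dist.resolution, p)
                )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def best_pvalue(
    sequence: str, motif: Motif, dist: Optional[ScoreDistribution] = None,
    both_strands: bool = True,
) -> tuple:
    """(best per-position p-value, m scanned positions) for one sequence."""
    if dist is None:
        dist = pwm_score_distribution(motif)
    sequence = sequence.upper()
    best = None
    m = 0
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        seq = sequence if strand == "+" else revcomp(sequence)
        scores = _int_scores(seq, dist)
        m += len(scores)
        if len(scores):
            p = dist.pvalue_int(int(scores.max()))
            best = p if best is None else min(best, p)
    return (1.0 if best is None else best), m


def sequence_evalue(
    per_sequence: Mapping[str, tuple],
    e_max: float = 10.0,
) -> list:
    """MAST-style per-sequence E-values from best-hit p-values.

    ``per_sequence`` maps seq_id -> (p_best, m, best_hit or None,
    tandem_count, tandem_in_5prime).  p_sequence = 1 - (1 - p_best)^m
    with m the number of scanned positions (both strands); e_value =
    p_sequence * N with N the number of sequences searched.  Results
    are sorted ascending by E-value; those with e_value < e_max are
    flagged significant.
    """
    n_seqs = len(per_sequence)
    results = []
    for seq_id, (p_best, m, best_hit, tandem_count, in5) in per_sequence.items():
        p_seq = float(-np.expm1(m * np.log1p(-p_best))) if p_best < 1 else 1.0
        if p_best == 0:
            p_seq = 0.0
        e = p_seq * n_seqs
        results.append(
            SequenceMotifResult(
                seq_id=seq_id,
                best_hit=best_hit,
                p_sequence=p_seq,
                e_value=e,
                tandem_count=tandem_count,
                tandem_in_5prime=in5,
                significant=e < e_max,
            )
        )
    results.sort(key=lambda r: (r.e_value, r.seq_id))
    return results


def tandem_sites(
    hits: Sequence[MotifHit],
    sequence_length: int,
    width: int,
    max_gap: int = 30,
    five_prime_fraction: float = 0.25,
) -> tuple:
    """Largest same-strand tandem run and whether it sits 5'.

    tandem_count is the size of the largest run of same-strand hits
    whose successive start-to-start gaps are <= max_gap.
    tandem_in_5prime is True iff that run (through the end of its last
    site) lies wholly within the first ``five_prime_fraction`` of the
    sequence.
    """
    if not hits:
        return 0, False
    best_run: list = []
    for strand in ("+", "-"):
        offs = sorted(h.offset for h in hits if h.strand == strand)
        run: list = []
        for off in offs:
            if run and off - run[-1] <= max_gap:
                run.append(off)
            else:
                if len(run) > len(best_run):
                    best_run = run
                run = [off]
        if len(run) > len(best_run):
            best_run = run
    in5 = (best_run[-1] + width) <= five_prime_fraction * sequence_length
    return len(best_run), bool(in5)


def analyze_library(
    sequences: Mapping[str, str],
    motif: Motif,
    p_threshold: float = 1e-3,
    max_gap: int = 30,
    five_prime_fraction: float = 0.25,
    e_max: float = 10.0,
) -> list:
    """Scan every sequence, compute E-values and tandem structure."""
    dist = pwm_score_distribution(motif)
    per_seq = {}
    for seq_id, seq in sequences.items():
        hits = scan_pwm(seq, motif, p_threshold, dist=dist, seq_id=seq_id)
        p_best, m = best_pvalue(seq, motif, dist=dist)
        best_hit = min(hits, key=lambda h: h.p_position) if hits else None
        count, in5 = tandem_sites(
            hits, len(seq), motif.width, max_gap, five_prime_fraction
        )
        per_seq[seq_id] = (p_best, m, best_hit, count, in5)
    return sequence_evalue(per_seq, e_max=e_max)


def cluster_motif_enrichment(
    site_presence: Mapping[str, bool],
    clusters: Mapping[str, int],
) -> dict:
    """Fisher exact test of motif presence between two clusters.

    Returns the 2x2 table (rows = clusters in sorted label order,
    cols = presence yes/no), the exact two-sided hypergeometric p and
    the odds ratio (Haldane-corrected, +0.5 per cell, when any cell is
    zero).
    """
    labels = sorted(set(clusters.values()))
    if len(labels) != 2:
        raise ValueError("exactly two clusters required")
    table = np.zeros((2, 2), dtype=int)
    for elem, lab in clusters.items():
        i = labels.index(lab)
        j = 0 if site_presence.get(elem, False) else 1
        table[i, j] += 1
    if table.sum(axis=1).min() == 0:
        raise ValueError("empty cluster")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    a, b, c, d = table.ravel().astype(float)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return {"table": table, "odds_ratio": float(odds), "p_value": float(p)}
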