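"""PWM motif scanning around TSSs and group-wise abundance comparison.

Motifs are position probability matrices over A/C/G/T. Scanning is a
log-odds scan of both strands of the +/-1 kb window around each TSS; the hit
threshold is the smallest score whose upper-tail probability under the
background model is at most 1e-4, computed by exact enumeration of the score
distribution. Abundances are normalized per TSS of each group and compared
with two-tailed Welch t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class Pwm:
    name: str
    probs: np.ndarray  # (length, 4) over A,C,G,T

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM must be length x 4")
        if np.abs(self.probs.sum(axis=1) - 1.0).max() > 1e-6:
            raise ValueError(f"PWM {self.name!r}: rows must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]


def read_jaspar_pfm(path) -> list[Pwm]:
    """Read JASPAR-style position frequency matrices; counts are converted
    to probabilities row-wise."""
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in BASES], dtype=float).T
            totals = counts.sum(axis=1, keepdims=True)
            if (totals <= 0).any():
                raise ValueError(f"motif {m.name}: zero-count column")
            out.append(Pwm(m.name or m.matrix_id, counts / totals))
    return out


def log_odds(pwm: Pwm, background: Sequence[float]) -> np.ndarray:
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-6 or (bg <= 0).any():
        raise ValueError("background must be 4 positive probabilities summing to 1")
    with np.errstate(divide="ignore"):
        return np.log2(pwm.probs) - np.log2(bg)[None, :]


def score_threshold(
    pwm: Pwm, background: Sequence[float], p_max: float = 1e-4,
    precision: int = 9,
) -> float:
    """Smallest log-odds score whose background upper-tail probability is
    <= p_max, by exact enumeration of the score distribution (scores rounded
    to ``precision`` decimals to collapse numerically equal sums).

    Returns +inf when no attainable score is that improbable (e.g. a uniform
    PWM), in which case no position can ever be a hit — except for PWMs with
    hard constraints (zero-probability bases): a motif too short for the tail
    bound but with impossible windows falls back to demanding the maximum
    attainable score, i.e. exact consensus matching.
    """
    lo = log_odds(pwm, background)
    bg = np.asarray(background, dtype=float)
    dist: dict[float, float] = {0.0: 1.0}
    for row in lo:
        new: dict[float, float] = {}
        for s, p in dist.items():
            for j in range(4):
                if bg[j] == 0:
                    continue
                s2 = s + row[j]
                key = -np.inf if np.isneginf(s2) else round(float(s2), precision)
                new[key] = new.get(key, 0.0) + p * bg[j]
        dist = new
    finite = sorted((s for s in dist if np.isfinite(s)), reverse=True)
    tail = 0.0
    threshold = np.inf
    for s in finite:
        tail += dist[s]
        if tail <= p_max:
            threshold = s
        else:
            break
    if not np.isfinite(threshold) and np.isneginf(lo).any() and finite:
        threshold = float(np.sum(np.max(lo, axis=1)))
    return float(threshold)


def _encode(seq: str) -> np.ndarray:
    idx = np.full(len(seq), 4, dtype=np.int8)
    for j, b in enumerate(BASES):
        idx[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = j
    return idx


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT.get(b, "N") for b in reversed(seq.upper()))


def _scan_one_strand(seq_idx: np.ndarray, lo: np.ndarray, threshold: float) -> int:
    m = lo.shape[0]
    n = seq_idx.shape[0]
    if n < m or not np.isfinite(threshold):
        return 0
    lo5 = np.hstack([lo, np.full((m, 1), -np.inf)])  # N never matches
    scores = np.zeros(n - m + 1)
    for j in range(m):
        scores = scores + lo5[j, seq_idx[j:j + n - m + 1]]
    return int(np.sum(scores >= threshold - 1e-12))


def scan_pwm(
    sequences: dict[str, str],
    pwms: list[Pwm],
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    p_max: float = 1e-4,
) -> dict[str, dict[str, int]]:
    """Occurrence counts per sequence per motif over both strands."""
    thresholds = {p.name: score_threshold(p, background, p_max) for p in pwms}
    lods = {p.name: log_odds(p, background) for p in pwms}
    out: dict[str, dict[str, int]] = {}
    for sid, seq in sequences.items():
        fwd = _encode(seq.upper())
        rev = _encode(reverse_complement(seq))
        counts = {}
        for p in pwms:
            lo, thr = lods[p.name], thresholds[p.name]
            counts[p.name] = (
                _scan_one_strand(fwd, lo, thr) + _scan_one_strand(rev, lo, thr)
            )
        out[sid] = counts
    return out


def compare_motif_abundance(
    counts_a: dict[str, dict[str, int]],
    counts_b: dict[str, dict[str, int]],
) -> dict[str, tuple[float, float, Optional[float], Optional[float]]]:
    """Per motif: (abundance A, abundance B, Welch t, two-tailed p).

    Abundance = total occurrences / number of TSSs in the group. The t-test
    runs on per-sequence counts; groups of size < 2 report p as missing, and
    a zero-variance-both-groups split is handled with an epsilon variance
    guard (identical groups give t = 0, p = 1).
    """
    from scipy import stats

    if not counts_a or not counts_b:
        raise ValueError("both groups must be non-empty")
    motifs = sorted({m for d in counts_a.values() for m in d})
    out = {}
    for motif in motifs:
        xa = np.array([d.get(motif, 0) for d in counts_a.values()], dtype=float)
        xb = np.array([d.get(motif, 0) for d in counts_b.values()], dtype=float)
        abund_a = float(xa.sum() / xa.size)
        abund_b = float(xb.sum() / xb.size)
        if xa.size < 2 or xb.size < 2:
            out[motif] = (abund_a, abund_b, None, None)
            continue
        if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0:
            if abund_a == abund_b:
                out[motif] = (abund_a, abund_b, 0.0, 1.0)
            else:
                eps = 1e-12
                se = np.sqrt(eps / xa.size + eps / xb.size)
                t = (abund_a - abund_b) / se
                out[motif] = (abund_a, abund_b, float(t), 0.0)
            continue
        res = stats.ttest_ind(xa, xb, equal_var=False)
        out[motif] = (abund_a, abund_b, float(res.statistic), float(res.pvalue))
    return out


def metaprofile(
    track: dict[str, np.ndarray],
    anchors: list[tuple[str, int, str]],
    flank: int = 3000,
    bin_size: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Anchor x bin matrix of mean track signal around anchors, 5'->3'.

    ``track`` holds per-position values per chromosome. Rows of minus-strand
    anchors are reversed so all rows read 5'->3'; positions beyond a
    chromosome edge are NaN and ignored by the columnwise mean profile.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be a multiple of bin_size")
    n_bins = 2 * flank // bin_size
    rows = np.full((len(anchors), n_bins), np.nan)
    for i, (chrom, pos, strand) in enumerate(anchors):
        values = track.get(chrom)
        if values is None:
            continue
        for b in range(n_bins):
            start = pos - flank + b * bin_size
            end = start + bin_size
            if start < 0 or end > values.shape[0]:
                continue
            rows[i, b] = float(np.mean(values[start:end]))
        if strand == "-":
            rows[i] = rows[i, ::-1]
    counts = np.sum(~np.isnan(rows), axis=0)
    sums = np.nansum(rows, axis=0)
    profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return rows, profile
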