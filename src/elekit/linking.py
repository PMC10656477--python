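"""Enhancer-gene target prediction by regulatory potential + correlation.

Each gene's regulatory potential (RP) is the sum of exponentially
distance-decayed contributions of enhancer-like elements within 20*d0 of
its TSS, RP = sum_i 2^(-d_i/d0) with decay distance d0 = 100 kb. ELE-gene
pairs within a 2 Mb window whose per-sample CAGE RPM Pearson correlation
exceeds 0.5 and whose gene RP is in the top half (median over genes with at
least one contributing ELE) are called predicted targets.

Tissue specificity of any expression row is labeled with the tau index,
tau = sum(1 - x_i/x_max)/(n-1) over per-tissue means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats


@dataclass
class RpParams:
    d0: float = 100_000.0
    window: float = 2_000_000.0
    k_range_multiplier: float = 20.0
    corr_min: float = 0.5
    rp_quantile: float = 0.5

    def __post_init__(self) -> None:
        if self.window <= 0 or self.d0 <= 0:
            raise ValueError("window and d0 must be positive")
        if not (0 <= self.corr_min <= 1):
            raise ValueError("corr_min must lie in [0,1]")
        if not (0 < self.rp_quantile <= 1):
            raise ValueError("rp_quantile must lie in (0,1]")


@dataclass
class TargetLink:
    gene_id: str
    ele_id: str
    distance: float
    rp: float
    correlation: Optional[float]
    predicted: bool


def candidate_pairs(
    eles: list[tuple[str, str, int]],
    genes: list[tuple[str, str, int]],
    params: RpParams | None = None,
) -> list[tuple[str, str, float]]:
    """All (ele_id, gene_id, distance) with |ELE position - gene TSS| within
    the pairing window on the same chromosome.

    ``eles``/``genes`` are (id, chrom, position) triples; positions are the
    ELE dominant position and the gene TSS.
    """
    params = params or RpParams()
    by_chrom: dict[str, list[tuple[str, int]]] = {}
    for gid, chrom, tss in genes:
        by_chrom.setdefault(chrom, []).append((gid, tss))
    out = []
    for eid, chrom, pos in eles:
        for gid, tss in by_chrom.get(chrom, []):
            d = abs(pos - tss)
            if d <= params.window:
                out.append((eid, gid, float(d)))
    out.sort()
    return out


def rp_score(distances: Sequence[float], params: RpParams | None = None) -> float:
    """RP = sum over ELEs within 20*d0 of 2^(-d/d0); farther ELEs contribute 0."""
    params = params or RpParams()
    cutoff = params.k_range_multiplier * params.d0
    total = 0.0
    for d in distances:
        if d < 0:
            raise ValueError("negative ELE-gene distance")
        if d <= cutoff:
            total += 2.0 ** (-d / params.d0)
    return total


def expression_correlation(
    ele_rpm: Sequence[float], gene_rpm: Sequence[float]
) -> Optional[float]:
    """Pearson r of per-sample RPM vectors; None when either side has zero
    variance (treated downstream as failing the correlation filter)."""
    x = np.asarray(ele_rpm, dtype=float)
    y = np.asarray(gene_rpm, dtype=float)
    if x.shape != y.shape:
        raise ValueError("expression vectors must have identical sample sets")
    if x.size < 3:
        raise ValueError("need at least 3 samples for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def predict_targets(
    pairs: list[tuple[str, str, float]],
    ele_expr: dict[str, Sequence[float]],
    gene_expr: dict[str, Sequence[float]],
    params: RpParams | None = None,
) -> list[TargetLink]:
    """Score all candidate pairs and flag predicted targets.

    The RP threshold is the ``rp_quantile`` quantile (default: median) of RP
    over genes having at least one contributing ELE. A pair is predicted iff
    its correlation is strictly greater than ``corr_min`` and its gene's RP
    reaches the threshold. Output is sorted and independent of input order.
    """
    params = params or RpParams()
    per_gene: dict[str, list[tuple[str, float]]] = {}
    for eid, gid, d in pairs:
        per_gene.setdefault(gid, []).append((eid, d))
    cutoff = params.k_range_multiplier * params.d0
    gene_rp = {
        gid: rp_score([d for _, d in lst], params) for gid, lst in per_gene.items()
    }
    contributing = [rp for gid, rp in gene_rp.items()
                    if any(d <= cutoff for _, d in per_gene[gid])]
    if contributing:
        threshold = float(np.quantile(contributing, 1.0 - params.rp_quantile))
    else:
        threshold = math.inf
    links = []
    for eid, gid, d in sorted(pairs):
        r = None
        if eid in ele_expr and gid in gene_expr:
            r = expression_correlation(ele_expr[eid], gene_expr[gid])
        predicted = (
            r is not None
            and r > params.corr_min
            and gene_rp[gid] >= threshold
        )
        links.append(TargetLink(gid, eid, d, gene_rp[gid], r, predicted))
    return links


def tissue_specificity(
    tissue_means: Sequence[float],
    tissue_names: Sequence[str],
    tau_min: float = 0.8,
) -> tuple[str, Optional[float]]:
    """Label one expression row: ``specific-to-<tissue>``/``ubiquitous``/``silent``.

    Uses the tau index over per-tissue mean RPM; tau >= tau_min with nonzero
    maximum is tissue-specific (to the argmax tissue).
    """
    x = np.asarray(tissue_means, dtype=float)
    if x.size != len(tissue_names):
        raise ValueError("means/names length mismatch")
    if x.size < 2:
        raise ValueError("tau is undefined for a single tissue")
    if (x < 0).any():
        raise ValueError("negative expression means")
    xmax = x.max()
    if xmax == 0:
        return "silent", None
    tau = float(np.sum(1.0 - x / xmax) / (x.size - 1))
    if tau >= tau_min:
        return f"specific-to-{tissue_names[int(np.argmax(x))]}", tau
    return "ubiquitous", tau
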