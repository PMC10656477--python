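"""Scoring of pipeline output against the generator's planted ground truth.

Used by the end-to-end tests and the acceptance script; all functions are
pure and operate on in-memory pipeline products.
"""

from __future__ import annotations

import numpy as np

from .annotate import AnnotatedCluster
from .linking import TargetLink
from .simulate import GroundTruth
from .te import fisher_exact_2x2


def match_planted_ele(annotated: AnnotatedCluster, truth: GroundTruth,
                      slack: int = 20) -> str | None:
    """The planted ELE whose (slightly padded) interval contains the called
    cluster's dominant position, if any."""
    pos = annotated.cluster.dominant_position
    chrom = annotated.cluster.interval.chrom
    for ele in truth.eles:
        if (ele.interval.chrom == chrom
                and ele.interval.start - slack <= pos < ele.interval.end + slack):
            return ele.ele_id
    return None


def ele_recall_precision(
    annotated: list[AnnotatedCluster], truth: GroundTruth
) -> tuple[float, float]:
    """Recall over planted ELEs; precision over called ele_tss clusters.

    Bidirectional transcription yields up to two called clusters (one per
    strand) per planted element; any matching cluster counts the element as
    recovered.
    """
    called = [a for a in annotated if a.category == "ele_tss"]
    matches = [match_planted_ele(a, truth) for a in called]
    recovered = {m for m in matches if m is not None}
    recall = len(recovered) / len(truth.eles) if truth.eles else 1.0
    precision = (
        sum(1 for m in matches if m is not None) / len(called) if called else 1.0
    )
    return recall, precision


def gene_tss_accuracy(
    annotated: list[AnnotatedCluster], truth: GroundTruth,
    shape: str = "sharp",
) -> float:
    """Fraction of expressed (non-weak) planted TSSs of the given shape with
    a cluster containing the planted position assigned to the right gene."""
    by_gene: dict[str, list[AnnotatedCluster]] = {}
    for a in annotated:
        if a.category == "gene_tss" and a.assigned_gene:
            by_gene.setdefault(a.assigned_gene, []).append(a)
    hits = total = 0
    for pg in truth.genes:
        if pg.weak or pg.shape != shape:
            continue
        total += 1
        for a in by_gene.get(pg.gene_id, []):
            iv = a.cluster.interval
            if iv.start - 2 <= pg.tss < iv.end + 2:
                hits += 1
                break
    return hits / total if total else 1.0


def planted_links(truth: GroundTruth) -> set[tuple[str, str]]:
    return {
        (ele.ele_id, gid) for ele in truth.eles for gid in ele.target_genes
    }


def link_recall(
    links: list[TargetLink],
    called_to_planted: dict[str, str | None],
    truth: GroundTruth,
) -> float:
    """Fraction of planted (ELE, target gene) pairs recovered as predicted
    links through any called cluster of that ELE."""
    predicted = {
        (called_to_planted.get(l.ele_id), l.gene_id)
        for l in links if l.predicted
    }
    wanted = planted_links(truth)
    if not wanted:
        return 1.0
    return sum(1 for pair in wanted if pair in predicted) / len(wanted)


def link_enrichment_pvalue(
    links: list[TargetLink],
    called_to_planted: dict[str, str | None],
    truth: GroundTruth,
) -> float:
    """Fisher p for association between 'predicted' and 'planted-true' over
    all candidate pairs (a permutation-free exact version of the random
    gene-set comparison)."""
    wanted = planted_links(truth)
    a = b = c = d = 0
    for l in links:
        true_pair = (called_to_planted.get(l.ele_id), l.gene_id) in wanted
        if l.predicted and true_pair:
            a += 1
        elif l.predicted:
            b += 1
        elif true_pair:
            c += 1
        else:
            d += 1
    return fisher_exact_2x2(a, b, c, d)[1]


def promoter_state_overlap(
    states: dict[str, np.ndarray], tss_state: int, truth: GroundTruth,
    bin_size: int = 500,
) -> float:
    """Fraction of expressed-gene TSS bins decoded as the TSS-active state."""
    hits = total = 0
    for pg in truth.genes:
        if pg.weak:
            continue
        arr = states.get(pg.chrom)
        if arr is None:
            continue
        b = pg.tss // bin_size
        if 0 <= b < arr.shape[0]:
            total += 1
            if arr[b] == tss_state:
                hits += 1
    return hits / total if total else 0.0


def mean_age_relative_error(
    estimated: dict[str, float], truth: GroundTruth
) -> float:
    """|mean estimated age - mean true age| / mean true age over elements
    dated in both."""
    common = [t for t in truth.te_ages if t in estimated and estimated[t] is not None]
    if not common:
        raise ValueError("no dated elements to compare")
    est = np.mean([estimated[t] for t in common])
    true = np.mean([truth.te_ages[t][1] for t in common])
    return abs(est - true) / true
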