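"""Hierarchical TSS classification.

Merged tag clusters are partitioned into mutually exclusive categories:

* ``gene_tss`` — cluster overlaps a gene's 5'UTR or the 500 bp window
  immediately upstream of its annotated TSS (strand-aware);
* ``ele_tss`` — intergenic cluster (>3 kb from any gene model) overlapping
  an H3K4me3 or H3K9ac peak: an enhancer-like element;
* ``lc_gene_tss`` — weak cluster rescued because its dominant position sits
  in a bin decoded as the TSS-active chromatin state and it lies in/around a
  gene;
* ``intergenic_other`` — intergenic without active marks;
* ``proximal_unclassified`` — within 3 kb of a gene but not gene-assigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .clustering import TagCluster
from .intervals import GenomicInterval, IntervalIndex
from .io import GeneModel

CATEGORIES = (
    "gene_tss", "lc_gene_tss", "ele_tss", "intergenic_other",
    "proximal_unclassified",
)


@dataclass
class AnnotationConfig:
    gene_upstream_bp: int = 500
    intergenic_min_dist_bp: int = 3000
    ele_required_marks: tuple[str, ...] = ("H3K4me3", "H3K9ac")

    def __post_init__(self) -> None:
        if self.gene_upstream_bp >= self.intergenic_min_dist_bp:
            raise ValueError("gene_upstream_bp must be < intergenic_min_dist_bp")


@dataclass
class AnnotatedCluster:
    cluster: TagCluster
    category: str
    assigned_gene: Optional[str] = None
    mark_overlaps: set[str] = field(default_factory=set)
    hmm_state: Optional[int] = None
    weak: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "gene_tss" and not self.assigned_gene:
            raise ValueError("gene_tss requires an assigned gene")


def _gene_windows(genes: list[GeneModel], config: AnnotationConfig):
    """Per-gene promoter-capture intervals: 5'UTRs plus the strand-aware
    [TSS-500, TSS) upstream window."""
    windows = []
    for g in genes:
        if g.strand == "+":
            start, end = max(0, g.tss - config.gene_upstream_bp), g.tss
        else:
            start, end = g.tss + 1, g.tss + 1 + config.gene_upstream_bp
        if end > start:
            windows.append((GenomicInterval(g.chrom, start, end, g.strand), g))
        for u in g.utr5:
            windows.append((u, g))
    return windows


def assign_gene_tss(
    clusters: list[TagCluster], genes: list[GeneModel], config: AnnotationConfig
) -> dict[int, str]:
    """Map cluster index -> gene id for clusters in a 5'UTR/upstream window.

    Ambiguity between genes is resolved by nearest TSS to the cluster's
    dominant position, then lexical gene id.
    """
    windows = _gene_windows(genes, config)
    index = IntervalIndex()
    window_genes: list[GeneModel] = []
    for iv, g in windows:
        index.add(GenomicInterval(iv.chrom, iv.start, iv.end, iv.strand,
                                  name=str(len(window_genes))))
        window_genes.append(g)
    out: dict[int, str] = {}
    for i, cl in enumerate(clusters):
        hits = index.overlapping(cl.interval)
        if not hits:
            continue
        candidates = {
            window_genes[int(h.name)].gene_id: window_genes[int(h.name)]
            for h in hits
        }.values()
        best = min(
            candidates,
            key=lambda g: (abs(g.tss - cl.dominant_position), g.gene_id),
        )
        out[i] = best.gene_id
    return out


def find_intergenic(
    clusters: list[TagCluster],
    indices: list[int],
    genes: list[GeneModel],
    config: AnnotationConfig,
) -> tuple[list[int], list[int]]:
    """Split unassigned cluster indices into (intergenic, proximal).

    Intergenic means strictly more than ``intergenic_min_dist_bp`` from the
    nearest gene-model interval on any strand (overlap = distance 0).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    intergenic, proximal = [], []
    for i in indices:
        iv = clusters[i].interval
        near = by_chrom.get(iv.chrom, [])
        if not near:
            intergenic.append(i)
            continue
        dist = min(iv.distance_to(g.interval) for g in near)
        (intergenic if dist > config.intergenic_min_dist_bp else proximal).append(i)
    return intergenic, proximal


def call_ele_tss(
    clusters: list[TagCluster],
    intergenic_indices: list[int],
    peaks: dict[str, list[GenomicInterval]],
    config: AnnotationConfig,
) -> dict[int, set[str]]:
    """Intergenic clusters overlapping >=1 bp of an H3K4me3 or H3K9ac peak
    (any strand) are enhancer-like; returns index -> overlapping mark names."""
    mark_indexes = {
        mark: IntervalIndex(peaks.get(mark, []))
        for mark in config.ele_required_marks
    }
    out: dict[int, set[str]] = {}
    for i in intergenic_indices:
        iv = clusters[i].interval
        marks = {
            mark for mark, idx in mark_indexes.items() if idx.overlapping(iv)
        }
        if marks:
            out[i] = marks
    return out


def _state_at(states: dict[str, np.ndarray], bin_size: int, chrom: str,
              position: int) -> Optional[int]:
    arr = states.get(chrom)
    if arr is None:
        return None
    b = position // bin_size
    if 0 <= b < arr.shape[0]:
        return int(arr[b])
    return None


def rescue_lc_gene_tss(
    weak_clusters: list[TagCluster],
    states: dict[str, np.ndarray],
    tss_state_index: int,
    genes: list[GeneModel],
    config: AnnotationConfig,
    bin_size: int = 500,
) -> dict[int, str]:
    """Rescue weak clusters in TSS-active chromatin as low-confidence gene TSSs.

    A weak cluster qualifies when its dominant position falls in a bin decoded
    as the TSS-active state and it overlaps a gene body or the gene's
    5'UTR/upstream window; it is then assigned to that gene.
    """
    window_index = IntervalIndex()
    window_genes: list[GeneModel] = []
    for iv, g in _gene_windows(genes, config):
        window_index.add(GenomicInterval(iv.chrom, iv.start, iv.end, iv.strand,
                                         name=str(len(window_genes))))
        window_genes.append(g)
    body_index = IntervalIndex()
    body_genes: list[GeneModel] = []
    for g in genes:
        body_index.add(GenomicInterval(g.chrom, g.start, g.end, g.strand,
                                       name=str(len(body_genes))))
        body_genes.append(g)
    out: dict[int, str] = {}
    for i, cl in enumerate(weak_clusters):
        state = _state_at(states, bin_size, cl.interval.chrom, cl.dominant_position)
        if state != tss_state_index:
            continue
        cand = {}
        for h in window_index.overlapping(cl.interval):
            g = window_genes[int(h.name)]
            cand[g.gene_id] = g
        for h in body_index.overlapping(cl.interval):
            g = body_genes[int(h.name)]
            cand[g.gene_id] = g
        if not cand:
            continue
        best = min(
            cand.values(),
            key=lambda g: (abs(g.tss - cl.dominant_position), g.gene_id),
        )
        out[i] = best.gene_id
    return out


def annotate(
    clusters: list[TagCluster],
    weak_clusters: list[TagCluster],
    genes: list[GeneModel],
    peaks: dict[str, list[GenomicInterval]],
    states: Optional[dict[str, np.ndarray]] = None,
    tss_state_index: Optional[int] = None,
    config: AnnotationConfig | None = None,
    bin_size: int = 500,
) -> tuple[list[AnnotatedCluster], dict[str, int]]:
    """Run the full decision cascade; every cluster gets exactly one category.

    Precedence: gene assignment first, then intergenic/ELE calling, then
    chromatin-state rescue of the weak pool, then residual labels. Returns
    the annotated clusters plus a category count table that always sums to
    the number of inputs (strong + weak).
    """
    config = config or AnnotationConfig()
    annotated: list[AnnotatedCluster] = []

    gene_hits = assign_gene_tss(clusters, genes, config)
    unassigned = [i for i in range(len(clusters)) if i not in gene_hits]
    intergenic, proximal = find_intergenic(clusters, unassigned, genes, config)
    ele_hits = call_ele_tss(clusters, intergenic, peaks, config)

    for i, cl in enumerate(clusters):
        state = _state_at(states or {}, bin_size, cl.interval.chrom,
                          cl.dominant_position)
        if i in gene_hits:
            annotated.append(AnnotatedCluster(cl, "gene_tss", gene_hits[i],
                                              set(), state))
        elif i in ele_hits:
            annotated.append(AnnotatedCluster(cl, "ele_tss", None,
                                              ele_hits[i], state))
        elif i in set(intergenic):
            annotated.append(AnnotatedCluster(cl, "intergenic_other", None,
                                              set(), state))
        else:
            annotated.append(AnnotatedCluster(cl, "proximal_unclassified",
                                              None, set(), state))

    rescued = {}
    if states is not None and tss_state_index is not None:
        rescued = rescue_lc_gene_tss(weak_clusters, states, tss_state_index,
                                     genes, config, bin_size)
    w_unassigned = [i for i in range(len(weak_clusters)) if i not in rescued]
    w_intergenic, _w_proximal = find_intergenic(weak_clusters, w_unassigned,
                                                genes, config)
    w_intergenic_set = set(w_intergenic)
    for i, cl in enumerate(weak_clusters):
        state = _state_at(states or {}, bin_size, cl.interval.chrom,
                          cl.dominant_position)
        if i in rescued:
            annotated.append(AnnotatedCluster(cl, "lc_gene_tss", rescued[i],
                                              set(), state, weak=True))
        elif i in w_intergenic_set:
            annotated.append(AnnotatedCluster(cl, "intergenic_other", None,
                                              set(), state, weak=True))
        else:
            annotated.append(AnnotatedCluster(cl, "proximal_unclassified",
                                              None, set(), state, weak=True))

    counts = {c: 0 for c in CATEGORIES}
    for a in annotated:
        counts[a.category] += 1
    assert sum(counts.values()) == len(clusters) + len(weak_clusters)
    return annotated, counts
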