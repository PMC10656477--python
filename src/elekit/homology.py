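"""Cross-subgenome homology classification of enhancer-like elements.

Collinear homoeologous gene anchors are chained per chromosome pair with a
longest-increasing-subsequence criterion; the regions between consecutive
anchors are syntenic blocks. For an ELE inside a block, the TSS plus 200 bp
downstream (strand-aware) is locally aligned (affine-gap Smith-Waterman)
against the counterpart block, with significance judged by a Karlin-Altschul
E-value (E <= 0.01 by default). Hits overlapping an active H3K4me3/H3K9ac
peak in the counterpart subgenome are active homologous ELEs; the per-pair
calls combine into subgenome-specific/shared/common categories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

from Bio import Align
from scipy.optimize import brentq

from .intervals import GenomicInterval, IntervalIndex
from .io import GeneModel

HOMOLOGY_CLASSES = (
    "no_syntenic_block", "no_homologous_sequence",
    "homologous_sequence_inactive", "homologous_ele_active",
)

# Karlin-Altschul K for ungapped match/mismatch schemes; used as a documented
# approximation together with the exactly solved lambda.
KA_K = 0.28


@dataclass
class SyntenicBlock:
    pair: tuple[str, str]             # (subgenome_a, subgenome_b)
    interval_a: GenomicInterval
    interval_b: GenomicInterval
    anchor_a: tuple[str, str]         # flanking gene ids in a
    anchor_b: tuple[str, str]


@dataclass
class HomologyCall:
    ele_id: str
    counterpart: str
    klass: str
    hit: Optional[GenomicInterval] = None
    score: Optional[float] = None
    evalue: Optional[float] = None

    def __post_init__(self) -> None:
        if self.klass not in HOMOLOGY_CLASSES:
            raise ValueError(f"unknown homology class {self.klass!r}")
        has_hit = self.klass in ("homologous_sequence_inactive",
                                 "homologous_ele_active")
        if has_hit != (self.hit is not None):
            raise ValueError("hit locus must be set iff a homolog was found")


def subgenome_of(chrom: str) -> str:
    """Default naming convention: the subgenome is the chrom's last letter
    (chr1A -> A)."""
    return chrom[-1]


def collinear_anchors(
    genes: list[GeneModel],
    homoeolog_pairs: list[tuple[str, str]],
    min_chain: int = 3,
) -> list[tuple[str, str]]:
    """Anchor pairs: homoeolog pairs on a chain of >= min_chain pairs whose
    positions increase strictly in both subgenomes (longest increasing
    subsequence per chromosome pair; deterministic tie-break by position)."""
    if not homoeolog_pairs:
        raise ValueError("no homoeolog mapping provided")
    by_id = {g.gene_id: g for g in genes}
    per_chrom_pair: dict[tuple[str, str], list[tuple[int, int, str, str]]] = {}
    for ga, gb in homoeolog_pairs:
        if ga not in by_id or gb not in by_id:
            continue
        a, b = by_id[ga], by_id[gb]
        per_chrom_pair.setdefault((a.chrom, b.chrom), []).append(
            (a.start, b.start, ga, gb)
        )
    anchors: list[tuple[str, str]] = []
    for key in sorted(per_chrom_pair):
        items = sorted(per_chrom_pair[key])
        chain = _lis(items)
        if len(chain) >= min_chain:
            anchors.extend((ga, gb) for _, _, ga, gb in chain)
    return anchors


def _lis(items: list[tuple[int, int, str, str]]):
    """Longest strictly-increasing subsequence in the second coordinate
    (items pre-sorted by the first). O(n^2) DP, earliest-chain tie-break."""
    n = len(items)
    if n == 0:
        return []
    length = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if (items[j][1] < items[i][1] and items[j][0] < items[i][0]
                    and length[j] + 1 > length[i]):
                length[i] = length[j] + 1
                prev[i] = j
    best_end = max(range(n), key=lambda i: (length[i], -i))
    chain = []
    i = best_end
    while i != -1:
        chain.append(items[i])
        i = prev[i]
    return chain[::-1]


def build_blocks(
    anchors: list[tuple[str, str]], genes: list[GeneModel]
) -> list[SyntenicBlock]:
    """One block between each consecutive anchor pair (per chromosome pair);
    block intervals lie strictly between the two anchor genes."""
    by_id = {g.gene_id: g for g in genes}
    per_pair: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for ga, gb in anchors:
        a, b = by_id[ga], by_id[gb]
        per_pair.setdefault((a.chrom, b.chrom), []).append((ga, gb))
    blocks = []
    for (chrom_a, chrom_b), lst in sorted(per_pair.items()):
        lst = sorted(lst, key=lambda p: by_id[p[0]].start)
        for (ga1, gb1), (ga2, gb2) in zip(lst, lst[1:]):
            a1, a2 = by_id[ga1], by_id[ga2]
            b1, b2 = by_id[gb1], by_id[gb2]
            if a1.end >= a2.start or b1.end >= b2.start:
                continue
            blocks.append(SyntenicBlock(
                (subgenome_of(chrom_a), subgenome_of(chrom_b)),
                GenomicInterval(chrom_a, a1.end, a2.start),
                GenomicInterval(chrom_b, b1.end, b2.start),
                (ga1, ga2), (gb1, gb2),
            ))
    return blocks


@lru_cache(maxsize=None)
def karlin_lambda(match: float = 1.0, mismatch: float = -2.0) -> float:
    """Positive root of sum_ij p_i p_j exp(lambda s_ij) = 1 for a uniform
    base background (p=1/4 identity, 3/4 mismatch)."""
    f = lambda lam: 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0
    return float(brentq(f, 1e-6, 10.0))


def evalue(score: float, m: int, n: int, match: float = 1.0,
           mismatch: float = -2.0, k: float = KA_K) -> float:
    """Karlin-Altschul E = K * m * n * exp(-lambda * S)."""
    lam = karlin_lambda(match, mismatch)
    return k * m * n * math.exp(-lam * score)


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def local_alignment_score(query: str, subject: str) -> float:
    """Optimal Smith-Waterman score under the module's scheme (0 if none)."""
    if not query or not subject:
        return 0.0
    return float(_local_aligner().score(query.upper(), subject.upper()))


def find_homolog(
    query: str,
    block_interval: GenomicInterval,
    block_seq: str,
    evalue_max: float = 0.01,
) -> Optional[tuple[GenomicInterval, float, float]]:
    """Best local hit of ``query`` inside a counterpart block.

    Returns (hit locus in genome coordinates, score, E) when E <= evalue_max,
    else None. Ties between co-optimal alignments resolve to the leftmost
    (first traceback)."""
    if not query or not block_seq:
        return None
    aligner = _local_aligner()
    alignments = aligner.align(query.upper(), block_seq.upper())
    try:
        aln = alignments[0]
    except IndexError:
        return None
    score = float(aln.score)
    e = evalue(score, len(query), len(block_seq))
    if e > evalue_max:
        return None
    sub_ranges = aln.aligned[1]
    start = int(sub_ranges[0][0])
    end = int(sub_ranges[-1][1])
    locus = GenomicInterval(
        block_interval.chrom, block_interval.start + start,
        block_interval.start + end,
    )
    return locus, score, e


def classify_homology(
    ele_id: str,
    counterpart: str,
    in_block: bool,
    hit: Optional[tuple[GenomicInterval, float, float]],
    counterpart_peaks: IntervalIndex,
) -> HomologyCall:
    """Combine block membership, alignment hit and counterpart active marks
    into one homology class."""
    if not in_block:
        return HomologyCall(ele_id, counterpart, "no_syntenic_block")
    if hit is None:
        return HomologyCall(ele_id, counterpart, "no_homologous_sequence")
    locus, score, e = hit
    active = bool(counterpart_peaks.overlapping(locus))
    klass = "homologous_ele_active" if active else "homologous_sequence_inactive"
    return HomologyCall(ele_id, counterpart, klass, locus, score, e)


def subgenome_category(
    home: str, calls: dict[str, HomologyCall], subgenomes: list[str]
) -> str:
    """Combine per-counterpart calls: active homolog in neither other
    subgenome -> '<home>_specific'; in exactly one -> 'shared_two'; in all
    others -> 'common'."""
    others = [s for s in subgenomes if s != home]
    missing = [s for s in others if s not in calls]
    if missing:
        raise ValueError(f"missing counterpart calls for {missing}")
    n_active = sum(
        1 for s in others if calls[s].klass == "homologous_ele_active"
    )
    if n_active == 0:
        return f"{home}_specific"
    if n_active == len(others):
        return "common"
    return "shared_two"


def classify_eles(
    eles: list[tuple[str, str, int, str]],
    genes: list[GeneModel],
    homoeolog_pairs: list[tuple[str, str]],
    sequences: dict[str, str],
    peaks_by_subgenome: dict[str, list[GenomicInterval]],
    subgenomes: list[str],
    query_downstream: int = 200,
    evalue_max: float = 0.01,
    min_chain: int = 3,
) -> tuple[dict[str, dict[str, HomologyCall]], dict[str, str]]:
    """Full homology stage for ELEs given as (ele_id, chrom, tss, strand).

    Returns per-ELE per-counterpart calls and the overall subgenome category.
    """
    anchors = collinear_anchors(genes, homoeolog_pairs, min_chain)
    blocks = build_blocks(anchors, genes)
    block_index: dict[tuple[str, str], list[SyntenicBlock]] = {}
    for blk in blocks:
        block_index.setdefault(blk.pair, []).append(blk)
        # also register the reversed orientation
        rev = SyntenicBlock(
            (blk.pair[1], blk.pair[0]), blk.interval_b, blk.interval_a,
            blk.anchor_b, blk.anchor_a,
        )
        block_index.setdefault(rev.pair, []).append(rev)
    peak_indexes = {
        s: IntervalIndex(pk) for s, pk in peaks_by_subgenome.items()
    }
    calls: dict[str, dict[str, HomologyCall]] = {}
    categories: dict[str, str] = {}
    for eid, chrom, tss, strand in eles:
        home = subgenome_of(chrom)
        seq = sequences[chrom]
        if strand == "-":
            start = max(0, tss - query_downstream)
            query = _revcomp(seq[start:tss + 1])
        else:
            query = seq[tss:tss + query_downstream + 1]
        calls[eid] = {}
        for other in subgenomes:
            if other == home:
                continue
            blk = _containing_block(block_index.get((home, other), []), chrom, tss)
            if blk is None:
                calls[eid][other] = HomologyCall(eid, other, "no_syntenic_block")
                continue
            block_seq = sequences[blk.interval_b.chrom][
                blk.interval_b.start:blk.interval_b.end
            ]
            hit = find_homolog(query, blk.interval_b, block_seq, evalue_max)
            calls[eid][other] = classify_homology(
                eid, other, True, hit,
                peak_indexes.get(other, IntervalIndex()),
            )
        categories[eid] = subgenome_category(home, calls[eid], subgenomes)
    return calls, categories


def _containing_block(blocks: list[SyntenicBlock], chrom: str, pos: int):
    for blk in blocks:
        if blk.interval_a.chrom == chrom and blk.interval_a.contains_point(pos):
            return blk
    return None


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp.get(b, "N") for b in reversed(seq.upper()))
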