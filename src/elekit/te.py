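"""TE-embedded ELE assignment and enrichment statistics.

An ELE is TE-embedded when its dominant position lies inside an annotated TE
(innermost element wins for nested TEs). Family/subfamily enrichment of
ELE-bearing TE copies uses a two-tailed Fisher's exact test with the whole
TE complement of the genome as background; tissue-bias enrichment contrasts
each TE group against all ELEs. Raw p-values and Benjamini-Hochberg adjusted
q-values are both reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from statsmodels.stats.multitest import multipletests

from .io import TeAnnotation


@dataclass
class EnrichmentResult:
    group: str
    table: tuple[int, int, int, int]  # (a, b, c, d)
    odds_ratio: Optional[float]       # None when 0/0; inf when x/0
    p_value: float
    q_value: Optional[float] = None


def assign_te(
    eles: list[tuple[str, str, int]], tes: list[TeAnnotation]
) -> dict[str, TeAnnotation]:
    """Map ele_id -> host TE for ELEs whose dominant position is inside a TE.

    ``eles`` are (ele_id, chrom, dominant_position). When nested TEs both
    contain the point, the shortest (innermost) element is assigned; residual
    ties break by te_id.
    """
    by_chrom: dict[str, list[TeAnnotation]] = {}
    for te in tes:
        by_chrom.setdefault(te.interval.chrom, []).append(te)
    out: dict[str, TeAnnotation] = {}
    for eid, chrom, pos in eles:
        hits = [
            te for te in by_chrom.get(chrom, [])
            if te.interval.contains_point(pos)
        ]
        if hits:
            out[eid] = min(hits, key=lambda te: (len(te.interval), te.te_id))
    return out


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[Optional[float], float]:
    """Two-tailed Fisher's exact test on [[a, b], [c, d]].

    p sums the hypergeometric probabilities of all tables with the observed
    margins whose point probability does not exceed the observed table's
    (ties compared exactly in integer arithmetic, so the conventional
    "p <= p_obs" rule is honored without floating-point ambiguity).
    Odds ratio ad/bc; 0/0 -> None, x/0 -> +inf.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    num, den = a * d, b * c
    if den == 0:
        odds = None if num == 0 else math.inf
    else:
        odds = num / den
    if n == 0:
        return None, 1.0
    r1, r2, c1 = a + b, c + d, a + c
    # weight(x) = C(r1, x) * C(r2, c1 - x), exact; p-values share the
    # denominator C(n, c1), so tie comparison reduces to integer weights.
    lo, hi = max(0, c1 - r2), min(r1, c1)
    w_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = math.comb(n, c1)
    tail = sum(
        w for x in range(lo, hi + 1)
        if (w := math.comb(r1, x) * math.comb(r2, c1 - x)) <= w_obs
    )
    return odds, tail / total


def _bh(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    if not results:
        return results
    qs = multipletests([r.p_value for r in results], method="fdr_bh")[1]
    for r, q in zip(results, qs):
        r.q_value = float(q)
    return results


def family_enrichment(
    ele_hosts: dict[str, TeAnnotation],
    tes: list[TeAnnotation],
    level: str = "subfamily",
) -> list[EnrichmentResult]:
    """Enrichment of ELE-bearing TE copies per family/subfamily vs the genome.

    The 2x2 per group is (ELE-bearing, non-bearing) x (group, all other TEs);
    the whole genome's TE complement is the background. Results are sorted by
    (q, p, group) so the top-ranked group is first.
    """
    if level not in ("family", "subfamily", "superfamily"):
        raise ValueError(f"unknown level {level!r}")
    key = lambda te: getattr(te, level)
    bearing_ids = {te.te_id for te in ele_hosts.values()}
    groups = sorted({key(te) for te in tes})
    results = []
    for g in groups:
        in_group = [te for te in tes if key(te) == g]
        out_group_n = len(tes) - len(in_group)
        a = sum(1 for te in in_group if te.te_id in bearing_ids)
        b = len(in_group) - a
        c = len(bearing_ids) - a
        d = out_group_n - c
        odds, p = fisher_exact_2x2(a, b, c, d)
        results.append(EnrichmentResult(g, (a, b, c, d), odds, p))
    results = _bh(results)
    results.sort(key=lambda r: (r.q_value, r.p_value,
                                -(r.odds_ratio if r.odds_ratio not in (None,)
                                  and not math.isinf(r.odds_ratio)
                                  else 1e18), r.group))
    return results


def tissue_enrichment(
    ele_group: dict[str, str],
    ele_tissue_label: dict[str, str],
    tissues: list[str],
) -> list[EnrichmentResult]:
    """Per (TE group, tissue) enrichment of tissue-specific ELEs.

    ``ele_group`` maps ele_id -> TE group (or absent for non-TE ELEs);
    ``ele_tissue_label`` maps ele_id -> specificity label from the tau
    classifier. Background = all labeled ELEs. Fisher two-tailed + BH.
    """
    all_eles = sorted(ele_tissue_label)
    groups = sorted(set(ele_group.values()))
    results = []
    for g in groups:
        for t in tissues:
            target = f"specific-to-{t}"
            a = sum(1 for e in all_eles
                    if ele_group.get(e) == g and ele_tissue_label[e] == target)
            b = sum(1 for e in all_eles
                    if ele_group.get(e) == g and ele_tissue_label[e] != target)
            c = sum(1 for e in all_eles
                    if ele_group.get(e) != g and ele_tissue_label[e] == target)
            d = len(all_eles) - a - b - c
            odds, p = fisher_exact_2x2(a, b, c, d)
            results.append(EnrichmentResult(f"{g}|{t}", (a, b, c, d), odds, p))
    results = _bh(results)
    results.sort(key=lambda r: (r.q_value, r.p_value, r.group))
    return results
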