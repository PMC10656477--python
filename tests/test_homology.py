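"""Collinearity chaining, syntenic blocks, homolog search, categories."""

import numpy as np
import pytest

from elekit.homology import (HomologyCall, build_blocks, classify_homology,
                             collinear_anchors, evalue, find_homolog,
                             karlin_lambda, local_alignment_score,
                             subgenome_category)
from elekit.intervals import GenomicInterval, IntervalIndex
from elekit.io import GeneModel


def gene(gene_id, chrom, start):
    return GeneModel(gene_id, chrom, start, start + 1000, "+",
                     [GenomicInterval(chrom, start, start + 1000, "+")], [])


def collinear_set(n=10, inverted=None):
    genes, pairs = [], []
    for i in range(n):
        ga = gene(f"a{i}", "chr1A", 10_000 * (i + 1))
        pos_b = 10_000 * (i + 1)
        if inverted is not None and i == inverted:
            pos_b = 10_000 * (n + 5)  # breaks the increasing order
        gb = gene(f"b{i}", "chr1B", pos_b)
        genes += [ga, gb]
        pairs.append((f"a{i}", f"b{i}"))
    return genes, pairs


class TestCollinearAnchors:
    def test_perfectly_collinear_all_retained(self):
        genes, pairs = collinear_set(10)
        assert len(collinear_anchors(genes, pairs)) == 10

    def test_inverted_gene_dropped_from_chain(self):
        genes, pairs = collinear_set(10, inverted=4)
        anchors = collinear_anchors(genes, pairs)
        assert len(anchors) == 9
        assert ("a4", "b4") not in anchors

    def test_no_chain_of_three(self):
        genes, pairs = collinear_set(4)
        # scramble positions in B so no increasing subsequence of length 3
        order = [3, 2, 1, 0]
        for i, g in enumerate(g for g in genes if g.chrom == "chr1B"):
            g.start = 10_000 * (order[i] + 1)
            g.end = g.start + 1000
        assert collinear_anchors(genes, pairs, min_chain=3) == []

    def test_missing_mapping_rejected(self):
        with pytest.raises(ValueError):
            collinear_anchors([], [])


class TestBuildBlocks:
    def test_fencepost(self):
        genes, pairs = collinear_set(10)
        anchors = collinear_anchors(genes, pairs)
        blocks = build_blocks(anchors, genes)
        assert len(blocks) == 9
        for blk in blocks:
            assert blk.interval_a.start >= 11_000  # strictly between genes

    def test_empty_anchors(self):
        assert build_blocks([], []) == []


MATCH, MISMATCH, OPEN, EXTEND = 1, -2, -5, -1


def oracle_local_score(a, b):
    """Iterative Smith-Waterman/Gotoh with the same gap convention (first
    gap position costs OPEN, subsequent EXTEND)."""
    NEG = -1e9
    la, lb = len(a), len(b)
    H = np.full((la + 1, lb + 1), NEG)
    E = np.full((la + 1, lb + 1), NEG)  # gap consuming b
    F = np.full((la + 1, lb + 1), NEG)  # gap consuming a
    best = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            H[i, j] = s + max(0.0, H[i - 1, j - 1], E[i - 1, j - 1],
                              F[i - 1, j - 1])
            E[i, j] = max(H[i, j - 1] + OPEN, E[i, j - 1] + EXTEND,
                          F[i, j - 1] + OPEN)
            F[i, j] = max(H[i - 1, j] + OPEN, F[i - 1, j] + EXTEND,
                          E[i - 1, j] + OPEN)
            best = max(best, H[i, j])
    return best


class TestFindHomolog:
    def test_exact_copy_is_significant_hit(self, rng):
        block_seq = "".join(rng.choice(list("ACGT"), size=3000))
        query = block_seq[1200:1401]
        block = GenomicInterval("chr1B", 50_000, 53_000)
        hit = find_homolog(query, block, block_seq)
        assert hit is not None
        locus, score, e = hit
        assert score == len(query)
        assert e < 1e-10
        assert locus.start == 50_000 + 1200 and locus.end == 50_000 + 1401

    def test_random_query_false_hit_rate_below_5pct(self, rng):
        hits = 0
        n = 100
        for _ in range(n):
            block_seq = "".join(rng.choice(list("ACGT"), size=2000))
            query = "".join(rng.choice(list("ACGT"), size=201))
            block = GenomicInterval("chr1B", 0, 2000)
            if find_homolog(query, block, block_seq) is not None:
                hits += 1
        assert hits / n < 0.05

    def test_local_score_matches_enumeration(self, rng):
        for _ in range(30):
            la, lb = rng.integers(1, 13, size=2)
            a = "".join(rng.choice(list("ACGT"), size=la))
            b = "".join(rng.choice(list("ACGT"), size=lb))
            assert local_alignment_score(a, b) == oracle_local_score(a, b)

    def test_karlin_lambda_solves_identity(self):
        lam = karlin_lambda()
        assert 0.25 * np.exp(lam) + 0.75 * np.exp(-2 * lam) == pytest.approx(
            1.0, abs=1e-9
        )
        assert evalue(20, 201, 2000) < evalue(10, 201, 2000)


class TestClassify:
    PEAK = IntervalIndex([GenomicInterval("chr1B", 100, 400)])
    EMPTY = IntervalIndex()

    def test_active_homolog(self):
        hit = (GenomicInterval("chr1B", 150, 350), 201.0, 1e-50)
        call = classify_homology("e1", "B", True, hit, self.PEAK)
        assert call.klass == "homologous_ele_active"

    def test_inactive_homolog(self):
        hit = (GenomicInterval("chr1B", 1_000, 1_200), 201.0, 1e-50)
        call = classify_homology("e1", "B", True, hit, self.PEAK)
        assert call.klass == "homologous_sequence_inactive"

    def test_no_block_and_no_hit(self):
        assert classify_homology("e1", "B", False, None,
                                 self.EMPTY).klass == "no_syntenic_block"
        assert classify_homology("e1", "B", True, None,
                                 self.EMPTY).klass == "no_homologous_sequence"

    def test_hit_locus_consistency_enforced(self):
        with pytest.raises(ValueError):
            HomologyCall("e1", "B", "homologous_ele_active", None)


class TestSubgenomeCategory:
    def _call(self, klass):
        hit = (GenomicInterval("chr1B", 0, 10)
               if klass.startswith("homologous_") else None)
        return HomologyCall("e", "x", klass,
                            hit if klass in ("homologous_ele_active",
                                             "homologous_sequence_inactive")
                            else None)

    def test_rules(self):
        subs = ["A", "B", "D"]
        inactive = self._call("no_homologous_sequence")
        active = self._call("homologous_ele_active")
        assert subgenome_category("A", {"B": inactive, "D": inactive},
                                  subs) == "A_specific"
        assert subgenome_category("A", {"B": active, "D": inactive},
                                  subs) == "shared_two"
        assert subgenome_category("A", {"B": active, "D": active},
                                  subs) == "common"

    def test_missing_counterpart_rejected(self):
        with pytest.raises(ValueError):
            subgenome_category("A", {}, ["A", "B", "D"])


def test_reciprocal_hit_on_exact_copies(rng):
    """If the counterpart block holds an exact copy, the hit found there
    aligns back to the source block (reciprocality)."""
    block_a = "".join(rng.choice(list("ACGT"), size=2000))
    core = block_a[800:1001]
    block_b = ("".join(rng.choice(list("ACGT"), size=700)) + core
               + "".join(rng.choice(list("ACGT"), size=700)))
    iv_a = GenomicInterval("chr1A", 10_000, 12_000)
    iv_b = GenomicInterval("chr1B", 20_000, 20_000 + len(block_b))
    fwd = find_homolog(core, iv_b, block_b)
    assert fwd is not None
    locus, _, _ = fwd
    found = block_b[locus.start - 20_000:locus.end - 20_000]
    back = find_homolog(found, iv_a, block_a)
    assert back is not None
    assert back[0].start == 10_800 and back[0].end == 11_001


def test_expanded_subfamily_eles_called_home_specific(pipeline_state):
    """>= 80% of ELEs hosted by the A-expanded subfamily classify as
    A-subgenome-specific."""
    state = pipeline_state
    bias = next(iter(state.config.sim.ele_tissue_bias))
    hosted = [eid for eid, te in state.ele_hosts.items()
              if te.subfamily == bias]
    assert hosted
    frac = np.mean([
        state.homology_categories[eid] == "A_specific" for eid in hosted
    ])
    assert frac >= 0.8


def test_specific_eles_more_tissue_restricted_than_common(pipeline_state):
    """Planted association: subgenome-specific ELEs are enriched among
    tissue-specific ELEs relative to subgenome-common ELEs."""
    from elekit.te import fisher_exact_2x2

    state = pipeline_state
    a = b = c = d = 0
    for eid, cat in state.homology_categories.items():
        label = state.ele_tissue_labels.get(eid, "")
        specific = label.startswith("specific-to-")
        if cat.endswith("_specific"):
            a, b = (a + 1, b) if specific else (a, b + 1)
        elif cat == "common":
            c, d = (c + 1, d) if specific else (c, d + 1)
    odds, p = fisher_exact_2x2(a, b, c, d)
    assert p < 0.05
    assert odds is None or odds > 1
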