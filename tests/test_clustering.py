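"""Tag-cluster calling: distance clustering, replicate support, merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from elekit.clustering import (ClusterParams, cluster_positions,
                               filter_reproducible, merge_tissues,
                               normalize_rpm, shape_class)
from elekit.io import CtssTable


def make_table(rows, samples):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", *samples])
    return CtssTable(df)


class TestNormalizeRpm:
    def test_direct_normalization(self):
        t = make_table([["c", 1, "+", 10], ["c", 2, "+", 30]], ["x_rep1"])
        rpm = normalize_rpm(t)
        assert rpm["x_rep1"].tolist() == [250000.0, 750000.0]
        assert rpm["x_rep1"].sum() == pytest.approx(1e6, rel=1e-6)

    def test_single_position(self):
        t = make_table([["c", 1, "+", 1]], ["x_rep1"])
        assert normalize_rpm(t)["x_rep1"].tolist() == [1e6]

    def test_zero_total_names_sample(self):
        t = make_table([["c", 1, "+", 1, 0]], ["x_rep1", "x_rep2"])
        with pytest.raises(ValueError, match="x_rep2"):
            normalize_rpm(t)


class TestClusterPositions:
    PARAMS = ClusterParams(max_dist=20, ctss_rpm_threshold=0.5)

    def test_split_beyond_max_dist(self):
        out = cluster_positions(np.array([100, 105, 130]),
                                np.array([1.0, 1.0, 1.0]), self.PARAMS)
        assert [(s, e) for s, e, _ in out] == [(100, 106), (130, 131)]

    def test_chaining_at_boundary(self):
        out = cluster_positions(np.array([100, 120, 140]),
                                np.array([1.0, 1.0, 1.0]), self.PARAMS)
        assert [(s, e) for s, e, _ in out] == [(100, 141)]

    def test_subthreshold_never_joins(self):
        out = cluster_positions(np.array([100, 110, 120]),
                                np.array([1.0, 0.4, 1.0]), self.PARAMS)
        assert [(s, e) for s, e, _ in out] == [(100, 121)]
        out2 = cluster_positions(np.array([100]), np.array([0.4]), self.PARAMS)
        assert out2 == []

    @given(st.lists(st.tuples(st.integers(0, 400), st.floats(0, 3)),
                    max_size=120))
    def test_matches_transitive_closure_oracle(self, items):
        positions = np.array(sorted({p for p, _ in items}))
        vals = {p: 0.0 for p in positions}
        for p, v in items:
            vals[p] = max(vals[p], v)
        values = np.array([vals[p] for p in positions])
        params = ClusterParams(max_dist=15, ctss_rpm_threshold=0.5)
        got = cluster_positions(positions, values, params)
        # oracle: union-find over retained positions within max_dist
        kept = [int(p) for p, v in zip(positions, values) if v >= 0.5]
        parent = {p: p for p in kept}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, p in enumerate(kept):
            for q in kept[i + 1:]:
                if abs(p - q) <= 15:
                    parent[find(p)] = find(q)
        groups = {}
        for p in kept:
            groups.setdefault(find(p), []).append(p)
        expected = sorted((min(g), max(g) + 1) for g in groups.values())
        assert [(s, e) for s, e, _ in got] == expected
        # partition: every retained position in exactly one cluster
        members = [p for _, _, run in got for p in run]
        assert sorted(members) == sorted(kept)


class TestFilterReproducible:
    def test_support_rules(self):
        positions = np.array([100, 105])
        clusters = [(100, 106, positions)]
        params = ClusterParams(min_supporting_samples=2)
        both = np.array([[1.0, 1.0], [0.0, 0.6]])
        assert filter_reproducible(clusters, positions, both, params) == [
            ((100, 106, positions), 2)
        ]
        one_of_three = np.array([[1.0, 0.0, 0.0], [0.8, 0.0, 0.0]])
        assert filter_reproducible(clusters, positions, one_of_three, params) == []

    def test_disabled_filter_keeps_all(self):
        positions = np.array([100])
        clusters = [(100, 101, positions)]
        params = ClusterParams(min_supporting_samples=1)
        only_one = np.array([[1.0, 0.0]])
        assert len(filter_reproducible(clusters, positions, only_one, params)) == 1


class TestMergeTissues:
    def _rpm(self):
        t = make_table(
            [["c", p, "+", a, a, b, b] for p, a, b in
             [(100, 5, 0), (105, 5, 5), (110, 0, 5), (119, 0, 5)]],
            ["spike_rep1", "spike_rep2", "root_rep1", "root_rep2"],
        )
        return normalize_rpm(t)

    def test_union_merge_across_tissues(self):
        rpm = self._rpm()
        spike = [{"chrom": "c", "strand": "+", "start": 100, "end": 110,
                  "tissue": "spike", "n_support": 2}]
        root = [{"chrom": "c", "strand": "+", "start": 105, "end": 120,
                 "tissue": "root", "n_support": 2}]
        merged = merge_tissues([spike, root], rpm, ClusterParams())
        assert len(merged) == 1
        assert (merged[0].interval.start, merged[0].interval.end) == (100, 120)

    def test_strand_separation(self):
        t = make_table([["c", 100, "+", 5, 5], ["c", 100, "-", 5, 5]],
                       ["spike_rep1", "spike_rep2"])
        rpm = normalize_rpm(t)
        plus = [{"chrom": "c", "strand": "+", "start": 100, "end": 101,
                 "tissue": "spike", "n_support": 2}]
        minus = [{"chrom": "c", "strand": "-", "start": 100, "end": 101,
                  "tissue": "spike", "n_support": 2}]
        assert len(merge_tissues([plus, minus], rpm, ClusterParams())) == 2

    def test_idempotent_and_order_invariant(self):
        rpm = self._rpm()
        spike = [{"chrom": "c", "strand": "+", "start": 100, "end": 110,
                  "tissue": "spike", "n_support": 2}]
        root = [{"chrom": "c", "strand": "+", "start": 105, "end": 120,
                 "tissue": "root", "n_support": 2}]
        a = merge_tissues([spike, root], rpm, ClusterParams())
        b = merge_tissues([root, spike], rpm, ClusterParams())
        assert [(c.interval, c.dominant_position, c.per_tissue_rpm)
                for c in a] == \
               [(c.interval, c.dominant_position, c.per_tissue_rpm)
                for c in b]
        again = merge_tissues(
            [[{"chrom": c.interval.chrom, "strand": c.interval.strand,
               "start": c.interval.start, "end": c.interval.end,
               "tissue": "merged", "n_support": c.n_supporting_samples}
              for c in a]], rpm, ClusterParams())
        assert [(c.interval.start, c.interval.end) for c in again] == \
               [(c.interval.start, c.interval.end) for c in a]


@pytest.mark.parametrize("width, expected", [
    (10, "sharp"), (11, "broad"), (1, "sharp"), (60, "broad"),
])
def test_broad_rule_strict_at_10bp(width, expected):
    assert shape_class(width) == expected


def test_planted_features_recovered_as_clusters(pipeline_state):
    """Planted gene TSSs and ELEs with strong signal each sit inside a
    called cluster interval (>= 95%)."""
    state = pipeline_state
    spans = {}
    for cl in state.clusters:
        spans.setdefault((cl.interval.chrom, cl.interval.strand), []).append(
            (cl.interval.start, cl.interval.end)
        )

    def covered(chrom, pos, strand):
        return any(s <= pos < e for s, e in spans.get((chrom, strand), []))

    anchors = []
    for pg in state.truth.genes:
        if not pg.weak:
            anchors.append((pg.chrom, pg.tss, pg.strand))
    for ele in state.truth.eles:
        anchors.append((ele.interval.chrom, ele.interval.start, "+"))
    hit = sum(covered(*a) for a in anchors)
    assert hit / len(anchors) >= 0.95
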