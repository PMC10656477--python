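"""CAGE tag-cluster calling.

Per-position CTSS counts are normalized to reads-per-million (RPM),
aggregated into distance-based tag clusters per tissue, filtered for
replicate support (a cluster must contain retained signal from at least two
samples of the tissue), merged across tissues into a unified cluster set
with a tissue x cluster expression matrix, and classified as sharp or broad
(broad = wider than 10 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .io import CtssTable, parse_sample_id


@dataclass
class ClusterParams:
    max_dist: int = 20                  # bp between consecutive retained CTSSs
    ctss_rpm_threshold: float = 0.5     # RPM floor for a CTSS to seed/join
    min_supporting_samples: int = 2     # replicate-support filter

    def __post_init__(self) -> None:
        if self.max_dist < 0:
            raise ValueError("max_dist must be >= 0")
        if self.ctss_rpm_threshold < 0 or self.min_supporting_samples < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class TagCluster:
    """A contiguous stranded run of CAGE signal (one candidate TSS)."""

    interval: GenomicInterval
    dominant_position: int
    per_sample_rpm: dict[str, float]
    per_tissue_rpm: dict[str, float]
    n_supporting_samples: int
    positions: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        if not self.interval.contains_point(self.dominant_position):
            raise ValueError("dominant_position outside cluster interval")

    @property
    def width(self) -> int:
        return len(self.interval)

    @property
    def shape(self) -> str:
        return shape_class(self.width)


def shape_class(width: int) -> str:
    """Sharp/broad call: clusters longer than 10 bp are broad (strict)."""
    return "broad" if width > 10 else "sharp"


def normalize_rpm(ctss: CtssTable) -> pd.DataFrame:
    """Per-sample RPM columns alongside chrom/pos/strand.

    Each sample column sums to 1e6 (up to float tolerance). A zero-total
    sample is an error naming the sample.
    """
    df = ctss.df.copy()
    for sample in ctss.samples:
        total = df[sample].sum()
        if total <= 0:
            raise ValueError(f"sample {sample!r} has zero total count")
        df[sample] = df[sample] * (1e6 / total)
    return df


def cluster_positions(
    positions: np.ndarray, values: np.ndarray, params: ClusterParams
) -> list[tuple[int, int, np.ndarray]]:
    """Distance-cluster retained positions on one chrom/strand.

    Positions with ``value >= ctss_rpm_threshold`` are partitioned into
    maximal runs in which consecutive retained positions are at most
    ``max_dist`` bp apart; each cluster spans first..last retained position
    (+1, half-open). Sub-threshold positions never seed or join clusters.

    Returns (start, end, member_positions) triples.
    """
    positions = np.asarray(positions)
    values = np.asarray(values, dtype=float)
    if positions.size and np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    keep = positions[values >= params.ctss_rpm_threshold]
    if keep.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(keep) > params.max_dist) + 1
    out = []
    for run in np.split(keep, breaks):
        out.append((int(run[0]), int(run[-1]) + 1, run))
    return out


def _rpm_matrix(rpm: pd.DataFrame, samples: list[str]):
    """Group normalized table by (chrom, strand) into sorted position arrays."""
    groups = {}
    for (chrom, strand), sub in rpm.groupby(["chrom", "strand"], sort=True):
        sub = sub.sort_values("pos", kind="mergesort")
        groups[(chrom, strand)] = (
            sub["pos"].to_numpy(),
            sub[samples].to_numpy(dtype=float),
        )
    return groups


def filter_reproducible(
    pooled_clusters: list[tuple[int, int, np.ndarray]],
    positions: np.ndarray,
    replicate_rpm: np.ndarray,
    params: ClusterParams,
) -> list[tuple[tuple[int, int, np.ndarray], int]]:
    """Keep tissue clusters with retained CTSS signal in enough replicates.

    A replicate supports a cluster when it contributes at least one position
    inside the pooled cluster interval at or above the RPM threshold. Returns
    (cluster, n_supporting_samples) for retained clusters.
    """
    out = []
    for start, end, members in pooled_clusters:
        inside = (positions >= start) & (positions < end)
        support = int(
            np.sum((replicate_rpm[inside] >= params.ctss_rpm_threshold).any(axis=0))
        )
        if support >= params.min_supporting_samples:
            out.append(((start, end, members), support))
    return out


def cluster_tissue(
    rpm: pd.DataFrame, tissue: str, samples: list[str], params: ClusterParams
) -> list[dict]:
    """Call reproducible clusters for one tissue from the normalized table.

    Clustering runs on the pooled tissue signal (mean replicate RPM); the
    replicate-support filter is then applied at CTSS-overlap level.
    """
    tissue_samples = [s for s in samples if parse_sample_id(s)[0] == tissue]
    groups = _rpm_matrix(rpm, tissue_samples)
    clusters = []
    for (chrom, strand), (positions, mat) in groups.items():
        pooled = mat.mean(axis=1)
        called = cluster_positions(positions, pooled, params)
        for (start, end, members), support in filter_reproducible(
            called, positions, mat, params
        ):
            clusters.append(
                {"chrom": chrom, "strand": strand, "start": start, "end": end,
                 "tissue": tissue, "n_support": support}
            )
    return clusters


def merge_tissues(
    tissue_clusters: list[list[dict]], rpm: pd.DataFrame, params: ClusterParams
) -> list[TagCluster]:
    """Merge per-tissue cluster sets into one unified TSS set.

    Same-strand clusters overlapping by >=1 bp across tissues merge into the
    union interval; per-tissue RPM is the summed pooled RPM of member CTSS
    positions, and the dominant position is recomputed from the all-sample
    pooled signal. Idempotent and invariant to tissue input order.
    """
    flat = sorted(
        (c for tc in tissue_clusters for c in tc),
        key=lambda c: (c["chrom"], c["strand"], c["start"], c["end"]),
    )
    merged: list[dict] = []
    for c in flat:
        last = merged[-1] if merged else None
        if (
            last
            and last["chrom"] == c["chrom"]
            and last["strand"] == c["strand"]
            and c["start"] < last["end"]
        ):
            last["end"] = max(last["end"], c["end"])
            last["n_support"] = max(last["n_support"], c["n_support"])
        else:
            merged.append(dict(c))

    samples = [s for s in rpm.columns if s not in ("chrom", "pos", "strand")]
    tissues = []
    for s in samples:
        t = parse_sample_id(s)[0]
        if t not in tissues:
            tissues.append(t)
    groups = _rpm_matrix(rpm, samples)
    out: list[TagCluster] = []
    for c in merged:
        positions, mat = groups[(c["chrom"], c["strand"])]
        inside = (positions >= c["start"]) & (positions < c["end"])
        sub_pos = positions[inside]
        sub = mat[inside]
        pooled = sub.sum(axis=1)
        dominant = int(sub_pos[int(np.argmax(pooled))]) if sub_pos.size else c["start"]
        per_sample = {s: float(sub[:, j].sum()) for j, s in enumerate(samples)}
        per_tissue = {}
        for t in tissues:
            idx = [j for j, s in enumerate(samples) if parse_sample_id(s)[0] == t]
            per_tissue[t] = float(sub[:, idx].mean(axis=1).sum()) if sub.size else 0.0
        n_support = int(
            np.sum((sub >= params.ctss_rpm_threshold).any(axis=0))
        ) if sub.size else 0
        out.append(
            TagCluster(
                GenomicInterval(c["chrom"], c["start"], c["end"], c["strand"]),
                dominant, per_sample, per_tissue, max(n_support, c["n_support"]),
                sub_pos,
            )
        )
    out.sort(key=lambda cl: (cl.interval.chrom, cl.interval.start,
                             cl.interval.end, cl.interval.strand))
    return out


def call_clusters(
    ctss: CtssTable, params: ClusterParams | None = None
) -> tuple[list[TagCluster], list[TagCluster]]:
    """Full clustering stage: (reproducible clusters, weak-cluster pool).

    The weak pool holds pooled clusters that failed the replicate-support
    filter or were built only from sub-threshold signal; they are candidates
    for chromatin-state rescue downstream.
    """
    params = params or ClusterParams()
    rpm = normalize_rpm(ctss)
    samples = ctss.samples
    per_tissue = [cluster_tissue(rpm, t, samples, params) for t in ctss.tissues]
    strong = merge_tissues(per_tissue, rpm, params)

    # Weak pool: cluster every nonzero pooled position with the same distance
    # rule but no RPM floor, then drop anything overlapping a strong cluster.
    weak_params = ClusterParams(params.max_dist, 0.0, 0)
    eps = np.finfo(float).tiny
    groups = _rpm_matrix(rpm, samples)
    weak_raw = []
    for (chrom, strand), (positions, mat) in groups.items():
        pooled = mat.mean(axis=1)
        nz = pooled > 0
        for start, end, members in cluster_positions(
            positions[nz], np.maximum(pooled[nz], eps), weak_params
        ):
            weak_raw.append(
                {"chrom": chrom, "strand": strand, "start": start, "end": end,
                 "tissue": "_pooled", "n_support": 0}
            )
    strong_keys = {}
    for cl in strong:
        strong_keys.setdefault((cl.interval.chrom, cl.interval.strand), []).append(
            (cl.interval.start, cl.interval.end)
        )
    weak_kept = []
    for c in weak_raw:
        spans = strong_keys.get((c["chrom"], c["strand"]), [])
        if any(c["start"] < e and s < c["end"] for s, e in spans):
            continue
        weak_kept.append(c)
    weak = merge_tissues([weak_kept], rpm, params) if weak_kept else []
    return strong, weak


def expression_matrix(clusters: list[TagCluster]) -> pd.DataFrame:
    """Tissue x cluster mean-RPM matrix (clusters as rows)."""
    if not clusters:
        return pd.DataFrame()
    tissues = list(clusters[0].per_tissue_rpm)
    rows = [[cl.per_tissue_rpm[t] for t in tissues] for cl in clusters]
    index = [
        f"{cl.interval.chrom}:{cl.interval.start}-{cl.interval.end}({cl.interval.strand})"
        for cl in clusters
    ]
    return pd.DataFrame(rows, index=index, columns=tissues)
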