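"""End-to-end orchestration: simulate -> cluster -> segment -> annotate ->
link -> te-enrich -> ltr-age -> motif-compare -> homology, with a flat
key=value config, per-stage outputs and a machine-readable summary.

Every stage is a plain function over in-memory objects; :func:`run_all`
wires them together on a run directory and writes each stage's outputs
before the next starts, so a failure aborts with the stage name while
earlier outputs survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import clustering as clu
from . import evaluate as ev
from . import hmm as chmm
from . import homology as hom
from . import linking as lnk
from . import ltr as ltrmod
from . import motifs as mot
from . import simulate as sim
from . import te as temod
from .intervals import GenomicInterval
from .io import write_bed

log = logging.getLogger("elekit")


@dataclass
class RunConfig:
    outdir: str = "run"
    seed: int = 0
    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    cluster: clu.ClusterParams = field(default_factory=clu.ClusterParams)
    annotation: ann.AnnotationConfig = field(default_factory=ann.AnnotationConfig)
    rp: lnk.RpParams = field(default_factory=lnk.RpParams)
    n_states: int = 15
    hmm_restarts: int = 3
    hmm_max_iter: int = 100
    tau_min: float = 0.8
    log_level: str = "INFO"


def validate_config(config: RunConfig) -> list[str]:
    """All invariant breaches across parameter blocks (empty when valid)."""
    problems = []
    for block, name in ((config.sim, "sim"), (config.cluster, "cluster"),
                        (config.annotation, "annotation"), (config.rp, "rp")):
        try:
            block.__post_init__()
        except ValueError as exc:
            problems.append(f"{name}: {exc}")
    if config.n_states < 2:
        problems.append("hmm: n_states must be >= 2")
    if not (0 <= config.tau_min <= 1):
        problems.append("tau_min must lie in [0,1]")
    return problems


# -- flat key=value config files -------------------------------------------

_SECTIONS = {"sim": sim.SimConfig, "cluster": clu.ClusterParams,
             "annotation": ann.AnnotationConfig, "rp": lnk.RpParams}


def _coerce(value: str, current):
    if isinstance(current, bool):
        return value.lower() in ("1", "true", "yes")
    if isinstance(current, int):
        return int(value)
    if isinstance(current, float):
        return float(value)
    if isinstance(current, (tuple, list)):
        items = [v.strip() for v in value.split(",") if v.strip()]
        if current and isinstance(current[0], (int, float)):
            typ = type(current[0])
            return tuple(typ(v) for v in items)
        return tuple(items)
    if isinstance(current, dict):
        out = {}
        for entry in value.split(";"):
            entry = entry.strip()
            if not entry:
                continue
            k, _, v = entry.partition("=")
            vals = [x.strip() for x in v.split(",")]
            if all(x.lstrip("-").replace(".", "", 1).isdigit() for x in vals):
                parsed = tuple(float(x) if "." in x else int(x) for x in vals)
                out[k.strip()] = parsed if len(parsed) > 1 else parsed[0]
            else:
                out[k.strip()] = v if len(vals) == 1 else tuple(vals)
        return out
    return value


def parse_config(path: str | Path) -> RunConfig:
    """Flat ``key = value`` file with ``[section]`` headers."""
    config = RunConfig()
    section = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip()
            if section not in _SECTIONS and section != "run":
                raise ValueError(f"{path}: line {lineno}: unknown section {section!r}")
            continue
        if "=" not in line:
            raise ValueError(f"{path}: line {lineno}: expected key = value")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        target = config if section in (None, "run") else getattr(config, section)
        if not hasattr(target, key):
            raise ValueError(f"{path}: line {lineno}: unknown key {key!r}")
        setattr(target, key, _coerce(value, getattr(target, key)))
    return config


def write_config(config: RunConfig, path: str | Path) -> None:
    lines = ["[run]"]
    for f in dc_fields(config):
        if f.name in _SECTIONS or f.name == "outdir":
            continue
        lines.append(f"{f.name} = {getattr(config, f.name)}")
    for section, _ in _SECTIONS.items():
        lines.append(f"[{section}]")
        block = getattr(config, section)
        for f in dc_fields(block):
            v = getattr(block, f.name)
            if isinstance(v, dict):
                v = ";".join(
                    f"{k}={','.join(map(str, val)) if isinstance(val, tuple) else val}"
                    for k, val in v.items()
                )
            elif isinstance(v, (tuple, list)):
                v = ",".join(map(str, v))
            lines.append(f"{f.name} = {v}")
    Path(path).write_text("\n".join(lines) + "\n")


# -- run state --------------------------------------------------------------


@dataclass
class RunState:
    """In-memory products of the pipeline stages."""

    config: RunConfig
    genome: sim.Genome | None = None
    truth: sim.GroundTruth | None = None
    ctss: object = None
    peaks: dict | None = None
    bin_counts: dict | None = None
    meth: list | None = None
    clusters: list = field(default_factory=list)
    weak_clusters: list = field(default_factory=list)
    model: chmm.ChromatinHMM | None = None
    states: dict | None = None
    tss_state: int | None = None
    annotated: list = field(default_factory=list)
    counts: dict | None = None
    links: list = field(default_factory=list)
    ele_records: list = field(default_factory=list)  # dicts per called ELE
    family_results: list = field(default_factory=list)
    tissue_results: list = field(default_factory=list)
    ages: dict = field(default_factory=dict)
    motif_stats: dict = field(default_factory=dict)
    homology_calls: dict = field(default_factory=dict)
    homology_categories: dict = field(default_factory=dict)


def stage_simulate(state: RunState, outdir: Path) -> None:
    cfg = state.config
    cfg.sim.seed = cfg.seed
    (state.genome, state.truth, state.ctss, state.peaks, state.bin_counts,
     state.meth) = sim.simulate_all(cfg.sim)
    sim.write_outputs(state.genome, state.truth, state.ctss, state.peaks,
                      state.bin_counts, state.meth, outdir / "inputs")


def stage_cluster(state: RunState, outdir: Path) -> None:
    state.clusters, state.weak_clusters = clu.call_clusters(
        state.ctss, state.config.cluster
    )
    ivs, extras = [], []
    for cl in state.clusters:
        ivs.append(cl.interval)
        extras.append([cl.dominant_position, cl.shape, cl.n_supporting_samples,
                       *(f"{cl.per_tissue_rpm[t]:.3f}" for t in cl.per_tissue_rpm)])
    write_bed(ivs, outdir / "clusters.bed", extras)


def stage_segment(state: RunState, outdir: Path) -> None:
    cfg = state.config
    tracks = chmm.binarize(state.bin_counts, sim.HMM_TRACKS, cfg.sim.bin_size)
    state.model, _ll = chmm.fit(
        tracks, n_states=cfg.n_states, seed=cfg.seed,
        n_restarts=cfg.hmm_restarts, max_iter=cfg.hmm_max_iter,
    )
    state.states = chmm.decode(state.model, tracks)
    state.tss_state = chmm.tss_active_state(state.model)
    state.model.save(outdir / "model.json")
    ivs = []
    for chrom in sorted(state.states):
        arr = state.states[chrom]
        for b in range(arr.shape[0]):
            ivs.append(GenomicInterval(chrom, b * cfg.sim.bin_size,
                                       (b + 1) * cfg.sim.bin_size, ".",
                                       name=f"state{int(arr[b])}"))
    write_bed(ivs, outdir / "states.bed")


def stage_annotate(state: RunState, outdir: Path) -> None:
    cfg = state.config
    if state.peaks is None:
        raise FileNotFoundError("peak sets required for annotation")
    state.annotated, state.counts = ann.annotate(
        state.clusters, state.weak_clusters, state.genome.genes, state.peaks,
        state.states, state.tss_state, cfg.annotation, cfg.sim.bin_size,
    )
    rows = []
    state.ele_records = []
    for i, a in enumerate(state.annotated):
        iv = a.cluster.interval
        rows.append({
            "cluster_id": f"cl{i:05d}", "chrom": iv.chrom, "start": iv.start,
            "end": iv.end, "strand": iv.strand,
            "dominant": a.cluster.dominant_position, "shape": a.cluster.shape,
            "category": a.category, "gene": a.assigned_gene or "",
            "marks": ",".join(sorted(a.mark_overlaps)),
            "state": "" if a.hmm_state is None else a.hmm_state,
        })
        if a.category == "ele_tss":
            state.ele_records.append({
                "ele_id": f"cl{i:05d}", "annotated": a,
                "chrom": iv.chrom, "dominant": a.cluster.dominant_position,
                "strand": iv.strand,
                "per_sample_rpm": a.cluster.per_sample_rpm,
                "per_tissue_rpm": a.cluster.per_tissue_rpm,
            })
    pd.DataFrame(rows).to_csv(outdir / "annotated.tsv", sep="\t", index=False)
    samples = state.ctss.samples
    pd.DataFrame(
        [{"cluster_id": f"cl{i:05d}",
          **{s: a.cluster.per_sample_rpm.get(s, 0.0) for s in samples}}
         for i, a in enumerate(state.annotated)]
    ).to_csv(outdir / "cluster_expression.tsv", sep="\t", index=False)


def stage_link(state: RunState, outdir: Path) -> None:
    cfg = state.config
    eles = [(r["ele_id"], r["chrom"], r["dominant"]) for r in state.ele_records]
    gene_points = [(g.gene_id, g.chrom, g.tss) for g in state.genome.genes]
    pairs = lnk.candidate_pairs(eles, gene_points, cfg.rp)
    samples = state.ctss.samples
    ele_expr = {
        r["ele_id"]: [r["per_sample_rpm"][s] for s in samples]
        for r in state.ele_records
    }
    gene_expr: dict[str, list[float]] = {}
    for a in state.annotated:
        if a.category != "gene_tss" or not a.assigned_gene:
            continue
        vec = [a.cluster.per_sample_rpm[s] for s in samples]
        if a.assigned_gene in gene_expr:
            gene_expr[a.assigned_gene] = [
                x + y for x, y in zip(gene_expr[a.assigned_gene], vec)
            ]
        else:
            gene_expr[a.assigned_gene] = vec
    state.links = lnk.predict_targets(pairs, ele_expr, gene_expr, cfg.rp)
    pd.DataFrame([
        {"gene": l.gene_id, "ele": l.ele_id, "distance": l.distance,
         "rp": l.rp, "r": "" if l.correlation is None else f"{l.correlation:.4f}",
         "predicted": int(l.predicted)}
        for l in state.links
    ]).to_csv(outdir / "links.tsv", sep="\t", index=False)


def stage_te_enrich(state: RunState, outdir: Path) -> None:
    cfg = state.config
    tissues = list(cfg.sim.tissue_labels)
    ele_points = [(r["ele_id"], r["chrom"], r["dominant"])
                  for r in state.ele_records]
    hosts = temod.assign_te(ele_points, state.genome.tes)
    state.family_results = temod.family_enrichment(hosts, state.genome.tes,
                                                   level="subfamily")
    labels = {}
    for r in state.ele_records:
        means = [r["per_tissue_rpm"][t] for t in tissues]
        labels[r["ele_id"]], _tau = lnk.tissue_specificity(means, tissues,
                                                           cfg.tau_min)
    groups = {eid: te.subfamily for eid, te in hosts.items()}
    state.tissue_results = temod.tissue_enrichment(groups, labels, tissues)
    state.ele_tissue_labels = labels
    state.ele_hosts = hosts
    for name, results in (("family_enrichment.tsv", state.family_results),
                          ("tissue_enrichment.tsv", state.tissue_results)):
        pd.DataFrame([
            {"group": r.group, "a": r.table[0], "b": r.table[1],
             "c": r.table[2], "d": r.table[3],
             "odds_ratio": "" if r.odds_ratio is None else r.odds_ratio,
             "p": r.p_value, "q": r.q_value}
            for r in results
        ]).to_csv(outdir / name, sep="\t", index=False)


def stage_ltr_age(state: RunState, outdir: Path) -> None:
    seqs = state.genome.sequences
    rows = []
    state.ages = {}
    for te in state.genome.tes:
        if not te.full_length:
            continue
        chrom_seq = seqs[te.interval.chrom]
        s5 = chrom_seq[te.ltr5.start:te.ltr5.end]
        s3 = chrom_seq[te.ltr3.start:te.ltr3.end]
        dating = ltrmod.date_element(te.te_id, te.subfamily, s5, s3)
        state.ages[te.te_id] = dating.insertion_time
        rows.append({
            "te_id": te.te_id, "subfamily": te.subfamily,
            "P": f"{dating.p_transition:.5f}", "Q": f"{dating.q_transversion:.5f}",
            "d_k2p": "saturated" if dating.d_k2p is None else f"{dating.d_k2p:.6f}",
            "generations": "" if dating.insertion_time is None
                           else f"{dating.insertion_time:.1f}",
        })
    pd.DataFrame(rows).to_csv(outdir / "ltr_ages.tsv", sep="\t", index=False)


def default_motif_set() -> list[mot.Pwm]:
    """The planted GA-rich motif plus two unrelated control consensus PWMs."""
    def consensus_pwm(name, consensus):
        rows = []
        for b in consensus:
            row = [0.01] * 4
            row["ACGT".index(b)] = 0.97
            rows.append(row)
        return mot.Pwm(name, np.array(rows))

    return [
        consensus_pwm("GA_rich", sim.PLANTED_MOTIF),
        consensus_pwm("control_TGACGTCA", "TGACGTCA"),
        consensus_pwm("control_CACGTGAC", "CACGTGAC"),
    ]


def stage_motifs(state: RunState, outdir: Path) -> None:
    hosts = getattr(state, "ele_hosts", {})
    bias_subfam = next(iter(state.config.sim.ele_tissue_bias), None)
    seqs = state.genome.sequences
    group_a, group_b = {}, {}
    for r in state.ele_records:
        pos = r["dominant"]
        seq = seqs[r["chrom"]]
        window = seq[max(0, pos - 1000):pos + 1000]
        host = hosts.get(r["ele_id"])
        if host is not None and host.subfamily == bias_subfam:
            group_a[r["ele_id"]] = window
        else:
            group_b[r["ele_id"]] = window
    if not group_a or not group_b:
        state.motif_stats = {}
        return
    pwms = default_motif_set()
    counts_a = mot.scan_pwm(group_a, pwms)
    counts_b = mot.scan_pwm(group_b, pwms)
    state.motif_stats = mot.compare_motif_abundance(counts_a, counts_b)
    pd.DataFrame([
        {"motif": m, "abundance_host": v[0], "abundance_other": v[1],
         "welch_t": "" if v[2] is None else v[2],
         "p": "" if v[3] is None else v[3]}
        for m, v in sorted(state.motif_stats.items())
    ]).to_csv(outdir / "motif_comparison.tsv", sep="\t", index=False)


def stage_homology(state: RunState, outdir: Path) -> None:
    cfg = state.config
    subgenomes = list(cfg.sim.subgenomes)
    marks = cfg.annotation.ele_required_marks
    peaks_by_sub: dict[str, list] = {s: [] for s in subgenomes}
    for mark in marks:
        for iv in state.peaks.get(mark, []):
            sub = hom.subgenome_of(iv.chrom)
            if sub in peaks_by_sub:
                peaks_by_sub[sub].append(iv)
    ele_points = [
        (r["ele_id"], r["chrom"], r["dominant"], r["strand"])
        for r in state.ele_records
    ]
    state.homology_calls, state.homology_categories = hom.classify_eles(
        ele_points, state.genome.genes, state.truth.homoeolog_pairs,
        state.genome.sequences, peaks_by_sub, subgenomes,
    )
    rows = []
    for eid in sorted(state.homology_calls):
        for other, call in sorted(state.homology_calls[eid].items()):
            rows.append({
                "ele_id": eid, "counterpart": other, "class": call.klass,
                "hit": "" if call.hit is None else
                       f"{call.hit.chrom}:{call.hit.start}-{call.hit.end}",
                "evalue": "" if call.evalue is None else f"{call.evalue:.3g}",
                "category": state.homology_categories[eid],
            })
    pd.DataFrame(rows).to_csv(outdir / "homology.tsv", sep="\t", index=False)


STAGES = [
    ("simulate", stage_simulate),
    ("cluster", stage_cluster),
    ("segment", stage_segment),
    ("annotate", stage_annotate),
    ("link", stage_link),
    ("te-enrich", stage_te_enrich),
    ("ltr-age", stage_ltr_age),
    ("motif-compare", stage_motifs),
    ("homology", stage_homology),
]


def run_all(config: RunConfig) -> RunState:
    """Run every stage in fixed order; abort names the failing stage."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    handler = logging.FileHandler(outdir / "run.log")
    log.addHandler(handler)
    state = RunState(config)
    write_config(config, outdir / "config.txt")
    try:
        for name, fn in STAGES:
            log.info("stage %s: start (seed=%d)", name, config.seed)
            try:
                fn(state, outdir)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done", name)
        _write_summary(state, outdir / "summary.txt")
    finally:
        log.removeHandler(handler)
        handler.close()
    return state


def _write_summary(state: RunState, path: Path) -> None:
    cfg = state.config
    lines = [f"seed = {cfg.seed}"]
    for cat, n in sorted(state.counts.items()):
        lines.append(f"count_{cat} = {n}")
    labels = getattr(state, "ele_tissue_labels", {})
    for t in cfg.sim.tissue_labels:
        n = sum(1 for v in labels.values() if v == f"specific-to-{t}")
        lines.append(f"ele_specific_{t} = {n}")
    if state.family_results:
        top = state.family_results[0]
        lines.append(f"top_enriched_subfamily = {top.group}")
        lines.append(f"top_enriched_q = {top.q_value:.3g}")
    if state.tissue_results:
        lines.append(f"top_tissue_enrichment = {state.tissue_results[0].group}")
    n_pred = sum(1 for l in state.links if l.predicted)
    lines.append(f"predicted_links = {n_pred}")
    from collections import Counter
    cat_counts = Counter(state.homology_categories.values())
    for k in sorted(cat_counts):
        lines.append(f"homology_{k} = {cat_counts[k]}")
    ages = [a for a in state.ages.values() if a is not None]
    if ages:
        lines.append(f"mean_ltr_age_generations = {np.mean(ages):.1f}")
    lines.append(f"tss_active_state = {state.tss_state}")
    Path(path).write_text("\n".join(lines) + "\n")
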