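"""Synthetic multi-subgenome genome with planted regulatory ground truth.

The generator emulates the data structure of a CAGE + epigenome study of a
polyploid genome at desk scale: 2-3 subgenomes of 2 Mb each, homoeologous
gene order between subgenomes, TE subfamilies with one subfamily expanded in
a single subgenome, full-length LTR retrotransposons whose LTR pairs diverge
under a K2P-symmetric substitution process, transcribed enhancer-like
elements (ELEs) planted inside TE copies or at intergenic loci, per-sample
stranded CTSS counts (sharp/broad gene TSSs, bidirectional ELE edges,
Poisson background noise), histone-mark peak sets, a binned track matrix for
chromatin-state learning, and a per-cytosine methylation table.

Everything is a pure function of (config, seed). The ground-truth object
records planted TSSs, ELEs with their host TEs/active tissues/target genes,
true LTR insertion ages and the homoeolog map, so every downstream stage can
be scored against what was planted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .io import (
    CtssTable, GeneModel, MethylationRecord, TeAnnotation,
    family_of_subfamily, superfamily_of, write_bed, write_ctss, write_fasta,
    write_gff3_genes, write_methylation, write_te_table,
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
TRANSITION = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T (indices into ACGT)
SUBGENOME_LABELS = ("A", "B", "D")

HMM_TRACKS = ["CAGE", "H3K4me3", "H3K9ac", "H3K36me3", "open", "GROseq", "RNAseq"]

# Consensus of the motif planted around expanded-subfamily ELE TSSs
# (a GA-rich element of the kind bound by BPC-class factors).
PLANTED_MOTIF = "GAGAGAGAGA"


@dataclass
class SimConfig:
    n_subgenomes: int = 3
    chrom_length_bp: int = 2_000_000
    n_genes: int = 40                      # per subgenome
    n_te_per_subfamily: dict = field(default_factory=lambda: {
        "RLG_famc7.3": (40, 2, 2),
        "RLG_famc7.1": (6, 6, 6),
        "RLC_famc1.1": (6, 6, 6),
        "DTC_famc5.1": (5, 5, 5),
    })
    n_planted_eles: int = 60
    tissue_labels: tuple = ("embryo", "seedling", "spike", "root")
    replicates_per_tissue: int = 2
    ele_tissue_bias: dict = field(default_factory=lambda: {"RLG_famc7.3": "spike"})
    ltr_divergence_range: tuple = (0.01, 0.10)
    noise_rate: float = 2e-5               # background CTSS reads per bp
    seed: int = 0
    # secondary knobs (documented defaults)
    collinear_fraction: float = 0.9
    n_weak_genes: int = 4                  # per subgenome; rescue candidates
    gene_mean_count: float = 30.0          # per replicate, ubiquitous gene
    target_mean_count: float = 60.0        # in ELE-active tissues
    ele_mean_count: float = 40.0
    weak_mean_count: float = 0.25
    sharp_fraction: float = 0.6
    ts_tv_ratio: float = 2.0
    bin_size: int = 500

    def __post_init__(self) -> None:
        if self.replicates_per_tissue < 2:
            raise ValueError("replicates_per_tissue must be >= 2")
        for x in (*self.ltr_divergence_range, self.noise_rate,
                  self.collinear_fraction, self.sharp_fraction):
            if not (0.0 <= x <= 1.0):
                raise ValueError("rates/fractions must lie in [0,1]")
        if not (2 <= self.n_subgenomes <= 3):
            raise ValueError("n_subgenomes must be 2 or 3")

    @property
    def subgenomes(self) -> tuple:
        return SUBGENOME_LABELS[: self.n_subgenomes]

    @property
    def samples(self) -> list[str]:
        return [
            f"{t}_rep{r}"
            for t in self.tissue_labels
            for r in range(1, self.replicates_per_tissue + 1)
        ]


@dataclass
class PlantedGene:
    gene_id: str
    chrom: str
    tss: int
    strand: str
    shape: str                       # sharp | broad
    tissue_means: dict               # tissue -> mean count per replicate
    weak: bool = False


@dataclass
class PlantedEle:
    ele_id: str
    interval: GenomicInterval
    host_te_id: Optional[str]
    host_subfamily: Optional[str]
    active_tissues: tuple
    target_genes: tuple
    common_group: Optional[int] = None   # shared locus id for cross-subgenome ELEs


@dataclass
class GroundTruth:
    genes: list[PlantedGene]
    eles: list[PlantedEle]
    te_ages: dict                     # te_id -> (divergence d, generations)
    homoeolog_pairs: list             # (gene_id, gene_id) across subgenome pairs

    def eles_by_id(self) -> dict:
        return {e.ele_id: e for e in self.eles}


@dataclass
class Genome:
    sequences: dict                   # chrom -> str
    genes: list[GeneModel]
    tes: list[TeAnnotation]
    config: SimConfig


# ---------------------------------------------------------------------------
# LTR divergence under K2P


def k2p_event_probs(d: float, ts_tv_ratio: float = 2.0) -> tuple[float, float]:
    """(P, Q): expected transition/transversion difference proportions after
    per-site substitution distance ``d`` under the K2P model with the given
    transition:transversion event ratio."""
    r = ts_tv_ratio
    beta_t = d / (2.0 * r + 2.0)
    alpha_t = r * d / (r + 1.0)
    P = 0.25 + 0.25 * math.exp(-4.0 * beta_t) - 0.5 * math.exp(-2.0 * (alpha_t + beta_t))
    Q = 0.5 - 0.5 * math.exp(-4.0 * beta_t)
    return P, Q


def diverge_sequence(
    codes: np.ndarray, d: float, rng: np.random.Generator,
    ts_tv_ratio: float = 2.0,
) -> np.ndarray:
    """Mutate base-index codes at K2P distance ``d`` (substitutions/site)."""
    if d == 0:
        return codes.copy()
    P, Q = k2p_event_probs(d, ts_tv_ratio)
    u = rng.random(codes.shape[0])
    out = codes.copy()
    ts_mask = u < P
    tv1_mask = (u >= P) & (u < P + Q / 2)
    tv2_mask = (u >= P + Q / 2) & (u < P + Q)
    trans = np.array([TRANSITION[i] for i in range(4)])
    out[ts_mask] = trans[codes[ts_mask]]
    # transversions: the two bases of the opposite chemical class
    tv_a = np.array([1, 0, 1, 0])  # A->C, C->A, G->C, T->A
    tv_b = np.array([3, 2, 3, 2])  # A->T, C->G, G->T, T->C
    out[tv1_mask] = tv_a[codes[tv1_mask]]
    out[tv2_mask] = tv_b[codes[tv2_mask]]
    return out


def simulate_ltr_pair(
    length: int, age_generations: float, rng: np.random.Generator,
    mu: float = 1.3e-8, ts_tv_ratio: float = 2.0,
) -> tuple[str, str]:
    """An LTR pair separated by total divergence 2*mu*age (both copies
    accumulate substitutions independently after insertion)."""
    codes = rng.integers(0, 4, size=length).astype(np.int64)
    d_total = 2.0 * mu * age_generations
    other = diverge_sequence(codes, d_total, rng, ts_tv_ratio)
    return _codes_to_str(codes), _codes_to_str(other)


def _codes_to_str(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode()


# ---------------------------------------------------------------------------
# Genome construction

GENE_LEN = 1200
UTR_LEN = 200
ELE_LEN = 300
LTR_LEN = 200
GENE_MARGIN = 4000   # TEs/ELEs stay this far from gene models (> 3 kb rule)


def _gene_layout(config: SimConfig, rng: np.random.Generator):
    """Gene positions/strands per subgenome with homoeologous order."""
    spacing = config.chrom_length_bp // (config.n_genes + 1)
    if spacing < GENE_LEN + 2 * GENE_MARGIN + 2000:
        raise ValueError("chromosome too short for the requested gene count")
    strands = rng.choice(["+", "-"], size=config.n_genes)
    collinear = rng.random(config.n_genes) < config.collinear_fraction
    layout = {}
    for s, sub in enumerate(config.subgenomes):
        chrom = f"chr1{sub}"
        jitter = rng.integers(-2000, 2001, size=config.n_genes)
        starts = [
            (i + 1) * spacing + int(jitter[i]) for i in range(config.n_genes)
        ]
        layout[sub] = [
            {
                "gene_id": (f"gene{i + 1:03d}{sub}" if collinear[i]
                            else f"gene{i + 1:03d}{sub}only"),
                "chrom": chrom,
                "start": starts[i],
                "strand": str(strands[i]),
                "collinear": bool(collinear[i]),
                "slot": i,
            }
            for i in range(config.n_genes)
        ]
    return layout


def _build_gene_model(info: dict) -> GeneModel:
    s = info["start"]
    chrom, strand = info["chrom"], info["strand"]
    if strand == "+":
        exons = [GenomicInterval(chrom, s, s + 300, strand),
                 GenomicInterval(chrom, s + 500, s + GENE_LEN, strand)]
        utr5 = [GenomicInterval(chrom, s, s + UTR_LEN, strand)]
    else:
        exons = [GenomicInterval(chrom, s, s + 700, strand),
                 GenomicInterval(chrom, s + 900, s + GENE_LEN, strand)]
        utr5 = [GenomicInterval(chrom, s + GENE_LEN - UTR_LEN, s + GENE_LEN, strand)]
    return GeneModel(info["gene_id"], chrom, s, s + GENE_LEN, strand, exons, utr5)


class _FreeSpace:
    """Free intervals between genes for feature placement (margin-aware)."""

    def __init__(self, chrom_len: int, gene_infos: list[dict]):
        self.free: list[list[int]] = []
        prev_end = GENE_MARGIN
        for info in sorted(gene_infos, key=lambda g: g["start"]):
            start = info["start"] - GENE_MARGIN
            if start - prev_end >= 1000:
                self.free.append([prev_end, start])
            prev_end = info["start"] + GENE_LEN + GENE_MARGIN
        if chrom_len - GENE_MARGIN - prev_end >= 1000:
            self.free.append([prev_end, chrom_len - GENE_MARGIN])

    def place(self, length: int, rng: np.random.Generator) -> int:
        """Reserve ``length`` bp somewhere free; returns the start."""
        candidates = [i for i, (a, b) in enumerate(self.free) if b - a >= length + 400]
        if not candidates:
            raise ValueError("chromosome too short to place requested features")
        i = int(rng.choice(candidates))
        a, b = self.free[i]
        start = int(rng.integers(a, b - length + 1))
        self.reserve(i, start, start + length)
        return start

    def place_in_gap(self, gap: tuple[int, int], length: int, offset_frac: float) -> int:
        """Reserve at a fixed relative offset inside a specific gene gap."""
        lo, hi = gap[0] + GENE_MARGIN, gap[1] - GENE_MARGIN
        start = int(lo + offset_frac * (hi - lo - length))
        for i, (a, b) in enumerate(self.free):
            if a <= start and start + length <= b:
                self.reserve(i, start, start + length)
                return start
        raise ValueError("requested gap region is not free")

    def reserve(self, i: int, start: int, end: int) -> None:
        a, b = self.free[i]
        sep = 200
        new = []
        if start - sep - a >= 600:
            new.append([a, start - sep])
        if b - (end + sep) >= 600:
            new.append([end + sep, b])
        self.free[i:i + 1] = new


def generate_genome(config: SimConfig) -> tuple[Genome, GroundTruth]:
    """Build sequences, gene models, TE table, homoeolog map and truth."""
    rng = np.random.default_rng(config.seed)
    layout = _gene_layout(config, rng)
    genes: list[GeneModel] = []
    for sub in config.subgenomes:
        genes.extend(_build_gene_model(info) for info in layout[sub])

    homoeolog_pairs = []
    for i in range(config.n_genes):
        ids = [layout[sub][i]["gene_id"] for sub in config.subgenomes
               if layout[sub][i]["collinear"]]
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                homoeolog_pairs.append((ids[a], ids[b]))
                homoeolog_pairs.append((ids[b], ids[a]))

    free = {
        sub: _FreeSpace(config.chrom_length_bp, layout[sub])
        for sub in config.subgenomes
    }

    # ELE budget
    n = config.n_planted_eles
    biased_subfamily = next(iter(config.ele_tissue_bias), None)
    n_biased = round(0.5 * n) if biased_subfamily else 0
    n_common_loci = max(1, round(0.2 * n / config.n_subgenomes))
    n_other_te = round(0.15 * n)
    n_single = max(0, n - n_biased - n_common_loci * config.n_subgenomes - n_other_te)

    # Common (cross-subgenome) ELE loci first, at homoeologous gap offsets.
    collinear_slots = [
        i for i in range(config.n_genes - 1)
        if all(layout[sub][i]["collinear"] and layout[sub][i + 1]["collinear"]
               for sub in config.subgenomes)
    ]
    rng.shuffle(collinear_slots)
    common_loci = []  # (group, sub -> start)
    for gi, slot in enumerate(collinear_slots[:n_common_loci]):
        per_sub = {}
        frac = 0.4 + 0.2 * rng.random()
        for sub in config.subgenomes:
            gap = (layout[sub][slot]["start"] + GENE_LEN,
                   layout[sub][slot + 1]["start"])
            per_sub[sub] = free[sub].place_in_gap(gap, ELE_LEN, frac)
        common_loci.append(per_sub)

    # TEs
    tes: list[TeAnnotation] = []
    te_by_sub: dict[str, list[TeAnnotation]] = {s: [] for s in config.subgenomes}
    te_counter = 0
    for subfam in sorted(config.n_te_per_subfamily):
        counts = config.n_te_per_subfamily[subfam]
        fam = family_of_subfamily(subfam)
        superfam = superfamily_of(subfam)
        is_ltr = superfam in ("RLG", "RLC")
        te_len = 1200 if is_ltr else 800
        for s, sub in enumerate(config.subgenomes):
            for _ in range(int(counts[s]) if s < len(counts) else 0):
                start = free[sub].place(te_len, rng)
                te_counter += 1
                chrom = f"chr1{sub}"
                iv = GenomicInterval(chrom, start, start + te_len, "+",
                                     f"te{te_counter:04d}")
                ltr5 = ltr3 = None
                if is_ltr:
                    ltr5 = GenomicInterval(chrom, start, start + LTR_LEN, "+")
                    ltr3 = GenomicInterval(chrom, start + te_len - LTR_LEN,
                                           start + te_len, "+")
                te = TeAnnotation(f"te{te_counter:04d}", iv, superfam, fam,
                                  subfam, is_ltr, ltr5, ltr3)
                tes.append(te)
                te_by_sub[sub].append(te)

    # ELE placement
    eles: list[PlantedEle] = []
    ele_counter = 0

    def next_ele_id():
        nonlocal ele_counter
        ele_counter += 1
        return f"ele{ele_counter:03d}"

    home_sub = config.subgenomes[0]
    expanded = [te for te in te_by_sub[home_sub] if te.subfamily == biased_subfamily]
    rng.shuffle(expanded)
    bias_tissue = config.ele_tissue_bias.get(biased_subfamily, "spike")
    for te in expanded[:n_biased]:
        off = int(rng.integers(LTR_LEN + 50, len(te.interval) - ELE_LEN - LTR_LEN))
        start = te.interval.start + off
        eles.append(PlantedEle(
            next_ele_id(),
            GenomicInterval(te.interval.chrom, start, start + ELE_LEN, "+"),
            te.te_id, te.subfamily, (bias_tissue,), (),
        ))

    other_hosts = [te for sub in config.subgenomes for te in te_by_sub[sub]
                   if te.subfamily != biased_subfamily]
    rng.shuffle(other_hosts)
    other_tissues = [t for t in config.tissue_labels if t != bias_tissue]
    for te in other_hosts[:n_other_te]:
        pad = LTR_LEN if te.full_length else 50
        off = int(rng.integers(pad + 50, len(te.interval) - ELE_LEN - pad))
        start = te.interval.start + off
        tissue = str(rng.choice(other_tissues))
        eles.append(PlantedEle(
            next_ele_id(),
            GenomicInterval(te.interval.chrom, start, start + ELE_LEN, "+"),
            te.te_id, te.subfamily, (tissue,), (),
        ))

    for group, per_sub in enumerate(common_loci):
        pair = tuple(str(t) for t in rng.choice(config.tissue_labels, size=2,
                                                replace=False))
        for sub in config.subgenomes:
            start = per_sub[sub]
            eles.append(PlantedEle(
                next_ele_id(),
                GenomicInterval(f"chr1{sub}", start, start + ELE_LEN, "+"),
                None, None, tuple(sorted(pair)), (), common_group=group,
            ))

    for _ in range(n_single):
        sub = str(rng.choice(list(config.subgenomes)))
        start = free[sub].place(ELE_LEN, rng)
        tissue = str(rng.choice(list(config.tissue_labels)))
        eles.append(PlantedEle(
            next_ele_id(),
            GenomicInterval(f"chr1{sub}", start, start + ELE_LEN, "+"),
            None, None, (tissue,), (),
        ))

    # Assign targets + expression profiles
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    profiles: dict[str, PlantedGene] = {}
    gene_info = {info["gene_id"]: info for sub in config.subgenomes
                 for info in layout[sub]}
    shapes = {}
    for g in genes:
        shapes[g.gene_id] = "sharp" if rng.random() < config.sharp_fraction else "broad"
        factors = 0.8 + 0.4 * rng.random(len(config.tissue_labels))
        profiles[g.gene_id] = PlantedGene(
            g.gene_id, g.chrom, g.tss, g.strand, shapes[g.gene_id],
            {t: config.gene_mean_count * float(f)
             for t, f in zip(config.tissue_labels, factors)},
        )

    # Planted regulatory potential per gene (from planted ELE positions).
    # Target links are only planted at genes in the upper half of this
    # distribution: the linking rule's top-50% RP filter cannot, by its own
    # definition, recover a target below the median, so links planted there
    # would be unrecoverable by construction rather than by method error.
    gene_rp: dict[str, float] = {}
    for g in genes:
        rp = 0.0
        for ele in eles:
            if ele.interval.chrom != g.chrom:
                continue
            d = abs(g.tss - ele.interval.start)
            if d <= 2_000_000:
                rp += 2.0 ** (-d / 100_000.0)
        gene_rp[g.gene_id] = rp
    rp_median = float(np.median([v for v in gene_rp.values() if v > 0]))

    taken: set[str] = set()
    assigned_tissues: dict[str, tuple] = {}
    for ele in eles:
        chrom_genes = genes_by_chrom[ele.interval.chrom]
        flexible = ele.host_subfamily != biased_subfamily

        def _near(max_dist, want_untaken, want_high_rp):
            return sorted(
                (g for g in chrom_genes
                 if abs(g.tss - ele.interval.start) <= max_dist
                 and (not want_untaken or g.gene_id not in taken)
                 and (not want_high_rp or gene_rp[g.gene_id] >= rp_median)),
                key=lambda g: (abs(g.tss - ele.interval.start), g.gene_id),
            )

        fresh = _near(500_000, True, True) or _near(2_000_000, True, True)
        targets = [g.gene_id for g in fresh[:2]]
        if not targets:
            # reuse an already-targeted high-RP gene; the ELE adopts that
            # gene's tissues (or, for the biased subfamily, requires a match)
            reuse = _near(2_000_000, False, True) or _near(2_000_000, False, False)
            for g in reuse:
                prior = assigned_tissues.get(g.gene_id)
                if prior is None or flexible or set(prior) == set(ele.active_tissues):
                    targets = [g.gene_id]
                    if prior is not None and flexible:
                        ele.active_tissues = prior
                    break
            if not targets and reuse:
                targets = [reuse[0].gene_id]
        ele.target_genes = tuple(targets)
        for gid in targets:
            taken.add(gid)
            assigned_tissues[gid] = tuple(ele.active_tissues)
            profiles[gid].tissue_means = {
                t: (config.target_mean_count if t in ele.active_tissues else 2.0)
                for t in config.tissue_labels
            }

    # Weak genes (rescue candidates): untargeted genes, lowest expression
    for sub in config.subgenomes:
        untargeted = [info["gene_id"] for info in layout[sub]
                      if info["gene_id"] not in taken]
        for gid in untargeted[: config.n_weak_genes]:
            pg = profiles[gid]
            pg.weak = True
            pg.tissue_means = {t: config.weak_mean_count for t in config.tissue_labels}

    # Sequences
    sequences = {}
    codes_by_chrom = {}
    for sub in config.subgenomes:
        chrom = f"chr1{sub}"
        codes_by_chrom[chrom] = rng.integers(
            0, 4, size=config.chrom_length_bp
        ).astype(np.int64)

    te_ages: dict[str, tuple[float, float]] = {}
    lo, hi = config.ltr_divergence_range
    mu = 1.3e-8
    for te in tes:
        if not te.full_length:
            continue
        d = float(lo + (hi - lo) * rng.random())
        codes = codes_by_chrom[te.interval.chrom]
        ltr5 = codes[te.ltr5.start:te.ltr5.end]
        codes[te.ltr3.start:te.ltr3.end] = diverge_sequence(
            ltr5, d, rng, config.ts_tv_ratio
        )
        te_ages[te.te_id] = (d, d / (2.0 * mu))

    motif_codes = np.frombuffer(PLANTED_MOTIF.encode(), dtype=np.uint8)
    motif_idx = np.array([int(np.where(BASES == b)[0][0]) for b in motif_codes])
    for ele in eles:
        if ele.host_subfamily == biased_subfamily:
            codes = codes_by_chrom[ele.interval.chrom]
            for k in range(2):  # two copies near the ELE TSS
                pos = ele.interval.start + 30 + 60 * k
                codes[pos:pos + motif_idx.size] = motif_idx

    # Common loci share one core sequence across subgenomes
    by_group: dict[int, list[PlantedEle]] = {}
    for ele in eles:
        if ele.common_group is not None:
            by_group.setdefault(ele.common_group, []).append(ele)
    for group, members in sorted(by_group.items()):
        core = rng.integers(0, 4, size=ELE_LEN + 200).astype(np.int64)
        for ele in members:
            codes = codes_by_chrom[ele.interval.chrom]
            codes[ele.interval.start:ele.interval.start + core.size] = core

    for chrom, codes in codes_by_chrom.items():
        sequences[chrom] = _codes_to_str(codes)

    truth = GroundTruth(
        genes=[profiles[g.gene_id] for g in genes],
        eles=eles,
        te_ages=te_ages,
        homoeolog_pairs=homoeolog_pairs,
    )
    genome = Genome(sequences, genes, tes, config)
    _check_truth(genome, truth)
    return genome, truth


def _check_truth(genome: Genome, truth: GroundTruth) -> None:
    te_by_id = {te.te_id: te for te in genome.tes}
    gene_by_id = {g.gene_id: g for g in genome.genes}
    for ele in truth.eles:
        if not ele.active_tissues:
            raise AssertionError(f"{ele.ele_id}: no active tissue")
        if ele.host_te_id is not None:
            host = te_by_id[ele.host_te_id].interval
            if not (host.start <= ele.interval.start
                    and ele.interval.end <= host.end):
                raise AssertionError(f"{ele.ele_id} outside host TE")
        if not ele.target_genes:
            raise AssertionError(f"{ele.ele_id}: no target gene")
        for gid in ele.target_genes:
            if abs(gene_by_id[gid].tss - ele.interval.start) > 2_000_000:
                raise AssertionError(f"{ele.ele_id}: target {gid} beyond 2 Mb")


# ---------------------------------------------------------------------------
# CTSS simulation

SHARP_OFFSETS = np.array([-1, 0, 1, 2])
SHARP_PROBS = np.array([0.04, 0.82, 0.1, 0.04])
ELE_OFFSETS = np.arange(5)
ELE_PROBS = np.array([0.5, 0.2, 0.15, 0.1, 0.05])


def simulate_ctss(genome: Genome, truth: GroundTruth,
                  config: SimConfig) -> CtssTable:
    """Per-sample stranded CTSS counts.

    Gene TSSs emit from a peaked positional distribution (sharp: >=90% of
    signal within a few bp; broad: uniform over ~30 bp); ELEs emit
    bidirectionally from their 5' edge in active tissues only; background
    positions carry Poisson noise at ``noise_rate`` per bp. Replicates are
    independent Poisson draws sharing tissue-level means.
    """
    rng = np.random.default_rng(config.seed + 1)
    counts: dict[tuple[str, int, str], np.ndarray] = {}
    samples = config.samples
    n_samples = len(samples)

    def add(chrom, pos, strand, sample_idx, k):
        if k <= 0:
            return
        key = (chrom, int(pos), strand)
        if key not in counts:
            counts[key] = np.zeros(n_samples, dtype=np.int64)
        counts[key][sample_idx] += k

    broad_width = {}
    for pg in truth.genes:
        broad_width[pg.gene_id] = int(rng.integers(20, 41))
    for si, sample in enumerate(samples):
        tissue = sample.rsplit("_rep", 1)[0]
        for pg in truth.genes:
            mean = pg.tissue_means[tissue]
            total = int(rng.poisson(mean))
            if total == 0:
                continue
            sign = 1 if pg.strand == "+" else -1
            if pg.shape == "sharp":
                offsets = rng.choice(SHARP_OFFSETS, size=total, p=SHARP_PROBS)
            else:
                offsets = rng.integers(0, broad_width[pg.gene_id], size=total)
            pos, cnt = np.unique(pg.tss + sign * offsets, return_counts=True)
            for p, k in zip(pos, cnt):
                add(pg.chrom, p, pg.strand, si, int(k))
        for ele in truth.eles:
            if tissue not in ele.active_tissues:
                continue
            total = int(rng.poisson(config.ele_mean_count))
            if total == 0:
                continue
            strands = rng.random(total) < 0.5
            offsets = rng.choice(ELE_OFFSETS, size=total, p=ELE_PROBS)
            positions = ele.interval.start + offsets
            for strand_flag in (True, False):
                sel = strands == strand_flag
                pos, cnt = np.unique(positions[sel], return_counts=True)
                st = "+" if strand_flag else "-"
                for p, k in zip(pos, cnt):
                    add(ele.interval.chrom, p, st, si, int(k))
        # noise
        for chrom, seq in genome.sequences.items():
            n_noise = int(rng.poisson(config.noise_rate * len(seq)))
            if n_noise == 0:
                continue
            pos = rng.integers(0, len(seq), size=n_noise)
            strands = rng.choice(["+", "-"], size=n_noise)
            for p, st in zip(pos, strands):
                add(chrom, int(p), str(st), si, 1)

    rows = []
    for (chrom, pos, strand), vec in counts.items():
        rows.append([chrom, pos, strand, *vec.tolist()])
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", *samples])
    df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort")
    return CtssTable(df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Epigenome simulation


def simulate_epigenome(genome: Genome, truth: GroundTruth, config: SimConfig):
    """Peak BEDs, the binned HMM track count matrix, and a methylation table.

    Active gene promoters and ELEs carry H3K4me3/H3K9ac peaks; expressed
    gene bodies carry elongation signal; TE bodies are heavily CG/CHG
    methylated except for hypo-methylated windows around planted ELEs.
    """
    rng = np.random.default_rng(config.seed + 2)
    peaks: dict[str, list[GenomicInterval]] = {"H3K4me3": [], "H3K9ac": [],
                                               "H3K27me3": []}
    for pg in truth.genes:
        start = max(0, pg.tss - 400)
        iv = GenomicInterval(pg.chrom, start, pg.tss + 400, ".")
        peaks["H3K4me3"].append(iv)
        peaks["H3K9ac"].append(iv)
    for ele in truth.eles:
        iv = GenomicInterval(ele.interval.chrom,
                             max(0, ele.interval.start - 100),
                             ele.interval.end + 100, ".")
        peaks["H3K4me3"].append(iv)
        peaks["H3K9ac"].append(iv)
    # a few repressive domains in otherwise empty space
    for chrom in genome.sequences:
        for _ in range(3):
            s = int(rng.integers(0, config.chrom_length_bp - 5000))
            peaks["H3K27me3"].append(GenomicInterval(chrom, s, s + 5000, "."))

    # binned count matrix
    bin_size = config.bin_size
    bin_counts: dict[str, np.ndarray] = {}
    track_idx = {t: j for j, t in enumerate(HMM_TRACKS)}
    for chrom, seq in genome.sequences.items():
        n_bins = len(seq) // bin_size
        bin_counts[chrom] = rng.poisson(1.0, size=(n_bins, len(HMM_TRACKS)))
    gene_by_id = {g.gene_id: g for g in genome.genes}

    def boost(chrom, lo_bin, hi_bin, tracks, lam):
        arr = bin_counts[chrom]
        lo_bin = max(0, lo_bin)
        hi_bin = min(arr.shape[0], hi_bin)
        if hi_bin <= lo_bin:
            return
        for t in tracks:
            arr[lo_bin:hi_bin, track_idx[t]] += rng.poisson(
                lam, size=hi_bin - lo_bin
            )

    for pg in truth.genes:
        b = pg.tss // bin_size
        boost(pg.chrom, b - 1, b + 2, ["CAGE", "H3K4me3", "H3K9ac", "open",
                                       "GROseq"], 20.0)
        if not pg.weak:
            # elongation marks are 3'-biased: they start past the promoter
            # window, so strong and weak promoters share one bin signature
            g = gene_by_id[pg.gene_id]
            lo, hi = g.start // bin_size, g.end // bin_size + 1
            if pg.strand == "+":
                lo = max(lo, b + 2)
            else:
                hi = min(hi, b - 1)
            boost(pg.chrom, lo, hi, ["H3K36me3", "RNAseq", "GROseq"], 15.0)
    for ele in truth.eles:
        # eRNAs are nascent transcripts: ELE bins carry run-on signal too,
        # so active ELEs and promoters share the TSS-active chromatin state
        b = ele.interval.start // bin_size
        boost(ele.interval.chrom, b, b + 1,
              ["CAGE", "H3K4me3", "H3K9ac", "open", "GROseq"], 20.0)

    # methylation over TE bodies
    meth: list[MethylationRecord] = []
    ele_windows: dict[str, list[tuple[int, int]]] = {}
    for ele in truth.eles:
        ele_windows.setdefault(ele.interval.chrom, []).append(
            (ele.interval.start - 100, ele.interval.end + 100)
        )
    for te in genome.tes:
        chrom = te.interval.chrom
        for pos in range(te.interval.start, te.interval.end, 37):
            hypo = any(a <= pos < b for a, b in ele_windows.get(chrom, []))
            rate = 0.05 if hypo else 0.9
            cov = 3 + int(rng.poisson(8))
            m = int(rng.binomial(cov, rate))
            context = "CG" if pos % 2 == 0 else "CHG"
            meth.append(MethylationRecord(chrom, pos, context, m, cov, "+"))

    return peaks, bin_counts, meth


# ---------------------------------------------------------------------------
# On-disk output


def write_outputs(genome: Genome, truth: GroundTruth, ctss: CtssTable,
                  peaks, bin_counts, meth, outdir: str | Path) -> dict[str, Path]:
    """Write every downstream input format plus the ground-truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["fasta"] = outdir / "genome.fa"
    write_fasta(genome.sequences, paths["fasta"])
    paths["gff3"] = outdir / "genes.gff3"
    write_gff3_genes(genome.genes, paths["gff3"])
    paths["te"] = outdir / "te_annotations.tsv"
    write_te_table(genome.tes, paths["te"])
    paths["ctss"] = outdir / "ctss.tsv"
    write_ctss(ctss, paths["ctss"])
    for mark, ivs in peaks.items():
        p = outdir / f"peaks_{mark}.bed"
        write_bed(ivs, p)
        paths[f"peaks_{mark}"] = p
    paths["bins"] = outdir / "hmm_bins.tsv"
    rows = []
    for chrom in sorted(bin_counts):
        arr = bin_counts[chrom]
        for b in range(arr.shape[0]):
            rows.append([chrom, b * genome.config.bin_size, *arr[b].tolist()])
    pd.DataFrame(rows, columns=["chrom", "bin_start", *HMM_TRACKS]).to_csv(
        paths["bins"], sep="\t", index=False
    )
    paths["methylation"] = outdir / "methylation.tsv"
    write_methylation(meth, paths["methylation"])
    paths["homoeologs"] = outdir / "homoeologs.tsv"
    pd.DataFrame(truth.homoeolog_pairs, columns=["gene_a", "gene_b"]).to_csv(
        paths["homoeologs"], sep="\t", index=False
    )
    paths["truth_eles"] = outdir / "truth_eles.tsv"
    pd.DataFrame([
        {
            "ele_id": e.ele_id, "chrom": e.interval.chrom,
            "start": e.interval.start, "end": e.interval.end,
            "host_te_id": e.host_te_id or "", "host_subfamily": e.host_subfamily or "",
            "active_tissues": ",".join(e.active_tissues),
            "target_genes": ",".join(e.target_genes),
            "common_group": "" if e.common_group is None else e.common_group,
        }
        for e in truth.eles
    ]).to_csv(paths["truth_eles"], sep="\t", index=False)
    paths["truth_genes"] = outdir / "truth_genes.tsv"
    pd.DataFrame([
        {"gene_id": g.gene_id, "chrom": g.chrom, "tss": g.tss,
         "strand": g.strand, "shape": g.shape, "weak": int(g.weak),
         **{f"mean_{t}": g.tissue_means[t] for t in genome.config.tissue_labels}}
        for g in truth.genes
    ]).to_csv(paths["truth_genes"], sep="\t", index=False)
    paths["truth_ages"] = outdir / "truth_te_ages.tsv"
    pd.DataFrame([
        {"te_id": tid, "divergence": d, "generations": t}
        for tid, (d, t) in sorted(truth.te_ages.items())
    ]).to_csv(paths["truth_ages"], sep="\t", index=False)
    return paths


def simulate_all(config: SimConfig):
    """Convenience wrapper: genome, truth, ctss, peaks, bins, methylation."""
    genome, truth = generate_genome(config)
    ctss = simulate_ctss(genome, truth, config)
    peaks, bin_counts, meth = simulate_epigenome(genome, truth, config)
    return genome, truth, ctss, peaks, bin_counts, meth
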