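"""Readers/writers for the on-disk formats shared by every pipeline stage.

Formats: BED4/BED6 (peaks, ELEs), GFF3 gene models, tab-delimited stranded
CTSS count tables, tab-delimited TE annotations, FASTA, tab-delimited
per-cytosine methylation tables. Internal coordinates are 0-based half-open
everywhere; GFF3's 1-based inclusive convention is converted at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval, sort_key


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED4/BED6 into intervals (0-based half-open, per standard).

    Input order is preserved. Malformed lines raise :class:`ParseError`
    naming the line number; inverted coordinates raise ``ValueError``.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            name = parts[3] if len(parts) > 3 else ""
            try:
                score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad score") from exc
            strand = parts[5] if len(parts) > 5 else "."
            try:
                out.append(GenomicInterval(parts[0], start, end, strand, name, score))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_bed(intervals, path: str | Path, extra_columns=None) -> None:
    """Write BED6 (+optional extra columns keyed by interval index), in the
    canonical deterministic order (chrom, start, end, strand)."""
    order = sorted(range(len(intervals)), key=lambda i: sort_key(intervals[i]))
    with open(path, "w") as fh:
        for i in order:
            iv = intervals[i]
            fields = [
                iv.chrom,
                str(iv.start),
                str(iv.end),
                iv.name or ".",
                f"{iv.score:g}",
                iv.strand,
            ]
            if extra_columns is not None:
                fields.extend(str(x) for x in extra_columns[i])
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Gene models (GFF3)


@dataclass
class GeneModel:
    """A gene with its TSS and sub-feature intervals, 0-based half-open.

    TSS is the start of the first exon on + strand and ``end - 1`` of the
    last exon on - strand (a single genomic position).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)

    @property
    def tss(self) -> int:
        if self.strand == "+":
            return min(e.start for e in self.exons) if self.exons else self.start
        return max(e.end for e in self.exons) - 1 if self.exons else self.end - 1

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand, self.gene_id)


def _gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if "=" in item:
            key, _, value = item.partition("=")
            out[key.strip()] = value.strip()
    return out


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Parse gene models from GFF3 (1-based inclusive on disk -> 0-based
    half-open internally). Requires the gene/mRNA feature hierarchy; exons
    and five_prime_UTR features are attached via Parent chains."""
    genes: dict[str, GeneModel] = {}
    mrna_to_gene: dict[str, str] = {}
    pending: list[tuple[int, str, str, int, int, str, dict]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start1, end1, _, strand, _, attrs = parts
            try:
                start1, end1 = int(start1), int(end1)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if end1 < start1:
                raise ValueError(f"{path}: line {lineno}: end < start")
            start, end = start1 - 1, end1  # to 0-based half-open
            a = _gff3_attributes(attrs)
            if ftype == "gene":
                gid = a.get("ID")
                if not gid:
                    raise ParseError(f"{path}: line {lineno}: gene without ID")
                genes[gid] = GeneModel(gid, chrom, start, end, strand)
            elif ftype == "mRNA":
                mid, parent = a.get("ID"), a.get("Parent")
                if not mid or not parent:
                    raise ParseError(f"{path}: line {lineno}: mRNA without ID/Parent")
                mrna_to_gene[mid] = parent
            elif ftype in ("exon", "five_prime_UTR"):
                pending.append((lineno, chrom, ftype, start, end, strand, a))
    for lineno, chrom, ftype, start, end, strand, a in pending:
        parent = a.get("Parent", "")
        gid = mrna_to_gene.get(parent, parent)
        if gid not in genes:
            raise ParseError(
                f"{path}: line {lineno}: {ftype} parent {parent!r} missing "
                "gene/mRNA hierarchy"
            )
        iv = GenomicInterval(chrom, start, end, strand)
        (genes[gid].exons if ftype == "exon" else genes[gid].utr5).append(iv)
    for g in genes.values():
        g.exons.sort(key=sort_key)
        g.utr5.sort(key=sort_key)
    return sorted(genes.values(), key=lambda g: (g.chrom, g.start, g.end, g.gene_id))


def write_gff3_genes(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models back to GFF3 (0-based half-open -> 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.gene_id)):
            mid = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\telekit\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\telekit\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={mid};Parent={g.gene_id}\n"
            )
            for iv in g.exons:
                fh.write(
                    f"{g.chrom}\telekit\texon\t{iv.start + 1}\t{iv.end}\t.\t{g.strand}\t.\tParent={mid}\n"
                )
            for iv in g.utr5:
                fh.write(
                    f"{g.chrom}\telekit\tfive_prime_UTR\t{iv.start + 1}\t{iv.end}\t.\t{g.strand}\t.\tParent={mid}\n"
                )


# ---------------------------------------------------------------------------
# CTSS tables


@dataclass
class CtssTable:
    """Per-position stranded CAGE 5'-end counts across samples.

    ``df`` columns: chrom, pos (0-based), strand, then one count column per
    sample named ``<tissue>_rep<k>``. (chrom, pos, strand) rows are unique;
    + and - records at the same position are distinct.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["chrom", "pos", "strand"]
        for col in required:
            if col not in self.df.columns:
                raise ValueError(f"CTSS table missing column {col!r}")
        if self.df.duplicated(subset=required).any():
            raise ValueError("duplicate (chrom, pos, strand) rows in CTSS table")
        for sample in self.samples:
            tissue, rep = parse_sample_id(sample)
            if rep < 1:
                raise ValueError(f"sample {sample!r}: replicate index must be >= 1")
            if (self.df[sample] < 0).any():
                raise ValueError(f"sample {sample!r}: negative counts")

    @property
    def samples(self) -> list[str]:
        return [c for c in self.df.columns if c not in ("chrom", "pos", "strand")]

    @property
    def tissues(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            t = parse_sample_id(s)[0]
            if t not in seen:
                seen.append(t)
        return seen

    def samples_for_tissue(self, tissue: str) -> list[str]:
        return [s for s in self.samples if parse_sample_id(s)[0] == tissue]

    def sorted(self) -> "CtssTable":
        df = self.df.sort_values(["chrom", "pos", "strand"], kind="mergesort")
        return CtssTable(df.reset_index(drop=True))


def parse_sample_id(sample: str) -> tuple[str, int]:
    """Split ``tissue_repN`` into (tissue, N)."""
    tissue, sep, rep = sample.rpartition("_rep")
    if not sep or not rep.isdigit():
        raise ValueError(f"sample id {sample!r} not of the form tissue_repN")
    return tissue, int(rep)


def read_ctss(path: str | Path) -> CtssTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    return CtssTable(df)


def write_ctss(table: CtssTable, path: str | Path) -> None:
    table.sorted().df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# TE annotations

TE_COLUMNS = [
    "te_id", "chrom", "start", "end", "strand", "superfamily", "family",
    "subfamily", "full_length", "ltr5_start", "ltr5_end", "ltr3_start", "ltr3_end",
]


@dataclass
class TeAnnotation:
    te_id: str
    interval: GenomicInterval
    superfamily: str
    family: str
    subfamily: str
    full_length: bool
    ltr5: Optional[GenomicInterval] = None
    ltr3: Optional[GenomicInterval] = None


def family_of_subfamily(subfamily: str) -> str:
    """``RLG_famc7.3`` -> ``RLG_famc7`` (subfamily suffix after the last dot)."""
    family, dot, _ = subfamily.rpartition(".")
    return family if dot else subfamily


def superfamily_of(subfamily: str) -> str:
    return subfamily.split("_", 1)[0]


def read_te_table(path: str | Path) -> list[TeAnnotation]:
    """Read the tab-delimited TE annotation table.

    Validates the nested naming (subfamily prefixed by family) and that
    full-length elements carry exactly two LTR sub-intervals inside their span.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in TE_COLUMNS[:9] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: TE table missing columns {missing}")
    out: list[TeAnnotation] = []
    for row in df.itertuples(index=False):
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand, row.te_id)
        subfam = str(row.subfamily)
        fam = str(row.family)
        if not subfam.startswith(fam):
            raise ValueError(
                f"{path}: subfamily {subfam!r} not prefixed by family {fam!r}"
            )
        full = bool(row.full_length)
        ltr5 = ltr3 = None
        if full:
            coords = [row.ltr5_start, row.ltr5_end, row.ltr3_start, row.ltr3_end]
            if any(pd.isna(c) for c in coords):
                raise ValueError(f"{path}: full-length element {row.te_id} missing LTR coords")
            ltr5 = GenomicInterval(row.chrom, int(row.ltr5_start), int(row.ltr5_end), row.strand)
            ltr3 = GenomicInterval(row.chrom, int(row.ltr3_start), int(row.ltr3_end), row.strand)
            for ltr in (ltr5, ltr3):
                if ltr.start < iv.start or ltr.end > iv.end:
                    raise ValueError(
                        f"{path}: LTR {ltr.start}-{ltr.end} outside element "
                        f"{row.te_id} span {iv.start}-{iv.end}"
                    )
        out.append(TeAnnotation(str(row.te_id), iv, str(row.superfamily), fam, subfam, full, ltr5, ltr3))
    return out


def write_te_table(tes: list[TeAnnotation], path: str | Path) -> None:
    rows = []
    for te in sorted(tes, key=lambda t: sort_key(t.interval)):
        rows.append({
            "te_id": te.te_id,
            "chrom": te.interval.chrom,
            "start": te.interval.start,
            "end": te.interval.end,
            "strand": te.interval.strand,
            "superfamily": te.superfamily,
            "family": te.family,
            "subfamily": te.subfamily,
            "full_length": int(te.full_length),
            "ltr5_start": te.ltr5.start if te.ltr5 else "",
            "ltr5_end": te.ltr5.end if te.ltr5 else "",
            "ltr3_start": te.ltr3.start if te.ltr3 else "",
            "ltr3_end": te.ltr3.end if te.ltr3 else "",
        })
    pd.DataFrame(rows, columns=TE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Methylation


@dataclass(frozen=True)
class MethylationRecord:
    chrom: str
    position: int
    context: str  # CG | CHG | CHH
    methylated_reads: int
    total_reads: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.context not in ("CG", "CHG", "CHH"):
            raise ValueError(f"invalid methylation context {self.context!r}")
        if not (0 <= self.methylated_reads <= self.total_reads):
            raise ValueError("methylated_reads must lie in [0, total_reads]")


def methylation_ratio(record: MethylationRecord, min_coverage: int = 3) -> Optional[float]:
    """mC / coverage, masked (None) below ``min_coverage`` reads.

    Positions covered by fewer than three reads are low-confidence and carry
    no ratio.
    """
    if record.total_reads < min_coverage:
        return None
    return record.methylated_reads / record.total_reads


def read_methylation(path: str | Path) -> list[MethylationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        MethylationRecord(r.chrom, int(r.position), r.context,
                          int(r.methylated_reads), int(r.total_reads), r.strand)
        for r in df.itertuples(index=False)
    ]


def write_methylation(records: list[MethylationRecord], path: str | Path) -> None:
    rows = [
        {"chrom": r.chrom, "position": r.position, "context": r.context,
         "methylated_reads": r.methylated_reads, "total_reads": r.total_reads,
         "strand": r.strand}
        for r in sorted(records, key=lambda r: (r.chrom, r.position, r.strand))
    ]
    pd.DataFrame(
        rows, columns=["chrom", "position", "context", "methylated_reads",
                       "total_reads", "strand"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")
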