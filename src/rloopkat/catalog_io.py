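"""Readers and writers for mutation catalogs, annotation and expression.

Conventions enforced at the I/O boundary and nowhere else:

* mutations are 1-based (VCF/MAF convention);
* all intervals are 0-based half-open (BED convention), so VCF position
  ``p`` corresponds to the interval ``[p-1, p)``;
* duplicate mutation records (same sample, chrom, pos, alt) are collapsed
  to a single record with a warning, which prevents artificial
  zero-length intermutational distances downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._reference import ReferenceGenome

CONSEQUENCES = ("nonsense", "splice_site", "frameshift_indel", "other", "unknown")

#: MAF Variant_Classification -> consequence class used by the
#: deleterious-mutation filter (stop codon, splice site, frameshift indel).
MAF_CONSEQUENCE_MAP = {
    "Nonsense_Mutation": "nonsense",
    "Splice_Site": "splice_site",
    "Frame_Shift_Del": "frameshift_indel",
    "Frame_Shift_Ins": "frameshift_indel",
}


@dataclass(frozen=True, order=True)
class MutationRecord:
    """One somatic variant.

    ``pos`` is the 1-based reference position of the first ref base.
    ``vaf`` is the variant allele frequency in [0, 1] when known.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: Optional[float] = field(default=None, compare=False)
    consequence: str = field(default="unknown", compare=False)
    gene_id: Optional[str] = field(default=None, compare=False)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.vaf is not None and not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")

    @property
    def is_sbs(self) -> bool:
        return len(self.ref) == 1 == len(self.alt)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    strand: str = "."

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tx: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        for ex in self.exons:
            if ex.start < self.tx.start or ex.end > self.tx.end:
                raise ValueError(f"gene {self.gene_id}: exon outside tx bounds")
        starts = [ex.start for ex in self.exons]
        ends = [ex.end for ex in self.exons]
        if any(s2 < e1 for e1, s2 in zip(ends, starts[1:])):
            raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")

    @property
    def exon_length_bp(self) -> int:
        return sum(len(ex) for ex in self.exons)

    @property
    def tx_length_bp(self) -> int:
        return len(self.tx)


@dataclass(frozen=True)
class SVBreakpoint:
    sample_id: str
    chrom: str
    pos: int  # 1-based

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("breakpoint pos must be >= 1")


@dataclass
class ExpressionTable:
    """Gene x sample expression matrix plus a per-gene normal baseline.

    ``values`` holds tumor samples; ``normal_baseline`` is the arithmetic
    mean over designated normal samples, defined for every gene in the
    matrix. Genes whose normal columns are all zero keep baseline 0 and
    are listed in ``zero_baseline_genes`` so downstream fold-change
    binning can report them.
    """

    values: pd.DataFrame
    normal_baseline: pd.Series

    def __post_init__(self):
        if (self.values.values < 0).any() or (self.normal_baseline.values < 0).any():
            raise ValueError("expression values must be nonnegative")
        missing = self.values.index.difference(self.normal_baseline.index)
        if len(missing):
            raise ValueError(
                f"baseline undefined for genes: {list(missing)[:5]} ...")
        self.normal_baseline = self.normal_baseline.loc[self.values.index]

    @property
    def zero_baseline_genes(self) -> list[str]:
        return list(self.normal_baseline.index[self.normal_baseline == 0])


# ---------------------------------------------------------------------------
# mutation catalogs

def _sorted_unique(records: Iterable[MutationRecord]) -> list[MutationRecord]:
    records = sorted(records, key=lambda r: (r.sample_id, r.chrom, r.pos, r.alt))
    out: list[MutationRecord] = []
    dropped = 0
    for rec in records:
        if out and (rec.sample_id, rec.chrom, rec.pos, rec.alt) == (
                out[-1].sample_id, out[-1].chrom, out[-1].pos, out[-1].alt):
            dropped += 1
            continue
        out.append(rec)
    if dropped:
        warnings.warn(f"collapsed {dropped} duplicate mutation records")
    return out


def _validate_against_reference(records: Sequence[MutationRecord],
                                reference: ReferenceGenome) -> None:
    for rec in records:
        if rec.chrom not in reference:
            raise ValueError(f"unknown chromosome {rec.chrom!r} "
                             f"({rec.sample_id} {rec.chrom}:{rec.pos})")
        if rec.is_sbs:
            base = reference.base(rec.chrom, rec.pos - 1)
            if base != rec.ref:
                raise ValueError(
                    f"ref mismatch at {rec.chrom}:{rec.pos} "
                    f"({rec.sample_id}): record has {rec.ref}, reference has {base}")


def read_mutations(path, format: str, reference: Optional[ReferenceGenome] = None,
                   sample_id: Optional[str] = None) -> list[MutationRecord]:
    """Read a somatic mutation catalog from VCF or MAF-like TSV.

    Parameters
    ----------
    path : str or Path
    format : {"vcf", "maf_tsv"}
    reference : ReferenceGenome, optional
        When given, every SBS ref allele is checked against the reference
        base at its position; a mismatch or unknown chromosome is a hard
        error naming the offending record.
    sample_id : str, optional
        Sample name for single-sample VCFs without a sample column;
        defaults to the file stem.

    Returns
    -------
    list of MutationRecord, sorted by (sample, chrom, pos), duplicates
    collapsed.
    """
    path = Path(path)
    if format == "vcf":
        records = _read_vcf(path, sample_id or path.stem.replace(".vcf", ""))
    elif format == "maf_tsv":
        records = _read_maf(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    records = _sorted_unique(records)
    if reference is not None:
        _validate_against_reference(records, reference)
    return records


def _read_vcf(path: Path, default_sample: str) -> list[MutationRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, pos, _id, ref, alts = fields[:5]
            info = fields[7] if len(fields) > 7 else "."
            kv = dict(item.split("=", 1) for item in info.split(";")
                      if "=" in item)
            sample = kv.get("SAMPLE", default_sample)
            vaf = float(kv["VAF"]) if "VAF" in kv else None
            gene = kv.get("GENE")
            for alt in alts.split(","):
                records.append(MutationRecord(
                    sample_id=sample, chrom=chrom, pos=int(pos),
                    ref=ref, alt=alt, vaf=vaf, gene_id=gene))
    return records


def _clean_cell(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and value != value):
        return None
    s = str(value).strip()
    return s if s and s != "NA" else None


def _read_maf(path: Path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    records = []
    for row in df.itertuples(index=False):
        d = {k: _clean_cell(v) for k, v in row._asdict().items()}
        vaf = None
        if d.get("VAF") is not None:
            vaf = float(d["VAF"])
        elif d.get("t_alt_count") and d.get("t_depth"):
            depth = float(d["t_depth"])
            vaf = float(d["t_alt_count"]) / depth if depth > 0 else None
        consequence = MAF_CONSEQUENCE_MAP.get(
            d.get("Variant_Classification") or "", "other")
        records.append(MutationRecord(
            sample_id=d["Tumor_Sample_Barcode"],
            chrom=d["Chromosome"],
            pos=int(d["Start_Position"]),
            ref=d["Reference_Allele"],
            alt=d["Tumor_Seq_Allele2"],
            vaf=vaf,
            consequence=consequence,
            gene_id=d.get("Hugo_Symbol")))
    return records


_MAF_CLASS = {"nonsense": "Nonsense_Mutation", "splice_site": "Splice_Site",
              "frameshift_indel": "Frame_Shift_Ins", "other": "Missense_Mutation",
              "unknown": "Missense_Mutation"}


def mutations_to_maf_frame(records: Sequence[MutationRecord]) -> pd.DataFrame:
    """MAF-like table readable back through read_mutations(format="maf_tsv")."""
    rows = []
    for r in records:
        cls = _MAF_CLASS[r.consequence]
        if r.consequence == "frameshift_indel" and len(r.ref) > len(r.alt):
            cls = "Frame_Shift_Del"
        rows.append((r.sample_id, r.chrom, r.pos, r.ref, r.alt, cls,
                     r.gene_id or "", "" if r.vaf is None else r.vaf))
    return pd.DataFrame(rows, columns=[
        "Tumor_Sample_Barcode", "Chromosome", "Start_Position",
        "Reference_Allele", "Tumor_Seq_Allele2", "Variant_Classification",
        "Hugo_Symbol", "VAF"])


def mutations_to_frame(records: Sequence[MutationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.sample_id, r.chrom, r.pos, r.ref, r.alt,
          np.nan if r.vaf is None else r.vaf, r.consequence, r.gene_id)
         for r in records],
        columns=["sample_id", "chrom", "pos", "ref", "alt",
                 "vaf", "consequence", "gene_id"])


# ---------------------------------------------------------------------------
# annotation

def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals per chromosome; names are dropped on merge."""
    out: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: iv.start)
        cur_s, cur_e, cur_name = ivs[0].start, ivs[0].end, ivs[0].name
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                if iv.end > cur_e:
                    cur_e = iv.end
                cur_name = None
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e, cur_name))
                cur_s, cur_e, cur_name = iv.start, iv.end, iv.name
        out.append(GenomicInterval(chrom, cur_s, cur_e, cur_name))
    return out


def read_bed(path) -> list[GenomicInterval]:
    """BED3+ -> intervals (0-based half-open, per BED)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            start, end = int(f[1]), int(f[2])
            if start >= end:
                raise ValueError(f"start >= end in BED line: {line.strip()!r}")
            name = f[3].strip() if len(f) > 3 else None
            strand = f[5].strip() if len(f) > 5 else "."
            out.append(GenomicInterval(f[0], start, end, name, strand))
    return out


def read_genes(path) -> list[GeneModel]:
    """Gene models from BED12 or a simplified TSV.

    The TSV form has a header with columns gene_id, chrom, strand,
    tx_start, tx_end, exon_starts, exon_ends (exon lists comma-separated,
    0-based half-open). BED12 is detected by the absence of a header and
    12 tab-separated columns.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("gene_id"):
        return _read_genes_tsv(path)
    return _read_genes_bed12(path)


def _read_genes_tsv(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    genes = []
    for row in df.itertuples(index=False):
        if row.strand not in ("+", "-"):
            raise ValueError(f"gene {row.gene_id}: missing or invalid strand")
        starts = [int(x) for x in str(row.exon_starts).rstrip(",").split(",")]
        ends = [int(x) for x in str(row.exon_ends).rstrip(",").split(",")]
        exons = tuple(GenomicInterval(row.chrom, s, e)
                      for s, e in zip(starts, ends))
        tx = GenomicInterval(row.chrom, int(row.tx_start), int(row.tx_end),
                             row.gene_id, row.strand)
        genes.append(GeneModel(row.gene_id, row.chrom, row.strand, tx, exons))
    return genes


def _read_genes_bed12(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError("BED12 gene file requires 12 columns")
            chrom, start, end, name, _score, strand = f[:6]
            if strand not in ("+", "-"):
                raise ValueError(f"gene {name}: missing strand in BED12")
            start, end = int(start), int(end)
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(GenomicInterval(chrom, start + o, start + o + s)
                          for o, s in zip(offsets, sizes))
            tx = GenomicInterval(chrom, start, end, name, strand)
            genes.append(GeneModel(name, chrom, strand, tx, exons))
    return genes


def read_sv_breakpoints(path) -> list[SVBreakpoint]:
    """TSV with header sample_id, chrom, pos (1-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    return [SVBreakpoint(r.sample_id, r.chrom, int(r.pos))
            for r in df.itertuples(index=False)]


def read_annotation(genes_path, rloops_path, sv_path):
    """Load gene models, merged R-loop intervals and SV breakpoints."""
    genes = read_genes(genes_path)
    rloops = merge_intervals(read_bed(rloops_path))
    svs = read_sv_breakpoints(sv_path)
    return genes, rloops, svs


# ---------------------------------------------------------------------------
# expression

def read_expression(path, normal_samples: Optional[Sequence[str]] = None
                    ) -> ExpressionTable:
    """TSV with gene_id in the first column and samples in the header.

    ``normal_samples`` designates baseline columns; by default any column
    whose name starts with "normal" is used. The baseline is the
    arithmetic mean over those columns per gene.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if normal_samples is None:
        normal_samples = [c for c in df.columns if c.lower().startswith("normal")]
    missing = set(normal_samples) - set(df.columns)
    if missing:
        raise ValueError(f"baseline undefined: normal columns {missing} absent")
    if not normal_samples:
        raise ValueError("baseline undefined: no normal columns designated")
    baseline = df[list(normal_samples)].mean(axis=1)
    tumor = df.drop(columns=list(normal_samples))
    return ExpressionTable(values=tumor, normal_baseline=baseline)


# ---------------------------------------------------------------------------
# results

def write_results(tables: dict[str, pd.DataFrame], out_dir) -> dict[str, Path]:
    """Write each table as ``<name>.tsv`` with a stable column order.

    Floats are written at full (round-trippable) precision so a
    write-then-read cycle reproduces every value exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.17g")
        paths[name] = p
    return paths


def read_result_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
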