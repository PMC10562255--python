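"""Self-contained synthetic tumor cohort with a planted-truth manifest.

The generator emulates the statistical structure of an APOBEC-mutagenized
breast-cancer cohort at desk scale: a random reference genome,
non-overlapping gene models, R-loop intervals biased toward gene 5' ends,
per-sample dispersed mutations with a tunable TCW C>T/C>G fraction,
strand-coordinated kataegic clusters with a tunable RTCA:YTCA mix and
coherent VAFs, structural-variant breakpoints, an expression table with
planted fold-change bins, and splice-factor / housekeeping gene labels.

Every random draw flows through one ``numpy.random.Generator`` seeded
from the config, so identical configs give bit-identical cohorts,
including the truth manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._reference import ReferenceGenome, motif_sites
from .catalog_io import (ExpressionTable, GeneModel, GenomicInterval,
                         MutationRecord, SVBreakpoint, mutations_to_frame)

import pandas as pd

#: Expression fold-change bins (G1..G7) and the approximate probability a
#: gene lands in each, shaped after the median per-bin gene counts of a
#: WES breast-tumor cohort (the middle bin dominates).
EXPRESSION_BIN_PROBS = {
    "G1": 0.115, "G2": 0.144, "G3": 0.620, "G4": 0.108,
    "G5": 0.008, "G6": 0.0036, "G7": 0.0034,
}
#: Fold-change ranges used to draw a value inside each planted bin.
EXPRESSION_BIN_FC = {
    "G2": (0.05, 0.8), "G3": (0.8, 1.2), "G4": (1.2, 4.0),
    "G5": (4.0, 8.0), "G6": (8.0, 16.0), "G7": (16.0, 64.0),
}


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions.

    ``apobec_fraction`` is the fraction of dispersed SBS forced onto
    genomic TCW cytosines as C>T or C>G. ``cluster_rtca_fraction`` is the
    per-member probability that an R-loop-planted cluster mutation sits
    in an RTCA (rather than YTCA) tetranucleotide; clusters planted
    outside R-loops draw TCW sites uniformly (motif-neutral).
    """

    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_length_bp: int = 5_000_000
    gc_fraction: float = 0.45
    # genes
    n_genes: int = 120
    gene_length_range: tuple[int, int] = (6_000, 20_000)
    exons_per_gene: tuple[int, int] = (2, 6)
    exon_fraction: float = 0.4
    allow_antisense_overlap: bool = False
    # R-loops
    rloop_count: int = 60
    rloop_length_bp: int = 800
    rloop_five_prime_bias: float = 0.8
    # cohort
    n_samples: int = 10
    dispersed_rate: float = 5.0  # mutations per Mbp, per sample (WGS-like)
    apobec_fraction: float = 0.2
    # clusters
    clusters_per_sample: int = 3
    cluster_size_range: tuple[int, int] = (5, 8)
    cluster_span_bp: int = 2_000
    cluster_rtca_fraction: float = 0.7
    cluster_vaf_sd: float = 0.02
    cluster_rloop_fraction: float = 0.17
    # SVs
    sv_per_sample: int = 5
    # gene sets
    n_splice_factor_genes: int = 10
    splice_factor_mut_prob: float = 0.3
    n_housekeeping_genes: int = 25
    # expression coupling: expected extra TCW mutations per top-bin gene
    expression_coupling: float = 2.0
    # per-gene probability of each fold-change bin (None = cohort-shaped)
    expression_bin_probs: Optional[dict[str, float]] = None

    def __post_init__(self):
        for name in ("gc_fraction", "apobec_fraction", "cluster_rtca_fraction",
                     "cluster_rloop_fraction", "rloop_five_prime_bias",
                     "splice_factor_mut_prob", "exon_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.dispersed_rate < 0 or self.expression_coupling < 0:
            raise ValueError("rates must be nonnegative")


@dataclass
class PlantedCluster:
    sample_id: str
    chrom: str
    positions: tuple[int, ...]  # 1-based, sorted
    rtca_flags: tuple[bool, ...]
    in_rloop: bool
    gene_id: Optional[str]
    pyr_strand: str

    @property
    def size(self) -> int:
        return len(self.positions)

    @property
    def span_bp(self) -> int:
        return self.positions[-1] - self.positions[0]


@dataclass
class SyntheticTruth:
    clusters: list[PlantedCluster]
    apobec_fraction: dict[str, float]  # per sample
    splice_factor_mutant: dict[str, bool]  # per sample
    gene_bins: dict[str, dict[str, str]]  # sample -> gene -> G1..G7
    splice_factor_gene_ids: list[str]
    housekeeping_gene_ids: list[str]
    coupled_mutation_counts: dict[str, int]  # per sample extra top-bin TCW

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(d, indent=1, default=str))


@dataclass
class SyntheticReference:
    reference: ReferenceGenome
    genes: list[GeneModel]
    rloops: list[GenomicInterval]
    breakpoints: list[SVBreakpoint]
    config: SyntheticConfig


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)
    return codes.tobytes().decode("ascii")


def _place_genes(rng: np.random.Generator, cfg: SyntheticConfig,
                 chroms: list[str]) -> list[GeneModel]:
    """Non-overlapping genes in equal slots with random jitter per slot."""
    per_chrom = int(np.ceil(cfg.n_genes / len(chroms)))
    slot = cfg.chrom_length_bp // per_chrom
    if slot <= cfg.gene_length_range[1] + 10:
        raise ValueError("requested genes do not fit in the genome")
    genes = []
    gid = 0
    for chrom in chroms:
        for k in range(per_chrom):
            if gid >= cfg.n_genes:
                break
            length = int(rng.integers(*cfg.gene_length_range))
            lo = k * slot
            start = int(rng.integers(lo, lo + slot - length))
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(cfg.exons_per_gene[0],
                                    cfg.exons_per_gene[1] + 1))
            exons = _place_exons(rng, start, start + length, n_ex,
                                 cfg.exon_fraction, chrom)
            tx = GenomicInterval(chrom, start, start + length,
                                 f"gene{gid:04d}", strand)
            genes.append(GeneModel(f"gene{gid:04d}", chrom, strand, tx, exons))
            gid += 1
    return genes


def _place_exons(rng, start, end, n_ex, exon_fraction, chrom):
    length = end - start
    exon_total = max(n_ex, int(length * exon_fraction))
    sizes = rng.multinomial(exon_total - n_ex, np.ones(n_ex) / n_ex) + 1
    gap_total = length - exon_total
    gaps = rng.multinomial(gap_total, np.ones(n_ex + 1) / (n_ex + 1))
    exons, cur = [], start
    for g, s in zip(gaps, sizes):
        cur += int(g)
        exons.append(GenomicInterval(chrom, cur, cur + int(s)))
        cur += int(s)
    return tuple(exons)


def _place_rloops(rng, cfg: SyntheticConfig,
                  genes: Sequence[GeneModel]) -> list[GenomicInterval]:
    """R-loop intervals inside genes, biased toward the 5' end."""
    rloops = []
    gene_idx = rng.integers(0, len(genes), size=cfg.rloop_count)
    for i, gi in enumerate(gene_idx):
        g = genes[int(gi)]
        room = len(g.tx) - cfg.rloop_length_bp
        if room <= 0:
            frac = 0.0
        elif rng.random() < cfg.rloop_five_prime_bias:
            frac = float(rng.beta(1.0, 6.0))  # hugs the 5' end
        else:
            frac = float(rng.random())
        offset = int(frac * max(room, 0))
        if g.strand == "+":
            s = g.tx.start + offset
        else:
            s = g.tx.end - offset - cfg.rloop_length_bp
        s = max(g.tx.start, min(s, g.tx.end - cfg.rloop_length_bp))
        rloops.append(GenomicInterval(g.chrom, s, s + cfg.rloop_length_bp,
                                      f"rloop{i:04d}", "."))
    return rloops


def generate_reference(config: SyntheticConfig) -> SyntheticReference:
    """Reference genome, gene models, R-loop intervals and SV breakpoints.

    Base composition follows ``gc_fraction`` binomially (within +-2% for
    chromosomes of 1 Mbp and up); genes never overlap; each R-loop lies
    inside its host gene with the configured 5' placement bias.
    """
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    seqs = {c: _random_sequence(rng, config.chrom_length_bp,
                                config.gc_fraction) for c in chroms}
    reference = ReferenceGenome(seqs)
    genes = _place_genes(rng, config, chroms)
    rloops = _place_rloops(rng, config, genes)
    breakpoints = []
    for s in range(config.n_samples):
        sid = f"S{s:03d}"
        for _ in range(config.sv_per_sample):
            chrom = chroms[int(rng.integers(len(chroms)))]
            breakpoints.append(SVBreakpoint(
                sid, chrom, int(rng.integers(1, config.chrom_length_bp + 1))))
    return SyntheticReference(reference, genes, rloops, breakpoints, config)


# ---------------------------------------------------------------------------
# cohort generation

class _SiteIndex:
    """Per-chromosome motif site lists, pyrimidine strand resolved."""

    def __init__(self, reference: ReferenceGenome):
        self.tcw: dict[str, dict[str, np.ndarray]] = {}
        self.rtca: dict[str, dict[str, np.ndarray]] = {}
        self.ytca: dict[str, dict[str, np.ndarray]] = {}
        for chrom in reference.chroms:
            seq = reference.sequence(chrom)
            for store, motif in ((self.tcw, "TCW"), (self.rtca, "RTCA"),
                                 (self.ytca, "YTCA")):
                plus, minus = motif_sites(seq, motif)
                store[chrom] = {"+": plus, "-": minus}

    def in_window(self, store, chrom, strand, start0, end0) -> np.ndarray:
        sites = store[chrom][strand]
        lo = np.searchsorted(sites, start0)
        hi = np.searchsorted(sites, end0)
        return sites[lo:hi]


def _alt_for(rng, ref_base: str) -> str:
    others = [b for b in "ACGT" if b != ref_base]
    return others[int(rng.integers(3))]


def _apobec_alt(rng, pyr_strand: str) -> str:
    """Alt allele of a TCW C>T / C>G mutation, on the reference strand."""
    pyr_alt = "T" if rng.random() < 0.5 else "G"
    if pyr_strand == "+":
        return pyr_alt
    return {"T": "A", "G": "C"}[pyr_alt]


def _gene_cover_maps(genes: Sequence[GeneModel]):
    """chrom -> sorted (start, end, strand, gene_id) arrays for lookup."""
    by_chrom: dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(
            (g.tx.start, g.tx.end, g.strand, g.gene_id))
    return {c: sorted(v) for c, v in by_chrom.items()}


def _covering_gene(cover, chrom, pos0):
    for s, e, strand, gid in cover.get(chrom, ()):
        if s <= pos0 < e:
            return gid, strand
        if s > pos0:
            break
    return None, None


def generate_cohort(config: SyntheticConfig, ref: SyntheticReference
                    ) -> tuple[list[MutationRecord], ExpressionTable, SyntheticTruth]:
    """Mutation catalog, expression table and truth manifest.

    Dispersed mutations are uniform over the genome except for the
    ``apobec_fraction`` planted on TCW cytosines; clusters draw one
    founder VAF and jitter members by ``cluster_vaf_sd``; extra TCW
    mutations are planted in top-expression-bin genes at rate
    ``expression_coupling`` per gene so the expression association is
    recoverable.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    reference, genes = ref.reference, ref.genes
    sites = _SiteIndex(reference)
    cover = _gene_cover_maps(genes)
    chroms = reference.chroms
    chrom_len = {c: reference.length(c) for c in chroms}
    genome_mbp = sum(chrom_len.values()) / 1e6

    n_tcw_total = sum(len(sites.tcw[c]["+"]) + len(sites.tcw[c]["-"])
                      for c in chroms)
    if config.apobec_fraction > 0 and n_tcw_total == 0:
        raise ValueError("apobec_fraction > 0 but the genome has no TCW site")

    rloop_host = {}
    for rl in ref.rloops:
        gid, strand = _covering_gene(cover, rl.chrom, rl.start)
        if gid is not None:
            rloop_host[rl.name] = (rl, gid, strand)

    samples = [f"S{s:03d}" for s in range(config.n_samples)]
    records: list[MutationRecord] = []
    truth_clusters: list[PlantedCluster] = []
    sf_genes = [g.gene_id for g in genes[: config.n_splice_factor_genes]]
    hk_genes = [g.gene_id for g in
                genes[config.n_splice_factor_genes:
                      config.n_splice_factor_genes + config.n_housekeeping_genes]]
    gene_by_id = {g.gene_id: g for g in genes}

    # expression: per-gene baseline shared by the cohort
    baseline = pd.Series(
        np.round(np.exp(rng.normal(1.0, 1.0, size=len(genes))), 4),
        index=[g.gene_id for g in genes])
    probs = config.expression_bin_probs or EXPRESSION_BIN_PROBS
    bin_names = list(probs)
    bin_p = np.array(list(probs.values()))
    bin_p = bin_p / bin_p.sum()

    expr_cols = {}
    gene_bins: dict[str, dict[str, str]] = {}
    sf_mutant: dict[str, bool] = {}
    coupled_counts: dict[str, int] = {}

    for sid in samples:
        used: set[tuple[str, int]] = set()
        sample_records: list[MutationRecord] = []

        def add(rec: MutationRecord) -> bool:
            key = (rec.chrom, rec.pos)
            if key in used:
                return False
            used.add(key)
            sample_records.append(rec)
            return True

        # --- planted clusters ----------------------------------------
        for _ in range(config.clusters_per_sample):
            planted = _plant_cluster(rng, config, sid, ref, sites,
                                     rloop_host, cover, used)
            if planted is None:
                continue
            cluster, recs = planted
            for r in recs:
                add(r)
            truth_clusters.append(cluster)

        # --- expression bins and coupling ----------------------------
        bins = {g.gene_id: bin_names[int(b)]
                for g, b in zip(genes, rng.choice(len(bin_names),
                                                  size=len(genes), p=bin_p))}
        gene_bins[sid] = bins
        tumor_vals = {}
        for g in genes:
            b = bins[g.gene_id]
            if b == "G1":
                tumor_vals[g.gene_id] = 0.0
            else:
                lo, hi = EXPRESSION_BIN_FC[b]
                tumor_vals[g.gene_id] = round(
                    baseline[g.gene_id] * rng.uniform(lo, hi), 4)
        expr_cols[sid] = tumor_vals

        n_coupled = 0
        if config.expression_coupling > 0:
            for g in genes:
                if bins[g.gene_id] != "G7":
                    continue
                extra = int(rng.poisson(config.expression_coupling))
                for _ in range(extra):
                    strand = "+" if rng.random() < 0.5 else "-"
                    pool = sites.in_window(sites.tcw, g.chrom, strand,
                                           g.tx.start, g.tx.end)
                    if len(pool) == 0:
                        continue
                    pos0 = int(pool[int(rng.integers(len(pool)))])
                    rec = MutationRecord(
                        sid, g.chrom, pos0 + 1,
                        reference.base(g.chrom, pos0),
                        _apobec_alt(rng, strand),
                        vaf=round(float(rng.uniform(0.1, 0.9)), 4),
                        gene_id=g.gene_id)
                    if add(rec):
                        n_coupled += 1
        coupled_counts[sid] = n_coupled

        # --- dispersed mutations --------------------------------------
        n_disp = int(round(config.dispersed_rate * genome_mbp))
        n_apo = int(round(config.apobec_fraction * n_disp))
        placed = 0
        while placed < n_apo:
            chrom = chroms[int(rng.integers(len(chroms)))]
            strand = "+" if rng.random() < 0.5 else "-"
            pool = sites.tcw[chrom][strand]
            if len(pool) == 0:
                continue
            pos0 = int(pool[int(rng.integers(len(pool)))])
            gid, _ = _covering_gene(cover, chrom, pos0)
            rec = MutationRecord(
                sid, chrom, pos0 + 1, reference.base(chrom, pos0),
                _apobec_alt(rng, strand),
                vaf=round(float(rng.uniform(0.1, 0.9)), 4), gene_id=gid)
            if add(rec):
                placed += 1
        placed = 0
        while placed < n_disp - n_apo:
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos0 = int(rng.integers(2, chrom_len[chrom] - 2))
            base = reference.base(chrom, pos0)
            if base not in "ACGT":
                continue
            gid, _ = _covering_gene(cover, chrom, pos0)
            rec = MutationRecord(
                sid, chrom, pos0 + 1, base, _alt_for(rng, base),
                vaf=round(float(rng.uniform(0.1, 0.9)), 4), gene_id=gid)
            if add(rec):
                placed += 1

        # --- splice-factor deleterious mutations ----------------------
        mutant = bool(rng.random() < config.splice_factor_mut_prob)
        sf_mutant[sid] = mutant
        if mutant:
            n_hit = int(rng.integers(1, 3))
            for gid in rng.choice(sf_genes, size=min(n_hit, len(sf_genes)),
                                  replace=False):
                g = gene_by_id[str(gid)]
                pos0 = int(rng.integers(g.tx.start + 2, g.tx.end - 2))
                base = reference.base(g.chrom, pos0)
                if base not in "ACGT":
                    continue
                kind = ["nonsense", "splice_site", "frameshift_indel"][
                    int(rng.integers(3))]
                if kind == "frameshift_indel":
                    rec = MutationRecord(sid, g.chrom, pos0 + 1, base,
                                         base + "A", consequence=kind,
                                         gene_id=g.gene_id)
                else:
                    rec = MutationRecord(sid, g.chrom, pos0 + 1, base,
                                         _alt_for(rng, base),
                                         consequence=kind, gene_id=g.gene_id)
                add(rec)

        records.extend(sample_records)

    records.sort(key=lambda r: (r.sample_id, r.chrom, r.pos, r.alt))
    expr = pd.DataFrame(expr_cols).loc[baseline.index]
    table = ExpressionTable(values=expr, normal_baseline=baseline)
    truth = SyntheticTruth(
        clusters=truth_clusters,
        apobec_fraction={sid: config.apobec_fraction for sid in samples},
        splice_factor_mutant=sf_mutant,
        gene_bins=gene_bins,
        splice_factor_gene_ids=sf_genes,
        housekeeping_gene_ids=hk_genes,
        coupled_mutation_counts=coupled_counts)
    return records, table, truth


def _plant_cluster(rng, cfg: SyntheticConfig, sid: str,
                   ref: SyntheticReference, sites: "_SiteIndex",
                   rloop_host: dict, cover, used: set):
    """One strand-coordinated cluster; returns (PlantedCluster, records).

    R-loop clusters sit on the host gene's coding strand and mix RTCA and
    YTCA sites per ``cluster_rtca_fraction``; elsewhere a random window
    and strand are chosen and TCW sites are drawn motif-neutrally.
    """
    reference = ref.reference
    size = int(rng.integers(cfg.cluster_size_range[0],
                            cfg.cluster_size_range[1] + 1))
    in_rloop = (rng.random() < cfg.cluster_rloop_fraction) and rloop_host

    for _attempt in range(50):
        if in_rloop:
            name = list(rloop_host)[int(rng.integers(len(rloop_host)))]
            rl, gid, strand = rloop_host[name]
            lo, hi = rl.start, rl.end
            rtca_pool = sites.in_window(sites.rtca, rl.chrom, strand, lo, hi)
            ytca_pool = sites.in_window(sites.ytca, rl.chrom, strand, lo, hi)
            tcw_pool = sites.in_window(sites.tcw, rl.chrom, strand, lo, hi)
            chrom = rl.chrom
            chosen: list[tuple[int, bool]] = []
            taken: set[int] = set()
            ok = True
            for _ in range(size):
                want_rtca = rng.random() < cfg.cluster_rtca_fraction
                pool = rtca_pool if want_rtca else ytca_pool
                pool = [p for p in pool if p not in taken]
                if not pool:
                    pool = [p for p in tcw_pool if p not in taken]
                    want_rtca = False
                if not pool:
                    ok = False
                    break
                p = int(pool[int(rng.integers(len(pool)))])
                taken.add(p)
                chosen.append((p, bool(want_rtca)))
            if not ok:
                continue
        else:
            chrom = reference.chroms[int(rng.integers(len(reference.chroms)))]
            strand = "+" if rng.random() < 0.5 else "-"
            start0 = int(rng.integers(0, reference.length(chrom)
                                      - cfg.cluster_span_bp))
            pool = sites.in_window(sites.tcw, chrom, strand, start0,
                                   start0 + cfg.cluster_span_bp)
            pool = [p for p in pool if (chrom, int(p) + 1) not in used]
            if len(pool) < size:
                continue
            picks = rng.choice(len(pool), size=size, replace=False)
            rtca_all = set(sites.in_window(sites.rtca, chrom, strand, start0,
                                           start0 + cfg.cluster_span_bp))
            chosen = [(int(pool[int(i)]), int(pool[int(i)]) in rtca_all)
                      for i in picks]
            gid = None

        positions0 = sorted(p for p, _ in chosen)
        if positions0[-1] - positions0[0] > cfg.cluster_span_bp:
            continue
        if any((chrom, p + 1) in used for p in positions0):
            continue
        founder = float(rng.uniform(0.2, 0.6))
        flags = dict(chosen)
        recs = []
        for p in positions0:
            vaf = float(np.clip(founder + rng.normal(0, cfg.cluster_vaf_sd),
                                0.01, 0.99))
            recs.append(MutationRecord(
                sid, chrom, p + 1, reference.base(chrom, p),
                _apobec_alt(rng, strand), vaf=round(vaf, 4),
                gene_id=gid if in_rloop else _covering_gene(cover, chrom, p)[0]))
        cluster = PlantedCluster(
            sample_id=sid, chrom=chrom,
            positions=tuple(p + 1 for p in positions0),
            rtca_flags=tuple(bool(flags[p]) for p in positions0),
            in_rloop=bool(in_rloop), gene_id=gid if in_rloop else None,
            pyr_strand=strand)
        return cluster, recs
    return None


# ---------------------------------------------------------------------------
# on-disk emission (CLI)

def write_cohort(out_dir, ref: SyntheticReference,
                 records: Sequence[MutationRecord],
                 expression: ExpressionTable, truth: SyntheticTruth) -> None:
    """Emit FASTA + gene/R-loop BED-style files + TSVs + truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref.reference.write_fasta(out / "reference.fa")
    with open(out / "genes.tsv", "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttx_start\ttx_end\t"
                 "exon_starts\texon_ends\n")
        for g in ref.genes:
            fh.write("\t".join([
                g.gene_id, g.chrom, g.strand, str(g.tx.start), str(g.tx.end),
                ",".join(str(e.start) for e in g.exons),
                ",".join(str(e.end) for e in g.exons)]) + "\n")
    with open(out / "rloops.bed", "w") as fh:
        for rl in ref.rloops:
            fh.write(f"{rl.chrom}\t{rl.start}\t{rl.end}\t{rl.name}\n")
    pd.DataFrame([(b.sample_id, b.chrom, b.pos) for b in ref.breakpoints],
                 columns=["sample_id", "chrom", "pos"]).to_csv(
        out / "sv_breakpoints.tsv", sep="\t", index=False)
    from .catalog_io import mutations_to_maf_frame
    mutations_to_maf_frame(records).to_csv(out / "mutations.tsv", sep="\t",
                                           index=False)
    expr = expression.values.copy()
    expr.insert(0, "normal_mean", expression.normal_baseline)
    expr.to_csv(out / "expression.tsv", sep="\t", index_label="gene_id")
    truth.to_json(out / "truth.json")


def simulate(config: SyntheticConfig):
    """Convenience: reference + cohort in one call."""
    ref = generate_reference(config)
    records, expression, truth = generate_cohort(config, ref)
    return ref, records, expression, truth
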