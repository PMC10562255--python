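"""Cohort-level association analyses.

Expression fold-change binning with per-megabase APOBEC mutation rates,
pairwise Welch t-tests between expression groups, transcriptional
strand-bias tests, the deleterious-mutation filter, splice-factor
contingency statistics and a resampling null over housekeeping gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog_io import ExpressionTable, GeneModel, MutationRecord
from .context_engine import PyrimidineContext, classify_motif

EXPRESSION_GROUPS = ("G1", "G2", "G3", "G4", "G5", "G6", "G7")
DELETERIOUS = ("nonsense", "splice_site", "frameshift_indel")


def fold_change_bins(expression: ExpressionTable, sample: str
                     ) -> tuple[dict[str, str], list[str]]:
    """Seven fold-change bins of one tumor against the normal baseline.

    G1: tumor expression 0; G2: 0 < FC < 0.8; G3: 0.8 <= FC <= 1.2;
    G4: 1.2 < FC <= 4; G5: 4 < FC <= 8; G6: 8 < FC <= 16; G7: FC > 16.
    Genes with a zero baseline but nonzero tumor value have no defined FC
    and are returned separately.
    """
    tumor = expression.values[sample]
    baseline = expression.normal_baseline
    bins: dict[str, str] = {}
    undefined: list[str] = []
    for gene, t in tumor.items():
        if t == 0:
            bins[gene] = "G1"
            continue
        b = baseline[gene]
        if b == 0:
            undefined.append(gene)
            continue
        fc = t / b
        if fc < 0.8:
            bins[gene] = "G2"
        elif fc <= 1.2:
            bins[gene] = "G3"
        elif fc <= 4:
            bins[gene] = "G4"
        elif fc <= 8:
            bins[gene] = "G5"
        elif fc <= 16:
            bins[gene] = "G6"
        else:
            bins[gene] = "G7"
    return bins, undefined


def _is_apobec_tcw(ctx: PyrimidineContext) -> bool:
    return ctx.is_apobec_class and classify_motif(ctx).is_TCW


def mutation_rate_per_group(contexts: Sequence[PyrimidineContext],
                            gene_bins: dict[str, str],
                            genes: Sequence[GeneModel],
                            sample_id: str,
                            exonic_only: bool = False) -> pd.DataFrame:
    """TCW C>T/C>G mutations per megabase of exon, per expression group.

    Mutations anywhere in a gene body count toward that gene's group
    (restrict to exons with ``exonic_only``); the denominator is always
    the summed exon length of the group's genes. Groups without exonic
    territory get a missing rate.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    exon_mbp = {grp: 0.0 for grp in EXPRESSION_GROUPS}
    for gene_id, grp in gene_bins.items():
        g = gene_by_id.get(gene_id)
        if g is not None:
            exon_mbp[grp] += g.exon_length_bp / 1e6

    cover: dict[str, list[tuple[int, int, str]]] = {}
    for gene_id in gene_bins:
        g = gene_by_id.get(gene_id)
        if g is None:
            continue
        ivs = g.exons if exonic_only else (g.tx,)
        for iv in ivs:
            cover.setdefault(g.chrom, []).append((iv.start, iv.end, g.gene_id))
    for c in cover:
        cover[c].sort()

    counts = {grp: 0 for grp in EXPRESSION_GROUPS}
    for ctx in contexts:
        if not _is_apobec_tcw(ctx):
            continue
        pos0 = ctx.pos - 1
        for s, e, gid in cover.get(ctx.chrom, ()):
            if s > pos0:
                break
            if pos0 < e:
                counts[gene_bins[gid]] += 1
                break

    rows = []
    for grp in EXPRESSION_GROUPS:
        mbp = exon_mbp[grp]
        rate = counts[grp] / mbp if mbp > 0 else np.nan
        rows.append((sample_id, grp, counts[grp], mbp, rate))
    return pd.DataFrame(rows, columns=["sample_id", "group", "n_tcw_mut",
                                       "exon_mbp", "rate"])


def group_comparisons(rates: pd.DataFrame) -> pd.DataFrame:
    """Welch t-tests for every lowest-three x highest-four group pair.

    ``rates`` is the concatenation of per-sample outputs of
    :func:`mutation_rate_per_group`. Twelve comparisons are emitted with
    BH correction within the family. Degenerate pairs (no variance in
    either group) get p = 1 when the means agree and p = 0 otherwise,
    flagged in the ``degenerate`` column.
    """
    low = ("G1", "G2", "G3")
    high = ("G4", "G5", "G6", "G7")
    rows = []
    for lo in low:
        for hi in high:
            a = rates.loc[(rates.group == lo) & rates.rate.notna(), "rate"].to_numpy()
            b = rates.loc[(rates.group == hi) & rates.rate.notna(), "rate"].to_numpy()
            if len(a) < 2 or len(b) < 2:
                rows.append((lo, hi, len(a), len(b), np.nan, np.nan, True))
                continue
            if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
                p = 1.0 if a.mean() == b.mean() else 0.0
                rows.append((lo, hi, len(a), len(b), np.nan, p, True))
                continue
            t, p = stats.ttest_ind(a, b, equal_var=False)
            rows.append((lo, hi, len(a), len(b), float(t), float(p), False))
    df = pd.DataFrame(rows, columns=["low_group", "high_group", "n_low",
                                     "n_high", "t", "p", "degenerate"])
    mask = df.p.notna()
    df["bh_q"] = np.nan
    if mask.any():
        _, q, _, _ = multipletests(df.loc[mask, "p"], method="fdr_bh")
        df.loc[mask, "bh_q"] = q
    return df


def quartile_bins(baseline: pd.Series) -> dict[str, str]:
    """Five baseline-expression groups: Exp = 0 plus quartiles.

    Group "Q0" holds nonexpressed genes; the remaining genes are split at
    the quartile edges of the expressed baseline values into Q1..Q4.
    """
    expressed = baseline[baseline > 0]
    if len(expressed) < 4:
        raise ValueError("need at least 4 expressed genes for quartiles")
    edges = np.quantile(expressed.to_numpy(), [0.25, 0.5, 0.75])
    bins: dict[str, str] = {}
    for gene, v in baseline.items():
        if v == 0:
            bins[gene] = "Q0"
        else:
            bins[gene] = f"Q{int(np.searchsorted(edges, v, side='left')) + 1}"
    return bins


def quartile_group_statistics(contexts: Sequence[PyrimidineContext],
                              bins: dict[str, str],
                              genes: Sequence[GeneModel],
                              sample_id: str) -> pd.DataFrame:
    """The three per-group statistics of the quartile analysis.

    Per group: (1) the TCW C>T/C>G mutation count, (2) that count divided
    by the sample's total SBS count and (3) the count per megabase of
    total gene body (exons plus introns, i.e. the tx span).
    """
    gene_by_id = {g.gene_id: g for g in genes}
    groups = ("Q0", "Q1", "Q2", "Q3", "Q4")
    body_mbp = {grp: 0.0 for grp in groups}
    for gene_id, grp in bins.items():
        g = gene_by_id.get(gene_id)
        if g is not None:
            body_mbp[grp] += g.tx_length_bp / 1e6

    cover: dict[str, list[tuple[int, int, str]]] = {}
    for gene_id in bins:
        g = gene_by_id.get(gene_id)
        if g is not None:
            cover.setdefault(g.chrom, []).append((g.tx.start, g.tx.end,
                                                  g.gene_id))
    for c in cover:
        cover[c].sort()

    counts = {grp: 0 for grp in groups}
    total_sbs = len(contexts)
    for ctx in contexts:
        if not _is_apobec_tcw(ctx):
            continue
        pos0 = ctx.pos - 1
        for s, e, gid in cover.get(ctx.chrom, ()):
            if s > pos0:
                break
            if pos0 < e:
                counts[bins[gid]] += 1
                break
    rows = []
    for grp in groups:
        n = counts[grp]
        rows.append((sample_id, grp, n,
                     n / total_sbs if total_sbs else np.nan,
                     n / body_mbp[grp] if body_mbp[grp] > 0 else np.nan))
    return pd.DataFrame(rows, columns=["sample_id", "group", "n_tcw_mut",
                                       "fraction_of_sbs", "per_mbp_gene_body"])


def strand_bias_test(nts_counts: Sequence[int], ts_counts: Sequence[int]
                     ) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum on per-tumor NTS vs TS mutation counts.

    Returns (statistic, p). Identical or all-zero inputs give p = 1.
    """
    a = np.asarray(nts_counts, dtype=float)
    b = np.asarray(ts_counts, dtype=float)
    if len(a) == 0 or len(b) == 0:
        return float("nan"), 1.0
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(len(a) * len(b) / 2), 1.0
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(u), float(p)


def per_tumor_strand_counts(contexts_by_sample: dict[str, list[PyrimidineContext]],
                            labels_by_sample: dict[str, Sequence[str]],
                            gene_sets: Optional[dict[str, set]] = None,
                            gene_of: Optional[dict] = None) -> pd.DataFrame:
    """Per-tumor NTS and TS counts of TCW C>T/C>G mutations.

    ``labels_by_sample[sid][i]`` is the region label of
    ``contexts_by_sample[sid][i]`` (from rloop_association). When
    ``gene_sets``/``gene_of`` restrict to a gene group, only mutations in
    those genes count.
    """
    rows = []
    for sid, ctxs in sorted(contexts_by_sample.items()):
        labels = labels_by_sample[sid]
        nts = ts = 0
        for ctx, lab in zip(ctxs, labels):
            if not _is_apobec_tcw(ctx):
                continue
            if gene_sets is not None and gene_of is not None:
                gid = gene_of.get((sid, ctx.chrom, ctx.pos))
                if gid is None or not any(gid in s for s in gene_sets.values()):
                    continue
            if lab == "NTS":
                nts += 1
            elif lab == "TS":
                ts += 1
        rows.append((sid, nts, ts))
    return pd.DataFrame(rows, columns=["sample_id", "nts", "ts"])


def deleterious_filter(mutations: Sequence[MutationRecord]
                       ) -> tuple[list[MutationRecord], int]:
    """Keep stop-codon, splice-site and frameshift-indel mutations.

    Returns (kept records, count of records with unknown consequence).
    """
    kept = [m for m in mutations if m.consequence in DELETERIOUS]
    n_unknown = sum(1 for m in mutations if m.consequence == "unknown")
    return kept, n_unknown


@dataclass
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    p: float
    percent_group1: float
    percent_group2: float


@dataclass
class SpliceFactorAssociation:
    apobec_by_sf: Optional[ContingencyResult]
    rtcw_absent_by_sf: Optional[ContingencyResult]
    apobec_fraction_t: Optional[tuple[float, float]]  # (t, p) Welch
    burden_t: Optional[tuple[float, float]]
    sf_mutant_samples: list[str] = field(default_factory=list)


def _two_sided_fisher(table) -> float:
    return float(stats.fisher_exact(np.asarray(table),
                                    alternative="two-sided").pvalue)


def splice_factor_association(mutations: Sequence[MutationRecord],
                              splice_genes: set[str],
                              apobec_positive: dict[str, bool],
                              contexts_by_sample: dict[str, list[PyrimidineContext]]
                              ) -> SpliceFactorAssociation:
    """Contingency and burden contrasts between splice-factor groups.

    A tumor is splice-factor mutant when it carries a deleterious
    mutation in the gene set. Three results: (i) two-sided Fisher on
    APOBEC-positive x SF-mutant; (ii) among APOBEC-positive tumors,
    two-sided Fisher on RTCW-absence x SF-mutant; (iii) Welch t-tests on
    the per-tumor APOBEC-attributed fraction and on total burden.
    """
    samples = sorted(apobec_positive)
    deleterious, _ = deleterious_filter(mutations)
    sf_mutant = {s: False for s in samples}
    for m in deleterious:
        if m.gene_id in splice_genes and m.sample_id in sf_mutant:
            sf_mutant[m.sample_id] = True

    def table_for(flag: dict[str, bool], universe: Sequence[str]):
        a = sum(1 for s in universe if sf_mutant[s] and flag[s])
        b = sum(1 for s in universe if sf_mutant[s] and not flag[s])
        c = sum(1 for s in universe if not sf_mutant[s] and flag[s])
        d = sum(1 for s in universe if not sf_mutant[s] and not flag[s])
        return ((a, b), (c, d))

    result_i = None
    if any(sf_mutant.values()) and not all(sf_mutant.values()):
        t = table_for(apobec_positive, samples)
        (a, b), (c, d) = t
        result_i = ContingencyResult(
            t, _two_sided_fisher(t),
            percent_group1=100 * a / (a + b) if a + b else float("nan"),
            percent_group2=100 * c / (c + d) if c + d else float("nan"))

    rtcw_present = {}
    for s in samples:
        present = any(
            ctx.is_apobec_class and classify_motif(ctx).is_RTCW
            for ctx in contexts_by_sample.get(s, []))
        rtcw_present[s] = present
    pos_samples = [s for s in samples if apobec_positive[s]]
    result_ii = None
    if (pos_samples and any(sf_mutant[s] for s in pos_samples)
            and not all(sf_mutant[s] for s in pos_samples)):
        rtcw_absent = {s: not rtcw_present[s] for s in pos_samples}
        t = table_for(rtcw_absent, pos_samples)
        (a, b), (c, d) = t
        result_ii = ContingencyResult(
            t, _two_sided_fisher(t),
            percent_group1=100 * a / (a + b) if a + b else float("nan"),
            percent_group2=100 * c / (c + d) if c + d else float("nan"))

    burden = {s: 0 for s in samples}
    tcw = {s: 0 for s in samples}
    for s, ctxs in contexts_by_sample.items():
        if s not in burden:
            continue
        burden[s] = len(ctxs)
        tcw[s] = sum(1 for ctx in ctxs if _is_apobec_tcw(ctx))

    def welch(values: dict[str, float]):
        a = np.array([values[s] for s in samples if sf_mutant[s]], dtype=float)
        b = np.array([values[s] for s in samples if not sf_mutant[s]],
                     dtype=float)
        if len(a) < 2 or len(b) < 2:
            return None
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return float(t), float(p)

    frac = {s: (tcw[s] / burden[s] if burden[s] else 0.0) for s in samples}
    return SpliceFactorAssociation(
        apobec_by_sf=result_i,
        rtcw_absent_by_sf=result_ii,
        apobec_fraction_t=welch(frac),
        burden_t=welch({s: float(b) for s, b in burden.items()}),
        sf_mutant_samples=[s for s in samples if sf_mutant[s]])


@dataclass
class HousekeepingNull:
    iterations: int
    k: int
    mutated_genes: np.ndarray  # per-iteration counts
    mutated_tumors: np.ndarray
    fisher_p: np.ndarray
    bh_q: np.ndarray

    @property
    def summary(self) -> dict[str, float]:
        mg, mt = self.mutated_genes, self.mutated_tumors
        return {
            "median_mutated_genes": float(np.median(mg)),
            "min_mutated_genes": float(mg.min()),
            "max_mutated_genes": float(mg.max()),
            "median_mutated_tumors": float(np.median(mt)),
            "min_mutated_tumors": float(mt.min()),
            "max_mutated_tumors": float(mt.max()),
            "min_bh_q": float(self.bh_q.min()) if len(self.bh_q) else 1.0,
        }


def housekeeping_null(mutations: Sequence[MutationRecord],
                      pool: Sequence[str],
                      apobec_positive: dict[str, bool],
                      k: int = 119,
                      iterations: int = 100_000,
                      seed: int = 0) -> HousekeepingNull:
    """Resampling null over random k-gene sets from the housekeeping pool.

    Per iteration, k pool genes are drawn without replacement; the number
    of drawn genes with a deleterious mutation anywhere in the cohort and
    the number of tumors carrying such a mutation are recorded, and a
    two-sided Fisher's exact test contrasts APOBEC positivity with
    carrying a mutation in the drawn set. BH runs across iterations.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    pool = list(pool)
    if len(pool) < k:
        raise ValueError(f"pool ({len(pool)}) smaller than k={k}")
    samples = sorted(apobec_positive)
    sample_idx = {s: i for i, s in enumerate(samples)}
    deleterious, _ = deleterious_filter(mutations)
    gene_idx = {g: i for i, g in enumerate(pool)}
    hit = np.zeros((len(pool), len(samples)), dtype=bool)
    for m in deleterious:
        gi = gene_idx.get(m.gene_id)
        si = sample_idx.get(m.sample_id)
        if gi is not None and si is not None:
            hit[gi, si] = True
    pos = np.array([apobec_positive[s] for s in samples])
    n_pos = int(pos.sum())
    n_neg = len(samples) - n_pos

    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    mutated_genes = np.empty(iterations, dtype=np.int64)
    mutated_tumors = np.empty(iterations, dtype=np.int64)
    ps = np.empty(iterations)
    cache: dict[tuple[int, int], float] = {}
    for it in range(iterations):
        idx = rng.choice(len(pool), size=k, replace=False)
        sub = hit[idx]
        mutated_genes[it] = int(sub.any(axis=1).sum())
        carrier = sub.any(axis=0)
        mutated_tumors[it] = int(carrier.sum())
        a = int((carrier & pos).sum())
        c = int((carrier & ~pos).sum())
        key = (a, c)
        if key not in cache:
            cache[key] = _two_sided_fisher([[a, n_pos - a], [c, n_neg - c]])
        ps[it] = cache[key]
    _, qs, _, _ = multipletests(ps, method="fdr_bh")
    return HousekeepingNull(iterations=iterations, k=k,
                            mutated_genes=mutated_genes,
                            mutated_tumors=mutated_tumors,
                            fisher_p=ps, bh_q=qs)
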