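"""R-loop overlap, transcriptional strand labels and motif-skew tests.

Mutations and kataegic events are partitioned into nontranscribed-strand
(NTS), transcribed-strand (TS) and intergenic classes. NTS means the
mutated pyrimidine lies on the gene's annotated (coding) strand — the
strand displayed as ssDNA in an R-loop — and TS its complement. R-loop
intervals are padded by 1 kbp on both sides before overlap. Per-event
RTCA/YTCA enrichment uses the same availability-normalized score as the
sample-level TCW enrichment; kataegic events are compared to nonclustered
control mutations per region with a two-sided Mann-Whitney U test, BH
correction across the region x motif family, and Cohen's d effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._reference import ReferenceGenome
from .catalog_io import GeneModel, GenomicInterval, merge_intervals
from .context_engine import PyrimidineContext, motif_counts
from .kataegis import ClusterCall

REGIONS = ("NTS", "TS", "intergenic")


@dataclass
class EventEnrichment:
    event_id: str
    E_RTCA: Optional[float]
    E_YTCA: Optional[float]
    skew: str  # RTCA | YTCA | neither


@dataclass
class ComparisonResult:
    region: str
    motif: str
    n_events: int
    n_controls: int
    median_event: float
    median_control: float
    u_stat: float
    p: float
    bh_q: Optional[float]
    cohens_d: Optional[float]
    skipped: bool = False


def expand_rloops(rloops: Sequence[GenomicInterval], pad: int = 1000,
                  chrom_lengths: Optional[dict[str, int]] = None
                  ) -> list[GenomicInterval]:
    """Pad each interval by ``pad`` bp on both sides, clip at 0 (and at
    the chromosome end when lengths are given), then merge overlaps."""
    padded = []
    for iv in rloops:
        start = max(0, iv.start - pad)
        end = iv.end + pad
        if chrom_lengths is not None:
            end = min(end, chrom_lengths[iv.chrom])
        padded.append(GenomicInterval(iv.chrom, start, end, iv.name))
    return merge_intervals(padded)


class _IntervalLookup:
    """Membership queries on a merged (sorted, disjoint) interval set."""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs = sorted(ivs, key=lambda x: x.start)
            self._starts[chrom] = np.array([iv.start for iv in ivs])
            self._ends[chrom] = np.array([iv.end for iv in ivs])

    def covers(self, chrom: str, pos0: int) -> bool:
        starts = self._starts.get(chrom)
        if starts is None:
            return False
        i = int(np.searchsorted(starts, pos0, side="right")) - 1
        return i >= 0 and pos0 < self._ends[chrom][i]


class GeneStrandLookup:
    """Which gene strands cover a position (genes may overlap antisense)."""

    def __init__(self, genes: Sequence[GeneModel]):
        self._lk = {s: _IntervalLookup([g.tx for g in genes if g.strand == s])
                    for s in "+-"}

    def strands_at(self, chrom: str, pos0: int) -> tuple[bool, bool]:
        return (self._lk["+"].covers(chrom, pos0),
                self._lk["-"].covers(chrom, pos0))


def assign_region(ctx: PyrimidineContext, genes: GeneStrandLookup,
                  padded_rloops: _IntervalLookup) -> tuple[str, bool]:
    """(region label, R-loop overlap) for one strand-normalized mutation.

    Intergenic when no gene covers the position; NTS when the pyrimidine
    strand equals the covering gene's strand; TS when opposite; ambiguous
    when genes on both strands cover it (kept in totals, excluded from
    strand statistics).
    """
    pos0 = ctx.pos - 1
    on_plus, on_minus = genes.strands_at(ctx.chrom, pos0)
    in_rloop = padded_rloops.covers(ctx.chrom, pos0)
    if not on_plus and not on_minus:
        return "intergenic", in_rloop
    if on_plus and on_minus:
        return "ambiguous", in_rloop
    gene_strand = "+" if on_plus else "-"
    return ("NTS" if ctx.pyr_strand == gene_strand else "TS"), in_rloop


def label_contexts(contexts: Iterable[PyrimidineContext],
                   genes: Sequence[GeneModel],
                   rloops: Sequence[GenomicInterval],
                   pad: int = 1000,
                   chrom_lengths: Optional[dict[str, int]] = None
                   ) -> pd.DataFrame:
    """Region + R-loop labels for a set of contexts, as a DataFrame."""
    lookup = GeneStrandLookup(genes)
    padded = _IntervalLookup(expand_rloops(rloops, pad, chrom_lengths))
    rows = []
    for ctx in contexts:
        region, in_rl = assign_region(ctx, lookup, padded)
        rows.append((ctx.chrom, ctx.pos, ctx.pyr_strand, region, in_rl))
    return pd.DataFrame(rows, columns=["chrom", "pos", "pyr_strand",
                                       "region", "rloop_overlap"])


def event_motif_enrichment(contexts: Sequence[PyrimidineContext],
                           reference: ReferenceGenome,
                           halfwidth: int = 20,
                           event_id: str = "") -> EventEnrichment:
    """RTCA and YTCA enrichment of one event (cluster or single mutation).

    E_motif = (m_motif * c_C) / (m_C * c_motif) with counts pooled over
    the event's +/-halfwidth windows; a component with zero denominator
    is undefined and forces skew = neither unless the other side decides.
    """
    counts = motif_counts(contexts, reference, halfwidth)
    e_rtca = (None if counts.m_C == 0 or counts.c_RTCA == 0
              else counts.m_RTCA * counts.c_C / (counts.m_C * counts.c_RTCA))
    e_ytca = (None if counts.m_C == 0 or counts.c_YTCA == 0
              else counts.m_YTCA * counts.c_C / (counts.m_C * counts.c_YTCA))
    if e_rtca is None or e_ytca is None or e_rtca == e_ytca:
        skew = "neither"
    else:
        skew = "RTCA" if e_rtca > e_ytca else "YTCA"
    return EventEnrichment(event_id=event_id, E_RTCA=e_rtca,
                           E_YTCA=e_ytca, skew=skew)


def cluster_region_label(member_labels: Sequence[str]) -> str:
    """Majority label of the members; ties -> ambiguous."""
    counts = pd.Series(member_labels).value_counts()
    top = counts[counts == counts.max()]
    return top.index[0] if len(top) == 1 else "ambiguous"


def _cohens_d(a: np.ndarray, b: np.ndarray) -> Optional[float]:
    if len(a) < 2 or len(b) < 2:
        return None
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = ((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2)
    if pooled == 0:
        return 0.0 if a.mean() == b.mean() else None
    return float((a.mean() - b.mean()) / np.sqrt(pooled))


def compare_groups(event_values: dict[str, dict[str, list[float]]],
                   control_values: dict[str, dict[str, list[float]]],
                   alpha: float = 0.05) -> list[ComparisonResult]:
    """Mann-Whitney U comparisons of event vs control enrichment.

    ``event_values[region][motif]`` and the control counterpart hold the
    per-event (respectively per-mutation) enrichment values. Regions or
    motifs where either group has fewer than 2 defined values are skipped
    and reported as such. BH runs across the tested region x motif family.
    """
    results: list[ComparisonResult] = []
    tested: list[int] = []
    ps: list[float] = []
    for region in REGIONS:
        for motif in ("RTCA", "YTCA"):
            ev = np.array([v for v in event_values.get(region, {}).get(motif, [])
                           if v is not None], dtype=float)
            ct = np.array([v for v in control_values.get(region, {}).get(motif, [])
                           if v is not None], dtype=float)
            if len(ev) < 2 or len(ct) < 2:
                results.append(ComparisonResult(
                    region, motif, len(ev), len(ct),
                    float(np.median(ev)) if len(ev) else float("nan"),
                    float(np.median(ct)) if len(ct) else float("nan"),
                    float("nan"), float("nan"), None, None, skipped=True))
                continue
            if np.all(ev == ev[0]) and np.all(ct == ct[0]) and ev[0] == ct[0]:
                u, p = len(ev) * len(ct) / 2, 1.0
            else:
                u, p = stats.mannwhitneyu(ev, ct, alternative="two-sided")
            results.append(ComparisonResult(
                region, motif, len(ev), len(ct),
                float(np.median(ev)), float(np.median(ct)),
                float(u), float(p), None, _cohens_d(ev, ct)))
            tested.append(len(results) - 1)
            ps.append(float(p))
    if ps:
        _, qs, _, _ = multipletests(ps, method="fdr_bh")
        for i, q in zip(tested, qs):
            results[i].bh_q = float(q)
    return results


def analyze_rloop_association(clusters: Sequence[ClusterCall],
                              contexts_by_sample: dict[str, list[PyrimidineContext]],
                              genes: Sequence[GeneModel],
                              rloops: Sequence[GenomicInterval],
                              reference: ReferenceGenome,
                              pad: int = 1000,
                              halfwidth: int = 20,
                              min_cluster_size: int = 3
                              ) -> tuple[list[ComparisonResult], pd.DataFrame]:
    """End-to-end Fig-style comparison on called clusters.

    Kataegic events (APOBEC-flagged clusters of >= min_cluster_size) are
    labeled by the majority region of their members; dispersed controls
    are APOBEC-context mutations outside any cluster of >=3, scored with
    the same per-mutation window enrichment. Returns the region x motif
    comparisons and a per-event table.
    """
    chrom_lengths = {c: reference.length(c) for c in reference.chroms}
    lookup = GeneStrandLookup(genes)
    padded = _IntervalLookup(expand_rloops(rloops, pad, chrom_lengths))

    ctx_at = {}
    for sid, ctxs in contexts_by_sample.items():
        for ctx in ctxs:
            ctx_at[(sid, ctx.chrom, ctx.pos)] = ctx

    # controls are nonclustered mutations: members of any called run,
    # including subthreshold pairs, are excluded from the control group
    clustered_keys = {(c.sample_id, c.chrom, p)
                      for c in clusters for p in c.positions}

    event_vals: dict[str, dict[str, list[float]]] = {
        r: {"RTCA": [], "YTCA": []} for r in REGIONS}
    control_vals: dict[str, dict[str, list[float]]] = {
        r: {"RTCA": [], "YTCA": []} for r in REGIONS}

    rows = []
    for k, cl in enumerate(clusters):
        if cl.size < min_cluster_size or not cl.apobec_flag:
            continue
        member_ctx = [ctx_at.get((cl.sample_id, cl.chrom, p))
                      for p in cl.positions]
        member_ctx = [c for c in member_ctx if c is not None]
        if not member_ctx:
            continue
        labels, in_rl = [], []
        for c in member_ctx:
            lab, rl = assign_region(c, lookup, padded)
            labels.append(lab)
            in_rl.append(rl)
        region = cluster_region_label(labels)
        cl.region_label = region
        enr = event_motif_enrichment(member_ctx, reference, halfwidth,
                                     event_id=f"{cl.sample_id}_cl{k}")
        rows.append((enr.event_id, cl.sample_id, cl.chrom, cl.size,
                     cl.size_class, region, any(in_rl),
                     np.nan if enr.E_RTCA is None else enr.E_RTCA,
                     np.nan if enr.E_YTCA is None else enr.E_YTCA, enr.skew))
        if region in REGIONS:
            event_vals[region]["RTCA"].append(enr.E_RTCA)
            event_vals[region]["YTCA"].append(enr.E_YTCA)

    for sid, ctxs in contexts_by_sample.items():
        for ctx in ctxs:
            if not ctx.is_apobec_class:
                continue
            if (sid, ctx.chrom, ctx.pos) in clustered_keys:
                continue
            region, _ = assign_region(ctx, lookup, padded)
            if region not in REGIONS:
                continue
            enr = event_motif_enrichment([ctx], reference, halfwidth)
            control_vals[region]["RTCA"].append(enr.E_RTCA)
            control_vals[region]["YTCA"].append(enr.E_YTCA)

    comparisons = compare_groups(event_vals, control_vals)
    events = pd.DataFrame(rows, columns=[
        "event_id", "sample_id", "chrom", "size", "size_class", "region",
        "rloop_overlap", "E_RTCA", "E_YTCA", "skew"])
    return comparisons, events


def comparisons_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.region, r.motif, r.n_events, r.n_controls, r.median_event,
          r.median_control, r.u_stat, r.p, r.bh_q, r.cohens_d, r.skipped)
         for r in results],
        columns=["region", "motif", "n_events", "n_controls", "median_event",
                 "median_control", "u_stat", "p", "bh_q", "cohens_d",
                 "skipped"])
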