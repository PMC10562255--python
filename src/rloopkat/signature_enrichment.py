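"""Per-sample APOBEC enrichment scores and SBS96 signature refitting.

The enrichment score compares the fraction of cytosine mutations that hit
TCW motifs against the local availability of those motifs:

    E = (m_TCW * c_C) / (m_C * c_TCW)

where m_* count C>T/C>G mutations and c_* count motif occurrences (both
strands) within +/-20 bp of each counted mutation. E ~ 1 when TCW
cytosines are hit no more often than their availability predicts;
significance is a one-sided Fisher's exact test on the corresponding 2x2
table with Benjamini-Hochberg correction across the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from ._reference import ReferenceGenome
from .catalog_io import MutationRecord
from .context_engine import (MotifCounts, contexts_by_sample, motif_counts)


@dataclass
class EnrichmentResult:
    sample_id: str
    counts: MotifCounts
    E: Optional[float]  # None when undefined (m_C = 0 or c_TCW = 0)
    fisher_p: Optional[float] = None
    bh_q: Optional[float] = None
    enriched: bool = False


@dataclass
class RefitWeights:
    sample_id: str
    weights: pd.Series  # nonnegative, sum 1 over retained signatures
    residual_norm: float
    apobec_signatures: tuple[str, ...] = ("SBS2", "SBS13")

    @property
    def apobec_weight(self) -> float:
        return float(sum(self.weights.get(s, 0.0) for s in self.apobec_signatures))


def enrichment_from_counts(counts: MotifCounts) -> Optional[float]:
    """E = (m_TCW * c_C) / (m_C * c_TCW); None when undefined."""
    if counts.m_C == 0 or counts.c_TCW == 0 or counts.c_C == 0:
        return None
    return (counts.m_TCW * counts.c_C) / (counts.m_C * counts.c_TCW)


def apobec_enrichment_score(mutations: Sequence[MutationRecord],
                            reference: ReferenceGenome,
                            halfwidth: int = 20) -> EnrichmentResult:
    """Enrichment score for the mutations of one sample.

    Only C>T/C>G SBS (pyrimidine notation) contribute; availability is
    pooled over the +/-halfwidth window around each contributing
    mutation. A sample with no eligible mutation gets a missing E.
    """
    samples = {m.sample_id for m in mutations}
    if len(samples) > 1:
        raise ValueError("apobec_enrichment_score expects a single sample")
    sample = samples.pop() if samples else ""
    ctxs = contexts_by_sample(mutations, reference).get(sample, [])
    counts = motif_counts(ctxs, reference, halfwidth)
    return EnrichmentResult(sample_id=sample, counts=counts,
                            E=enrichment_from_counts(counts))


def enrichment_significance(results: Sequence[EnrichmentResult],
                            alpha: float = 0.05) -> list[EnrichmentResult]:
    """Attach Fisher p, BH q and the enriched call to cohort results.

    Per sample the 2x2 table [[m_TCW, m_C - m_TCW], [c_TCW, c_C - c_TCW]]
    is tested one-sided for an excess of TCW mutation over availability;
    BH runs across all samples in the call. enriched <=> q < alpha and
    E > 1. Degenerate tables (zero margin) get p = 1.
    """
    ps = []
    for r in results:
        c = r.counts
        table = np.array([[c.m_TCW, c.m_C - c.m_TCW],
                          [c.c_TCW, c.c_C - c.c_TCW]])
        if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
            p = 1.0
        else:
            p = float(stats.fisher_exact(table, alternative="greater").pvalue)
        ps.append(p)
    if ps:
        _, qs, _, _ = multipletests(ps, method="fdr_bh")
    else:
        qs = []
    out = []
    for r, p, q in zip(results, ps, qs):
        out.append(EnrichmentResult(
            sample_id=r.sample_id, counts=r.counts, E=r.E,
            fisher_p=p, bh_q=float(q),
            enriched=bool(q < alpha and r.E is not None and r.E > 1)))
    return out


def cohort_enrichment(mutations: Sequence[MutationRecord],
                      reference: ReferenceGenome,
                      halfwidth: int = 20,
                      alpha: float = 0.05) -> list[EnrichmentResult]:
    """Enrichment scores plus significance for a multi-sample catalog."""
    by_sample: dict[str, list[MutationRecord]] = {}
    for m in mutations:
        by_sample.setdefault(m.sample_id, []).append(m)
    results = [apobec_enrichment_score(ms, reference, halfwidth)
               for _, ms in sorted(by_sample.items())]
    return enrichment_significance(results, alpha)


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        c = r.counts
        rows.append((r.sample_id, c.m_C, c.m_TCW, c.m_RTCA, c.m_YTCA,
                     c.c_C, c.c_TCW, c.c_RTCA, c.c_YTCA,
                     np.nan if r.E is None else r.E,
                     r.fisher_p, r.bh_q, r.enriched))
    return pd.DataFrame(rows, columns=[
        "sample_id", "m_C", "m_TCW", "m_RTCA", "m_YTCA",
        "c_C", "c_TCW", "c_RTCA", "c_YTCA", "E", "fisher_p", "bh_q",
        "enriched"])


# ---------------------------------------------------------------------------
# signature refitting

def read_signature_matrix(path) -> pd.DataFrame:
    """Signature matrix TSV: 96 labeled channel rows x named signatures.

    Columns are renormalized to sum to 1 (they describe per-channel
    probabilities).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != 96:
        raise ValueError(f"signature matrix must have 96 rows, got {df.shape[0]}")
    colsum = df.sum(axis=0)
    if (colsum <= 0).any():
        raise ValueError("signature matrix has an empty column")
    return df / colsum


def refit_signatures(catalog: pd.Series, signatures: pd.DataFrame,
                     prune_threshold: float = 0.06,
                     sample_id: str = "") -> RefitWeights:
    """Nonnegative least-squares refit of one SBS96 catalog.

    The normalized catalog is fit to the signature columns by NNLS;
    signatures whose normalized weight falls below ``prune_threshold``
    are dropped and the fit repeated until the retained set is stable.
    Weights are renormalized to sum to 1.
    """
    if signatures.shape[1] == 0:
        raise ValueError("signature matrix has no columns")
    total = float(catalog.sum())
    if total <= 0:
        raise ValueError("cannot refit an empty catalog")
    y = catalog.reindex(signatures.index).fillna(0).to_numpy(dtype=float) / total

    active = list(signatures.columns)
    while True:
        A = signatures[active].to_numpy(dtype=float)
        w, rnorm = optimize.nnls(A, y)
        s = w.sum()
        norm = w / s if s > 0 else w
        keep = [sig for sig, wn in zip(active, norm)
                if wn >= prune_threshold or prune_threshold == 0]
        if not keep:  # keep the single best signature rather than none
            keep = [active[int(np.argmax(w))]]
        if keep == active:
            break
        active = keep
    weights = pd.Series(0.0, index=signatures.columns)
    weights[active] = norm
    return RefitWeights(sample_id=sample_id, weights=weights,
                        residual_norm=float(rnorm))


def refit_cohort(sbs96: pd.DataFrame, signatures: pd.DataFrame,
                 prune_threshold: float = 0.06) -> list[RefitWeights]:
    return [refit_signatures(sbs96.loc[s], signatures, prune_threshold,
                             sample_id=s)
            for s in sbs96.index]


def classify_apobec_positive(weights: RefitWeights,
                             detect_threshold: float = 0.06) -> bool:
    """Detectable APOBEC signature: SBS2+SBS13 weight above threshold."""
    return weights.apobec_weight >= detect_threshold
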