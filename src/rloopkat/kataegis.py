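"""Simulation-calibrated kataegis detection.

Clustered mutations are called with a sample-dependent intermutational
distance (IMD) cutoff. The cutoff is calibrated against background
simulations that reassign each observed substitution to a random genomic
position sharing its pyrimidine-normalized +/-2 bp sequence context
(genic mutations stay within genes of the source gene's strand). The
largest candidate cutoff at which at least 90% of sub-cutoff mutations
are in excess of the simulated expectation — with a BH-corrected
one-sided empirical p below alpha across the candidate grid — becomes the
sample's cutoff. A 10 Mbp regional mutation-density correction shrinks
the cutoff inside unusually dense windows, and adjacent cluster members
must agree in VAF within 0.10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from ._reference import ReferenceGenome, interval_mask, penta_codes, tri_codes
from .catalog_io import GeneModel, MutationRecord, SVBreakpoint
from .context_engine import classify_motif, pyrimidine_normalize

DEFAULT_GRID = tuple(2 ** k for k in range(4, 17))

#: Gap inserted between chromosomes in the global coordinate system; it
#: exceeds every candidate cutoff, so cross-chromosome neighbor distances
#: never register as clustered.
_CHROM_GAP = 10 ** 9


@dataclass
class BackgroundModel:
    sample_id: str
    n_sims: int
    seed: int
    sims: list[np.ndarray]  # global positions per simulation, sorted
    context_match: str = "penta"  # or "tri" after fallback
    n_fallback: int = 0


@dataclass
class ImdModel:
    sample_id: str
    grid: tuple[int, ...]
    obs: np.ndarray
    exp: np.ndarray
    pvals: np.ndarray
    qvals: np.ndarray
    cutoff_bp: Optional[int]
    # (chrom, window index) -> corrected cutoff; filled by
    # regional_correction, empty means "use cutoff_bp everywhere"
    window_cutoffs: dict = field(default_factory=dict)
    window_bp: int = 10_000_000

    def cutoff_at(self, chrom: str, pos: int) -> Optional[float]:
        if self.cutoff_bp is None:
            return None
        return self.window_cutoffs.get((chrom, (pos - 1) // self.window_bp),
                                       float(self.cutoff_bp))


@dataclass
class ClusterCall:
    sample_id: str
    chrom: str
    members: tuple[MutationRecord, ...]
    size_class: str  # clustered_ge3 | kataegis_ge5 | subthreshold
    apobec_flag: Optional[bool] = None
    min_sv_distance_bp: float = float("inf")
    sv_proximal: Optional[bool] = None
    region_label: Optional[str] = None
    vaf_gap_skipped: bool = False  # some junction lacked a VAF

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def span_bp(self) -> int:
        return self.members[-1].pos - self.members[0].pos

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(m.pos for m in self.members)


class GenomeContextIndex:
    """Genome positions grouped by normalized pentamer context.

    Built once per reference; provides eligible-position lookups for the
    background simulation under three masks: the whole genome, positions
    inside plus-strand genes and positions inside minus-strand genes.
    Trinucleotide groupings are built lazily for the fallback path.
    """

    def __init__(self, reference: ReferenceGenome, genes: Sequence[GeneModel]):
        self.reference = reference
        self.chroms = list(reference.chroms)
        self.offsets = {}       # gapped global coordinates (IMD space)
        self._array_off = {}    # dense offsets into the code arrays
        off = aoff = 0
        for c in self.chroms:
            self.offsets[c] = off
            self._array_off[c] = aoff
            off += reference.length(c) + _CHROM_GAP
            aoff += reference.length(c)
        self._penta = {}
        self._tri: dict = {}
        codes_all, pos_all = [], []
        masks = {"+": [], "-": []}
        for c in self.chroms:
            seq = reference.sequence(c)
            codes = penta_codes(seq)
            pos = np.arange(len(seq), dtype=np.int64) + self.offsets[c]
            codes_all.append(codes)
            pos_all.append(pos)
            for strand in "+-":
                ivs = [(g.tx.start, g.tx.end) for g in genes
                       if g.chrom == c and g.strand == strand]
                masks[strand].append(interval_mask(len(seq), ivs))
        codes = np.concatenate(codes_all)
        pos = np.concatenate(pos_all)
        self._codes = codes
        self._gpos = pos
        self._genic = {s: np.concatenate(masks[s]) for s in "+-"}
        self._penta = {
            "all": _group_positions(codes, pos, codes >= 0),
            "+": _group_positions(codes, pos, (codes >= 0) & self._genic["+"]),
            "-": _group_positions(codes, pos, (codes >= 0) & self._genic["-"]),
        }

    def to_global(self, chrom: str, pos1: int) -> int:
        return self.offsets[chrom] + pos1 - 1

    def to_chrom(self, gpos: int) -> tuple[str, int]:
        for c in reversed(self.chroms):
            if gpos >= self.offsets[c]:
                return c, int(gpos - self.offsets[c] + 1)
        raise ValueError(f"bad global position {gpos}")

    def _array_index(self, chrom: str, pos1: int) -> int:
        return self._array_off[chrom] + pos1 - 1

    def penta_code_at(self, chrom: str, pos1: int) -> int:
        return int(self._codes[self._array_index(chrom, pos1)])

    def mask_for(self, chrom: str, pos1: int) -> str:
        g = self._array_index(chrom, pos1)
        on_plus = bool(self._genic["+"][g])
        on_minus = bool(self._genic["-"][g])
        if on_plus and not on_minus:
            return "+"
        if on_minus and not on_plus:
            return "-"
        return "all"

    def eligible(self, mask: str, code: int) -> np.ndarray:
        return self._penta[mask].get(code, _EMPTY)

    def eligible_tri(self, mask: str, chrom: str, pos1: int) -> np.ndarray:
        if mask not in self._tri:
            sel = self._codes >= -1  # all positions
            if mask in "+-":
                base = self._genic[mask]
            else:
                base = np.ones_like(self._codes, dtype=bool)
            tri_all = []
            for c in self.chroms:
                tri_all.append(tri_codes(self.reference.sequence(c)))
            tri = np.concatenate(tri_all)
            self._tri_codes = tri
            self._tri[mask] = _group_positions(tri, self._gpos,
                                               (tri >= 0) & base)
        code = int(self._tri_codes[self._array_index(chrom, pos1)])
        return self._tri[mask].get(code, _EMPTY)


_EMPTY = np.empty(0, dtype=np.int64)


def _group_positions(codes: np.ndarray, pos: np.ndarray,
                     select: np.ndarray) -> dict[int, np.ndarray]:
    c = codes[select]
    p = pos[select]
    if len(c) == 0:
        return {}
    order = np.argsort(c, kind="stable")
    c, p = c[order], p[order]
    bounds = np.flatnonzero(np.diff(c)) + 1
    starts = np.concatenate([[0], bounds])
    ends = np.concatenate([bounds, [len(c)]])
    return {int(c[s]): p[s:e] for s, e in zip(starts, ends)}


def _choose_without_replacement(rng: np.random.Generator,
                                pool: np.ndarray, k: int) -> np.ndarray:
    """Uniform k-subset of pool; cheap when k << len(pool)."""
    n = len(pool)
    if k > n:
        raise ValueError("pool smaller than requested draw")
    if k * 3 >= n:
        return pool[rng.permutation(n)[:k]]
    while True:
        draw = np.unique(rng.integers(0, n, size=k + 8 + k // 4))
        if len(draw) >= k:
            return pool[rng.permutation(draw)[:k]]


def simulate_background(mutations: Sequence[MutationRecord],
                        reference: ReferenceGenome,
                        genes: Sequence[GeneModel],
                        n_sims: int = 200,
                        seed: int = 0,
                        index: Optional[GenomeContextIndex] = None
                        ) -> BackgroundModel:
    """Context-preserving random redistributions of one sample's SBS.

    Each simulation reassigns every observed SBS to a position drawn
    uniformly (without replacement within the simulation) from all
    genomic positions sharing its normalized pentanucleotide context;
    mutations inside a gene stay inside genes of the same strand. A
    context with too few eligible positions falls back to the
    trinucleotide grouping with a warning.
    """
    sample_ids = {m.sample_id for m in mutations}
    if len(sample_ids) > 1:
        raise ValueError("simulate_background expects a single sample")
    sample_id = sample_ids.pop() if sample_ids else ""
    if index is None:
        index = GenomeContextIndex(reference, genes)

    groups: dict[tuple[str, int], list] = {}
    fallback_keys: list[tuple[str, str, int]] = []
    n_sbs = 0
    for m in mutations:
        if not m.is_sbs:
            continue
        code = index.penta_code_at(m.chrom, m.pos)
        if code < 0:
            continue  # boundary / ambiguous context
        n_sbs += 1
        mask = index.mask_for(m.chrom, m.pos)
        groups.setdefault((mask, code), []).append((m.chrom, m.pos))

    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    pools: list[tuple[np.ndarray, int]] = []
    n_fallback = 0
    for (mask, code), members in sorted(groups.items()):
        pool = index.eligible(mask, code)
        if len(pool) < len(members):
            chrom, pos1 = members[0]
            pool = index.eligible_tri(mask, chrom, pos1)
            n_fallback += len(members)
            warnings.warn(
                f"pentamer context of {chrom}:{pos1} has too few eligible "
                "positions; falling back to trinucleotide matching")
        if len(pool) < len(members):
            raise ValueError("not enough context-matched positions to simulate")
        pools.append((pool, len(members)))

    sims = []
    for _ in range(n_sims):
        parts = [_choose_without_replacement(rng, pool, k)
                 for pool, k in pools]
        gpos = np.sort(np.concatenate(parts)) if parts else _EMPTY
        sims.append(gpos)
    return BackgroundModel(sample_id=sample_id, n_sims=n_sims, seed=seed,
                           sims=sims,
                           context_match="tri" if n_fallback else "penta",
                           n_fallback=n_fallback)


def _nn_distances(gpos: np.ndarray) -> np.ndarray:
    """Nearest-neighbor distance per position (sorted global coords)."""
    if len(gpos) < 2:
        return np.full(len(gpos), np.inf)
    d = np.diff(gpos).astype(float)
    left = np.concatenate([[np.inf], d])
    right = np.concatenate([d, [np.inf]])
    return np.minimum(left, right)


def _sub_cutoff_counts(gpos: np.ndarray, grid: Sequence[int]) -> np.ndarray:
    nn = np.sort(_nn_distances(gpos))
    return np.searchsorted(nn, np.array(grid, dtype=float), side="left")


def global_positions(mutations: Sequence[MutationRecord],
                     index: GenomeContextIndex) -> np.ndarray:
    gpos = np.array([index.to_global(m.chrom, m.pos)
                     for m in mutations if m.is_sbs], dtype=np.int64)
    return np.sort(gpos)


def derive_imd_cutoff(mutations: Sequence[MutationRecord],
                      background: BackgroundModel,
                      index: GenomeContextIndex,
                      grid: Sequence[int] = DEFAULT_GRID,
                      alpha: float = 0.01) -> ImdModel:
    """Sample-dependent IMD cutoff from the background simulations.

    For each candidate cutoff c, obs(c) counts observed mutations whose
    nearest-neighbor IMD is below c and exp(c) is the mean of the same
    count over simulations. The cutoff is the largest c with
    (obs - exp)/obs >= 0.90 and a BH-corrected plus-one empirical p
    (fraction of simulations reaching obs) below alpha; None if no
    candidate qualifies.
    """
    if background.n_sims < 20:
        raise ValueError("need at least 20 background simulations")
    gpos = global_positions(mutations, index)
    obs = _sub_cutoff_counts(gpos, grid).astype(float)
    sim_counts = np.vstack([_sub_cutoff_counts(s, grid)
                            for s in background.sims]).astype(float)
    exp = sim_counts.mean(axis=0)
    n_sims = background.n_sims
    pvals = ((sim_counts >= obs[None, :]).sum(axis=0) + 1) / (n_sims + 1)
    defined = obs > 0
    qvals = np.ones(len(grid))
    if defined.any():
        _, q, _, _ = multipletests(pvals[defined], method="fdr_bh")
        qvals[defined] = q
    excess = np.where(obs > 0, (obs - exp) / np.maximum(obs, 1), 0.0)
    ok = defined & (excess >= 0.90) & (qvals < alpha)
    cutoff = int(np.array(grid)[ok][-1]) if ok.any() else None
    return ImdModel(sample_id=background.sample_id, grid=tuple(grid),
                    obs=obs, exp=exp, pvals=pvals, qvals=qvals,
                    cutoff_bp=cutoff)


def regional_correction(imd: ImdModel,
                        mutations: Sequence[MutationRecord],
                        chrom_lengths: dict[str, int],
                        window_bp: int = 10_000_000) -> ImdModel:
    """Shrink the cutoff inside mutation-dense 10 Mbp windows.

    Each window's corrected cutoff is c * min(1, global_density /
    window_density); windows without mutations keep the global cutoff.
    The correction never loosens the calibration (multiplier capped at 1).
    """
    if imd.cutoff_bp is None:
        return imd
    positions = [(m.chrom, m.pos) for m in mutations if m.is_sbs]
    total_bp = sum(chrom_lengths.values())
    global_density = len(positions) / total_bp
    counts: dict[tuple[str, int], int] = {}
    for chrom, pos in positions:
        key = (chrom, (pos - 1) // window_bp)
        counts[key] = counts.get(key, 0) + 1
    window_cutoffs = {}
    for (chrom, w), n in counts.items():
        w_len = min(window_bp, chrom_lengths[chrom] - w * window_bp)
        density = n / w_len
        factor = min(1.0, global_density / density) if density > 0 else 1.0
        window_cutoffs[(chrom, w)] = imd.cutoff_bp * factor
    imd.window_cutoffs = window_cutoffs
    imd.window_bp = window_bp
    return imd


def call_clusters(mutations: Sequence[MutationRecord], imd: ImdModel,
                  vaf_tol: float = 0.10) -> list[ClusterCall]:
    """Maximal runs of sub-cutoff IMDs, split at incoherent VAF junctions.

    Consecutive same-chromosome mutations join a run when their distance
    is below the corrected cutoff of the window containing the earlier
    mutation; an adjacent pair whose VAFs differ by >= vaf_tol splits the
    run. Runs of >=3 are clustered (>=5 additionally kataegis); runs of 2
    are reported as subthreshold.
    """
    if imd.cutoff_bp is None:
        raise ValueError("no IMD cutoff derived for this sample")
    sample_ids = {m.sample_id for m in mutations}
    if len(sample_ids) > 1:
        raise ValueError("call_clusters expects a single sample")
    sbs = sorted((m for m in mutations if m.is_sbs),
                 key=lambda m: (m.chrom, m.pos))
    clusters: list[ClusterCall] = []
    run: list[MutationRecord] = []
    run_vaf_gap = False

    def flush():
        nonlocal run, run_vaf_gap
        if len(run) >= 2:
            cls = ("kataegis_ge5" if len(run) >= 5 else
                   "clustered_ge3" if len(run) >= 3 else "subthreshold")
            clusters.append(ClusterCall(
                sample_id=run[0].sample_id, chrom=run[0].chrom,
                members=tuple(run), size_class=cls,
                vaf_gap_skipped=run_vaf_gap))
        run, run_vaf_gap = [], False

    prev: Optional[MutationRecord] = None
    for m in sbs:
        if prev is not None and m.chrom == prev.chrom:
            cut = imd.cutoff_at(m.chrom, prev.pos)
            linked = (m.pos - prev.pos) < cut
            if linked:
                if prev.vaf is None or m.vaf is None:
                    run_vaf_gap = True
                elif abs(m.vaf - prev.vaf) >= vaf_tol:
                    linked = False
        else:
            linked = False
        if linked:
            if not run:
                run = [prev]
            run.append(m)
        else:
            flush()
        prev = m
    flush()
    return clusters


def filter_apobec(clusters: Sequence[ClusterCall],
                  reference: ReferenceGenome) -> list[ClusterCall]:
    """Set apobec_flag: every member a TCW-context C>T or C>G."""
    out = []
    for cl in clusters:
        flag = True
        for m in cl.members:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ctx = pyrimidine_normalize(m, reference)
            if ctx is None or not (ctx.is_apobec_class
                                   and classify_motif(ctx).is_TCW):
                flag = False
                break
        cl.apobec_flag = flag
        out.append(cl)
    return out


def sv_partition(clusters: Sequence[ClusterCall],
                 breakpoints: Sequence[SVBreakpoint],
                 radius: int = 10_000):
    """Distance of each cluster to the nearest same-sample SV breakpoint.

    The distance is the minimum over cluster members and same-chromosome
    breakpoints; infinity when the sample has no breakpoint on that
    chromosome. ``sv_proximal`` marks clusters within ``radius``.
    """
    by_key: dict[tuple[str, str], np.ndarray] = {}
    for b in breakpoints:
        by_key.setdefault((b.sample_id, b.chrom), []).append(b.pos)  # type: ignore
    by_key = {k: np.sort(np.array(v)) for k, v in by_key.items()}

    def nearest(sample_id, chrom, positions):
        bps = by_key.get((sample_id, chrom))
        if bps is None or len(bps) == 0:
            return float("inf")
        pos = np.asarray(positions)
        idx = np.searchsorted(bps, pos)
        best = np.full(len(pos), np.inf)
        left = idx > 0
        best[left] = np.abs(pos[left] - bps[idx[left] - 1])
        right = idx < len(bps)
        best[right] = np.minimum(best[right],
                                 np.abs(pos[right] - bps[idx[right]]))
        return float(best.min())

    for cl in clusters:
        d = nearest(cl.sample_id, cl.chrom, cl.positions)
        cl.min_sv_distance_bp = d
        cl.sv_proximal = d < radius
    return list(clusters)


def dispersed_sv_distances(mutations: Sequence[MutationRecord],
                           clusters: Sequence[ClusterCall],
                           breakpoints: Sequence[SVBreakpoint]) -> np.ndarray:
    """Nearest-SV distance per dispersed (non-clustered) mutation."""
    clustered = {(c.sample_id, c.chrom, p) for c in clusters
                 for p in c.positions}
    by_key: dict[tuple[str, str], list[int]] = {}
    for b in breakpoints:
        by_key.setdefault((b.sample_id, b.chrom), []).append(b.pos)
    sorted_bps = {k: np.sort(np.array(v)) for k, v in by_key.items()}
    out = []
    for m in mutations:
        if not m.is_sbs or (m.sample_id, m.chrom, m.pos) in clustered:
            continue
        bps = sorted_bps.get((m.sample_id, m.chrom))
        if bps is None:
            out.append(float("inf"))
            continue
        i = np.searchsorted(bps, m.pos)
        cands = []
        if i > 0:
            cands.append(abs(m.pos - bps[i - 1]))
        if i < len(bps):
            cands.append(abs(m.pos - bps[i]))
        out.append(float(min(cands)))
    return np.array(out)


def detect_kataegis(mutations: Sequence[MutationRecord],
                    reference: ReferenceGenome,
                    genes: Sequence[GeneModel],
                    breakpoints: Sequence[SVBreakpoint] = (),
                    n_sims: int = 200,
                    seed: int = 0,
                    grid: Sequence[int] = DEFAULT_GRID,
                    alpha: float = 0.01,
                    vaf_tol: float = 0.10,
                    sv_radius: int = 10_000,
                    index: Optional[GenomeContextIndex] = None
                    ) -> tuple[dict[str, ImdModel], list[ClusterCall]]:
    """Per-sample calibration and cluster calling for a whole catalog."""
    if index is None:
        index = GenomeContextIndex(reference, genes)
    chrom_lengths = {c: reference.length(c) for c in reference.chroms}
    by_sample: dict[str, list[MutationRecord]] = {}
    for m in mutations:
        by_sample.setdefault(m.sample_id, []).append(m)
    models: dict[str, ImdModel] = {}
    clusters: list[ClusterCall] = []
    for i, (sid, ms) in enumerate(sorted(by_sample.items())):
        bg = simulate_background(ms, reference, genes, n_sims=n_sims,
                                 seed=seed + i, index=index)
        imd = derive_imd_cutoff(ms, bg, index, grid=grid, alpha=alpha)
        if imd.cutoff_bp is not None:
            imd = regional_correction(imd, ms, chrom_lengths)
            clusters.extend(call_clusters(ms, imd, vaf_tol=vaf_tol))
        models[sid] = imd
    clusters = filter_apobec(clusters, reference)
    if breakpoints:
        clusters = sv_partition(clusters, breakpoints, radius=sv_radius)
    return models, clusters
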