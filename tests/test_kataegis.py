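import dataclasses

import numpy as np
import pytest

import rloopkat as rk
from rloopkat import kataegis as kat
from rloopkat._reference import ReferenceGenome
from rloopkat.catalog_io import MutationRecord, SVBreakpoint
from conftest import make_gene


def manual_imd(cutoff, sample_id="s"):
    grid = (cutoff,)
    one = np.ones(1)
    return kat.ImdModel(sample_id=sample_id, grid=grid, obs=one, exp=one,
                        pvals=one, qvals=one, cutoff_bp=cutoff)


def mut(sample, chrom, pos, vaf=None, ref="C", alt="T"):
    return MutationRecord(sample, chrom, pos, ref, alt, vaf=vaf)


@pytest.fixture(scope="module")
def planted_setup():
    """Single-sample default-condition cohort with its context index."""
    cfg = rk.SyntheticConfig(seed=42, n_samples=2)
    ref, records, _, truth = rk.simulate(cfg)
    index = kat.GenomeContextIndex(ref.reference, ref.genes)
    return cfg, ref, records, truth, index


class TestBackgroundSimulation:
    def test_simulated_positions_share_source_penta_context(self, planted_setup):
        _, ref, records, _, index = planted_setup
        sample = [m for m in records if m.sample_id == "S000"]
        bg = kat.simulate_background(sample, ref.reference, ref.genes,
                                     n_sims=25, seed=3, index=index)
        observed = sorted(
            index.penta_code_at(m.chrom, m.pos) for m in sample
            if m.is_sbs and index.penta_code_at(m.chrom, m.pos) >= 0)
        for sim in bg.sims:
            codes = sorted(index.penta_code_at(*index.to_chrom(int(g)))
                           for g in sim)
            assert codes == observed
        assert bg.context_match == "penta" and bg.n_fallback == 0

    def test_single_context_constrained_to_known_sites(self):
        # one GTCAT mutation on a genome with exactly 7 normalized GTCAT
        # sites: every simulated position must be one of them
        block = "GTCAT"
        spacer = "AAAAAAAAAA"
        seq = spacer + (block + spacer) * 7
        ref = ReferenceGenome({"c": seq})
        index = kat.GenomeContextIndex(ref, [])
        # 1-based positions of the C inside each GTCAT occurrence
        expected = {i + 3 for i in range(len(seq)) if seq.startswith(block, i)}
        assert len(expected) == 7
        first = sorted(expected)[0]
        assert ref.base("c", first - 1) == "C"
        m = mut("s", "c", first)
        bg = kat.simulate_background([m], ref, [], n_sims=50, seed=1,
                                     index=index)
        for sim in bg.sims:
            _, pos1 = index.to_chrom(int(sim[0]))
            assert pos1 in expected

    def test_genic_mutations_stay_on_matching_strand_genes(self):
        seq = ("AAAAA" + "GTCAT" + "AAAAA") * 40
        ref = ReferenceGenome({"c": seq})
        genes = [make_gene("gp", "c", "+", 0, 150),
                 make_gene("gm", "c", "-", 300, 450)]
        index = kat.GenomeContextIndex(ref, genes)
        m = mut("s", "c", 8)  # the GTCAT cytosine inside the + gene
        assert ref.base("c", 7) == "C"
        bg = kat.simulate_background([m], ref, genes, n_sims=40, seed=2,
                                     index=index)
        for sim in bg.sims:
            _, pos1 = index.to_chrom(int(sim[0]))
            assert 1 <= pos1 <= 150  # never the - gene or intergenic

    def test_fallback_to_tri_context_warns(self):
        # the mutation's penta is unique, so two mutations sharing it
        # cannot be placed without replacement -> tri fallback
        seq = "AAAA" + "GTCAT" + "AAAA" + "ATCAA" + "AAAA"
        ref = ReferenceGenome({"c": seq})
        index = kat.GenomeContextIndex(ref, [])
        m = mut("s", "c", 7)
        assert ref.base("c", 6) == "C"
        m2 = mut("s2", "c", 7)  # same position, forced same context
        with pytest.warns(UserWarning, match="trinucleotide"):
            bg = kat.simulate_background(
                [m, dataclasses.replace(m2, sample_id="s")], ref, [],
                n_sims=20, seed=1, index=index)
        assert bg.n_fallback == 2

    def test_seeded_determinism(self, planted_setup):
        _, ref, records, _, index = planted_setup
        sample = [m for m in records if m.sample_id == "S000"]
        runs = [kat.simulate_background(sample, ref.reference, ref.genes,
                                        n_sims=20, seed=9, index=index)
                for _ in range(2)]
        for a, b in zip(runs[0].sims, runs[1].sims):
            assert np.array_equal(a, b)


class TestImdCutoff:
    def test_planted_clusters_yield_cutoff_and_recovery(self, planted_setup):
        _, ref, records, truth, index = planted_setup
        models, clusters = kat.detect_kataegis(
            records, ref.reference, ref.genes, ref.breakpoints,
            seed=11, index=index)
        assert any(m.cutoff_bp is not None for m in models.values())
        called = {(c.sample_id, c.chrom): c for c in clusters}
        recovered = 0
        for pc in truth.clusters:
            hits = [c for c in clusters
                    if c.sample_id == pc.sample_id and c.chrom == pc.chrom
                    and len(set(c.positions) & set(pc.positions))
                    >= min(5, pc.size)]
            recovered += bool(hits)
        assert recovered / len(truth.clusters) >= 0.9

    def test_dispersed_only_sample_gets_no_cutoff(self):
        cfg = rk.SyntheticConfig(seed=13, n_samples=1, clusters_per_sample=0,
                                 dispersed_rate=300, expression_coupling=0)
        ref, records, _, _ = rk.simulate(cfg)
        index = kat.GenomeContextIndex(ref.reference, ref.genes)
        bg = kat.simulate_background(records, ref.reference, ref.genes,
                                     n_sims=50, seed=1, index=index)
        imd = kat.derive_imd_cutoff(records, bg, index)
        assert imd.cutoff_bp is None

    def test_cutoff_non_increasing_with_burden(self):
        cutoffs = []
        for rate in (5.0, 10.0):
            cfg = rk.SyntheticConfig(seed=21, n_samples=1,
                                     dispersed_rate=rate,
                                     clusters_per_sample=4)
            ref, records, _, _ = rk.simulate(cfg)
            index = kat.GenomeContextIndex(ref.reference, ref.genes)
            bg = kat.simulate_background(records, ref.reference, ref.genes,
                                         n_sims=60, seed=2, index=index)
            imd = kat.derive_imd_cutoff(records, bg, index)
            cutoffs.append(imd.cutoff_bp if imd.cutoff_bp else 0)
        assert cutoffs[1] <= cutoffs[0]

    def test_too_few_simulations_rejected(self, planted_setup):
        _, ref, records, _, index = planted_setup
        sample = [m for m in records if m.sample_id == "S000"]
        bg = kat.simulate_background(sample, ref.reference, ref.genes,
                                     n_sims=5, seed=1, index=index)
        with pytest.raises(ValueError, match="at least 20"):
            kat.derive_imd_cutoff(sample, bg, index)


class TestRegionalCorrection:
    def test_dense_window_shrinks_sparse_window_capped(self):
        # 2 windows of 10 Mbp: 80 mutations in the first, 20 in the second
        # -> global density 5e-6; window densities 8e-6 and 2e-6
        muts = ([mut("s", "chr1", 100 * i + 1, vaf=0.5) for i in range(80)]
                + [mut("s", "chr1", 10_000_000 + 1000 * i + 1, vaf=0.5)
                   for i in range(20)])
        imd = manual_imd(1024)
        out = kat.regional_correction(imd, muts, {"chr1": 20_000_000})
        assert out.window_cutoffs[("chr1", 0)] == pytest.approx(1024 * 50 / 80)
        assert out.window_cutoffs[("chr1", 1)] == 1024  # capped at 1

    def test_empty_window_keeps_global_cutoff(self):
        muts = [mut("s", "chr1", i + 1, vaf=0.5) for i in range(10)]
        imd = manual_imd(512)
        out = kat.regional_correction(imd, muts, {"chr1": 30_000_000})
        assert out.cutoff_at("chr1", 25_000_000) == 512


class TestCallClusters:
    def test_simple_run_is_called(self):
        muts = [mut("s", "chr1", p, v) for p, v in
                [(10_000, 0.40), (10_200, 0.42), (10_550, 0.45),
                 (500_000, 0.50)]]
        clusters = kat.call_clusters(muts, manual_imd(1000))
        (cl,) = [c for c in clusters if c.size >= 3]
        assert cl.size == 3 and cl.size_class == "clustered_ge3"
        assert cl.positions == (10_000, 10_200, 10_550)

    def test_vaf_jump_splits_run(self):
        muts = [mut("s", "chr1", p, v) for p, v in
                [(1000, 0.50), (1300, 0.65), (1600, 0.64)]]
        clusters = kat.call_clusters(muts, manual_imd(1000))
        assert all(c.size < 3 for c in clusters)

    def test_five_members_are_kataegis(self):
        muts = [mut("s", "chr1", 1000 + 100 * i, 0.4) for i in range(5)]
        (cl,) = kat.call_clusters(muts, manual_imd(1000))
        assert cl.size_class == "kataegis_ge5"

    def test_missing_vaf_skips_filter_with_flag(self):
        muts = [mut("s", "chr1", 1000, None), mut("s", "chr1", 1100, 0.5),
                mut("s", "chr1", 1200, 0.5)]
        (cl,) = kat.call_clusters(muts, manual_imd(1000))
        assert cl.size == 3 and cl.vaf_gap_skipped

    def test_members_never_span_chromosomes_and_increase(self):
        muts = [mut("s", "chr1", 1000, 0.4), mut("s", "chr1", 1100, 0.4),
                mut("s", "chr2", 1150, 0.4), mut("s", "chr2", 1250, 0.4)]
        clusters = kat.call_clusters(muts, manual_imd(1000))
        for c in clusters:
            assert len({m.chrom for m in c.members}) == 1
            assert list(c.positions) == sorted(c.positions)
            assert c.size == 2

    def test_no_cutoff_is_error(self):
        imd = kat.ImdModel("s", (16,), np.zeros(1), np.zeros(1),
                           np.ones(1), np.ones(1), cutoff_bp=None)
        with pytest.raises(ValueError, match="no IMD cutoff"):
            kat.call_clusters([mut("s", "chr1", 100, 0.4)], imd)


class TestApobecFilterAndSv:
    def test_all_tcw_members_flagged(self):
        ref = ReferenceGenome({"c": "AA" + "TCA" * 5 + "AA"})
        muts = [mut("s", "c", 4 + 3 * i, 0.4) for i in range(5)]
        cl = kat.ClusterCall("s", "c", tuple(muts), "kataegis_ge5")
        (out,) = kat.filter_apobec([cl], ref)
        assert out.apobec_flag is True

    def test_single_non_tcw_member_unflags(self):
        ref = ReferenceGenome({"c": "AATCATCATCAGGTAA"})
        muts = [mut("s", "c", 4, 0.4), mut("s", "c", 7, 0.4),
                mut("s", "c", 10, 0.4), mut("s", "c", 13, 0.4, ref="G", alt="T")]
        cl = kat.ClusterCall("s", "c", tuple(muts), "clustered_ge3")
        (out,) = kat.filter_apobec([cl], ref)
        assert out.apobec_flag is False

    def test_sv_distance_and_proximity(self):
        members = tuple(mut("s", "chr1", p, 0.4)
                        for p in (95_500, 95_750, 96_000))
        cl = kat.ClusterCall("s", "chr1", members, "clustered_ge3")
        bp = [SVBreakpoint("s", "chr1", 100_000)]
        (out,) = kat.sv_partition([cl], bp, radius=10_000)
        assert out.min_sv_distance_bp == 4_000 and out.sv_proximal

    def test_no_breakpoint_on_chromosome_is_infinite(self):
        members = tuple(mut("s", "chr1", p, 0.4) for p in (100, 200, 300))
        cl = kat.ClusterCall("s", "chr1", members, "clustered_ge3")
        (out,) = kat.sv_partition([cl], [SVBreakpoint("s", "chr2", 5)],
                                  radius=10_000)
        assert out.min_sv_distance_bp == float("inf") and not out.sv_proximal

    def test_other_samples_breakpoints_ignored(self):
        members = tuple(mut("s", "chr1", p, 0.4) for p in (100, 200, 300))
        cl = kat.ClusterCall("s", "chr1", members, "clustered_ge3")
        (out,) = kat.sv_partition([cl], [SVBreakpoint("other", "chr1", 150)])
        assert out.min_sv_distance_bp == float("inf")


class TestDeterminism:
    def test_detection_is_bit_identical_across_reruns(self, planted_setup):
        _, ref, records, _, index = planted_setup
        outs = []
        for _ in range(2):
            models, clusters = kat.detect_kataegis(
                records, ref.reference, ref.genes, ref.breakpoints,
                n_sims=40, seed=17, index=index)
            outs.append((
                {s: m.cutoff_bp for s, m in models.items()},
                [(c.sample_id, c.positions) for c in clusters]))
        assert outs[0] == outs[1]
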