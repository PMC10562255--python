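import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rloopkat as rk
from rloopkat import cohort_association as ca
from rloopkat.catalog_io import ExpressionTable, MutationRecord
from rloopkat.context_engine import PyrimidineContext
from conftest import make_gene


def tcw_ctx(chrom, pos, penta="ATCAG"):
    return PyrimidineContext(chrom, pos, "C", "T", "+", penta)


def expr_table(tumor, baseline):
    genes = list(baseline)
    values = pd.DataFrame({"T1": [tumor[g] for g in genes]}, index=genes)
    return ExpressionTable(values=values,
                           normal_baseline=pd.Series(baseline))


class TestFoldChangeBins:
    @pytest.mark.parametrize("tumor,baseline,expected", [
        (0.0, 1.0, "G1"),
        (0.5, 1.0, "G2"),
        (0.8, 1.0, "G3"),   # closed lower boundary of G3
        (1.0, 1.0, "G3"),
        (1.2, 1.0, "G3"),   # closed upper boundary of G3
        (4.0, 1.0, "G4"),
        (5.0, 1.0, "G5"),
        (8.0, 1.0, "G5"),   # half-open upward: G5 keeps its upper edge
        (16.0, 1.0, "G6"),
        (17.0, 1.0, "G7"),
    ])
    def test_bin_boundaries(self, tumor, baseline, expected):
        table = expr_table({"g": tumor}, {"g": baseline})
        bins, undefined = ca.fold_change_bins(table, "T1")
        assert bins["g"] == expected and not undefined

    def test_zero_baseline_nonzero_tumor_is_undefined(self):
        table = expr_table({"g": 2.0}, {"g": 0.0})
        bins, undefined = ca.fold_change_bins(table, "T1")
        assert undefined == ["g"] and "g" not in bins

    def test_partition_each_gene_in_exactly_one_bin(self, rng):
        genes = {f"g{i}": float(v)
                 for i, v in enumerate(rng.uniform(0, 30, 200))}
        baseline = {g: 1.0 for g in genes}
        table = expr_table(genes, baseline)
        bins, undefined = ca.fold_change_bins(table, "T1")
        assert len(bins) + len(undefined) == 200
        assert set(bins.values()) <= set(ca.EXPRESSION_GROUPS)


class TestMutationRates:
    def test_rate_arithmetic(self):
        # 12 TCW mutations in G7 genes with 6 Mbp of exons -> 2.0 per Mbp
        genes = [make_gene(f"g{i}", "chr1", "+",
                           i * 4_000_000, i * 4_000_000 + 3_000_000)
                 for i in range(2)]
        gene_bins = {"g0": "G7", "g1": "G7"}
        ctxs = [tcw_ctx("chr1", 1000 + i) for i in range(6)] + \
               [tcw_ctx("chr1", 4_000_000 + 1000 + i) for i in range(6)]
        rates = ca.mutation_rate_per_group(ctxs, gene_bins, genes, "T1")
        g7 = rates[rates.group == "G7"].iloc[0]
        assert g7.n_tcw_mut == 12 and g7.exon_mbp == 6.0 and g7.rate == 2.0

    def test_zero_mutations_give_zero_rate(self):
        genes = [make_gene("g0", "chr1", "+", 0, 1_000_000)]
        rates = ca.mutation_rate_per_group([], {"g0": "G3"}, genes, "T1")
        assert rates[rates.group == "G3"].iloc[0].rate == 0.0

    def test_group_without_exons_has_missing_rate(self):
        genes = [make_gene("g0", "chr1", "+", 0, 1000)]
        rates = ca.mutation_rate_per_group([], {"g0": "G3"}, genes, "T1")
        assert np.isnan(rates[rates.group == "G7"].iloc[0].rate)

    def test_exonic_only_flag_restricts_counting(self):
        gene = make_gene("g0", "chr1", "+", 0, 10_000,
                         exons=((0, 1000), (9000, 10_000)))
        intronic = tcw_ctx("chr1", 5000)
        full = ca.mutation_rate_per_group([intronic], {"g0": "G3"}, [gene],
                                          "T1", exonic_only=False)
        exon = ca.mutation_rate_per_group([intronic], {"g0": "G3"}, [gene],
                                          "T1", exonic_only=True)
        assert full[full.group == "G3"].iloc[0].n_tcw_mut == 1
        assert exon[exon.group == "G3"].iloc[0].n_tcw_mut == 0


class TestGroupComparisons:
    def make_rates(self, values_by_group):
        rows = []
        for grp, vals in values_by_group.items():
            for i, v in enumerate(vals):
                rows.append((f"S{i}", grp, 0, 1.0, v))
        return pd.DataFrame(rows, columns=["sample_id", "group", "n_tcw_mut",
                                           "exon_mbp", "rate"])

    def test_twelve_pairs_emitted(self):
        rates = self.make_rates({g: [1.0, 2.0, 3.0]
                                 for g in ca.EXPRESSION_GROUPS})
        out = ca.group_comparisons(rates)
        assert len(out) == 12

    def test_identical_groups_degenerate_p_one(self):
        rates = self.make_rates({g: [2.0, 2.0, 2.0]
                                 for g in ca.EXPRESSION_GROUPS})
        out = ca.group_comparisons(rates)
        assert (out.p == 1.0).all() and out.degenerate.all()

    def test_separated_groups_significant(self, rng):
        vals = {g: list(rng.normal(1.0, 1.0, 40)) for g in ("G1", "G2", "G3")}
        vals.update({g: list(rng.normal(3.0, 1.0, 40))
                     for g in ("G4", "G5", "G6", "G7")})
        out = ca.group_comparisons(self.make_rates(vals))
        assert (out.p < 0.01).all()
        # cross-check one pair against the scipy Welch oracle directly
        t, p = stats.ttest_ind(vals["G1"], vals["G7"], equal_var=False)
        row = out[(out.low_group == "G1") & (out.high_group == "G7")].iloc[0]
        assert row.p == pytest.approx(p)

    def test_planted_topbin_coupling_recovered(self):
        # generator plants extra TCW mutations in >16-fold overexpressed
        # genes; G7 rates should exceed the low-bin rates
        probs = {"G1": 0.1, "G2": 0.1, "G3": 0.5, "G4": 0.1, "G5": 0.07,
                 "G6": 0.06, "G7": 0.07}
        cfg = rk.SyntheticConfig(seed=31, n_chroms=1,
                                 chrom_length_bp=3_000_000, n_genes=120,
                                 gene_length_range=(6_000, 14_000),
                                 rloop_count=20, n_samples=8,
                                 clusters_per_sample=0,
                                 expression_coupling=3.0,
                                 expression_bin_probs=probs)
        ref, records, expression, truth = rk.simulate(cfg)
        from rloopkat.context_engine import contexts_by_sample
        ctxs = contexts_by_sample(records, ref.reference)
        frames = []
        for sid in expression.values.columns:
            bins, _ = ca.fold_change_bins(expression, sid)
            frames.append(ca.mutation_rate_per_group(
                ctxs.get(sid, []), bins, ref.genes, sid))
        rates = pd.concat(frames)
        mean = rates.groupby("group")["rate"].mean()
        assert mean["G7"] > mean[["G1", "G2", "G3"]].max()


class TestQuartileBins:
    def test_five_groups_from_baseline(self):
        baseline = pd.Series({"a": 0.0, "b": 1.0, "c": 2.0, "d": 3.0,
                              "e": 4.0})
        bins = ca.quartile_bins(baseline)
        assert bins["a"] == "Q0"
        assert sorted(bins[g] for g in "bcde") == ["Q1", "Q2", "Q3", "Q4"]

    def test_too_few_expressed_genes_is_error(self):
        with pytest.raises(ValueError, match="4 expressed"):
            ca.quartile_bins(pd.Series({"a": 0.0, "b": 1.0}))

    def test_statistics_fraction_and_gene_body_denominator(self):
        # statistic 2 is count/total SBS; statistic 3 divides by the tx
        # span (exons + introns), not the exon sum
        gene = make_gene("g", "chr1", "+", 0, 2_000_000,
                         exons=((0, 1000),))
        bins = {"g": "Q1"}
        ctxs = [tcw_ctx("chr1", 100 + i) for i in range(10)]
        ctxs += [PyrimidineContext("chr1", 3_000_000 + i, "T", "C", "+",
                                   "AATAG") for i in range(90)]
        out = ca.quartile_group_statistics(ctxs, bins, [gene], "T1")
        q1 = out[out.group == "Q1"].iloc[0]
        assert q1.n_tcw_mut == 10
        assert q1.fraction_of_sbs == pytest.approx(0.10)
        assert q1.per_mbp_gene_body == pytest.approx(10 / 2.0)


class TestStrandBias:
    def test_identical_counts_give_p_one(self):
        stat, p = ca.strand_bias_test([5, 6, 7], [5, 6, 7])
        assert p == pytest.approx(1.0)

    def test_swapping_labels_leaves_p_unchanged(self, rng):
        nts = list(rng.poisson(6, 15))
        ts = list(rng.poisson(3, 15))
        _, p1 = ca.strand_bias_test(nts, ts)
        _, p2 = ca.strand_bias_test(ts, nts)
        assert p1 == pytest.approx(p2)

    def test_planted_nts_excess_detected_at_twenty_tumors(self, rng):
        nts = list(rng.poisson(8, 20))
        ts = list(rng.poisson(1, 20))
        _, p = ca.strand_bias_test(nts, ts)
        assert p < 0.05

    def test_all_zero_counts_give_p_one(self):
        _, p = ca.strand_bias_test([0, 0, 0], [0, 0, 0])
        assert p == 1.0


class TestDeleteriousFilter:
    def test_keeps_only_deleterious_classes(self):
        muts = [
            MutationRecord("s", "c", 10, "C", "T", consequence="other"),
            MutationRecord("s", "c", 20, "C", "T", consequence="nonsense"),
            MutationRecord("s", "c", 30, "C", "CA",
                           consequence="frameshift_indel"),
            MutationRecord("s", "c", 40, "C", "T", consequence="splice_site"),
            MutationRecord("s", "c", 50, "C", "T", consequence="unknown"),
        ]
        kept, n_unknown = ca.deleterious_filter(muts)
        assert [m.pos for m in kept] == [20, 30, 40]
        assert n_unknown == 1

    def test_missense_only_input_empty(self):
        muts = [MutationRecord("s", "c", 10, "C", "T", consequence="other")]
        kept, _ = ca.deleterious_filter(muts)
        assert kept == []


class TestSpliceFactorAssociation:
    def test_two_by_two_enumeration_oracle(self):
        # [[2,0],[0,2]] two-sided Fisher: P(0)=1/6, P(1)=4/6, P(2)=1/6
        assert ca._two_sided_fisher([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_identical_proportions_give_p_one(self):
        assert ca._two_sided_fisher([[5, 5], [10, 10]]) == pytest.approx(1.0)

    def test_contingency_built_from_cohort(self):
        muts = [MutationRecord("s1", "c", 10, "C", "T",
                               consequence="nonsense", gene_id="sf1"),
                MutationRecord("s3", "c", 30, "C", "T",
                               consequence="other", gene_id="sf1")]
        positive = {"s1": True, "s2": False, "s3": False, "s4": True}
        out = ca.splice_factor_association(muts, {"sf1"}, positive, {})
        assert out.sf_mutant_samples == ["s1"]  # s3's hit is not deleterious
        assert out.apobec_by_sf.table == ((1, 0), (1, 2))


class TestHousekeepingNull:
    def test_unmutated_pool_gives_all_zero_summary(self):
        positive = {f"s{i}": i % 2 == 0 for i in range(6)}
        null = ca.housekeeping_null([], [f"g{i}" for i in range(30)],
                                    positive, k=10, iterations=50, seed=3)
        s = null.summary
        assert s["median_mutated_genes"] == s["max_mutated_genes"] == 0
        assert s["median_mutated_tumors"] == 0 and s["min_bh_q"] == 1.0

    def test_seeded_determinism(self):
        muts = [MutationRecord("s0", "c", 10, "C", "T",
                               consequence="nonsense", gene_id="g1"),
                MutationRecord("s1", "c", 20, "C", "T",
                               consequence="splice_site", gene_id="g5")]
        positive = {f"s{i}": i < 2 for i in range(6)}
        pool = [f"g{i}" for i in range(20)]
        a = ca.housekeeping_null(muts, pool, positive, k=8, iterations=200,
                                 seed=9)
        b = ca.housekeeping_null(muts, pool, positive, k=8, iterations=200,
                                 seed=9)
        assert a.summary == b.summary
        assert np.array_equal(a.mutated_genes, b.mutated_genes)

    def test_pool_smaller_than_k_is_error(self):
        with pytest.raises(ValueError, match="smaller than k"):
            ca.housekeeping_null([], ["g1"], {"s": True}, k=5, iterations=10)

    def test_zero_iterations_is_error(self):
        with pytest.raises(ValueError, match="iterations"):
            ca.housekeeping_null([], [f"g{i}" for i in range(10)],
                                 {"s": True}, k=5, iterations=0)
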