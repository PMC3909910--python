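"""Tests for accuracy scoring, CV, concordance, LD, QC and spectrum tests."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hlatag as ht


class TestScorePrediction:
    @pytest.mark.parametrize(
        "true,pred,expect",
        [
            (("0201", "1101"), ("0201", "1101"), 1.0),
            (("0201", "1101"), ("0201", "2402"), 0.5),
            (("0201", "0201"), ("1101", "2402"), 0.0),
            (("0201", "0201"), ("0201", "1101"), 0.5),  # homozygous truth, half match
            (("0201", "1101"), ("1101", "0201"), 1.0),  # order-free
        ],
    )
    def test_half_pair_convention(self, true, pred, expect):
        assert ht.score_prediction(true, pred) == expect

    def test_locus_mismatch_rejected(self):
        a = ht.HlaAllele("HLA-A", "0101")
        b = ht.HlaAllele("HLA-B", "0702")
        with pytest.raises(ValueError):
            ht.score_prediction((a, a), (b, b))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(["0101", "0201", "0301"]), min_size=4, max_size=4))
    def test_symmetric_and_bounded(self, codes):
        t, p = tuple(codes[:2]), tuple(codes[2:])
        s = ht.score_prediction(t, p)
        assert s in (0.0, 0.5, 1.0)
        assert s == ht.score_prediction(p, t)
        if set(t) == set(p) and sorted(t) == sorted(p):
            assert s == 1.0


class TestCrossValidate:
    def test_perfect_tags_give_perfect_accuracy(self, perfect_cohort):
        rep = ht.cross_validate(perfect_cohort, "HLA-A", k=5, ct=0.0, seed=1, max_snps=4)
        assert rep.mean_accuracy == 1.0
        assert rep.call_rate == 1.0

    def test_fold_partition(self, perfect_cohort):
        rep = ht.cross_validate(perfect_cohort, "HLA-A", k=5, ct=0.0, seed=2, max_snps=2)
        assert sorted(rep.fold_assignment.index) == sorted(perfect_cohort.samples)
        sizes = rep.fold_assignment.value_counts()
        assert sizes.max() - sizes.min() <= 1
        assert rep.per_fold["n_test"].sum() == perfect_cohort.n_samples

    def test_accuracy_is_tv_over_nv(self, noisy_cohort):
        pool, ds = noisy_cohort
        rep = ht.cross_validate(ds, pool.locus, k=3, ct=0.0, seed=3, max_snps=3)
        for _, row in rep.per_fold.iterrows():
            assert row["accuracy"] == pytest.approx(row["t_v"] / row["n_called"])
        scored = rep.predictions.loc[rep.predictions["called"], "score"]
        assert rep.pooled_accuracy == pytest.approx(scored.sum() / len(scored))

    def test_call_rate_one_at_ct_zero(self, noisy_cohort):
        pool, ds = noisy_cohort
        rep = ht.cross_validate(ds, pool.locus, k=3, ct=0.0, seed=4, max_snps=3)
        assert rep.call_rate == 1.0

    def test_call_rate_monotone_in_ct(self, noisy_cohort):
        pool, ds = noisy_cohort
        rates = [
            ht.cross_validate(ds, pool.locus, k=3, ct=ct, seed=5, max_snps=3).call_rate
            for ct in (0.0, 0.5, 0.9)
        ]
        assert rates[0] >= rates[1] >= rates[2]
        assert rates[0] == 1.0

    def test_higher_ct_raises_accuracy_on_average(self):
        """Filtering to confident calls cannot hurt accuracy (20 cohorts, on average)."""
        acc0, acc9 = [], []
        for seed in range(20):
            pool = ht.build_founder_pool(10, 3, 250_000, [0.5, 0.3, 0.2],
                                         (0.15, 0.5, 100_000), seed=seed)
            ds = ht.simulate_cohort(pool, ht.SimulationConfig(n_samples=160, seed=seed + 30))
            rows, pairs = ds.hla_pairs(pool.locus)
            train, test = rows[:110], rows[110:]
            model = ht.select_snps(ds.genotypes[train], ds.markers, pairs[:110],
                                   locus=pool.locus, max_snps=3)
            cols = [ds.marker_ids().index(m) for m in model.table.marker_ids]
            posts = [(model.posterior(ds.genotypes[t, cols]), p)
                     for t, p in zip(test, pairs[110:])]
            for ct, acc in ((0.0, acc0), (0.9, acc9)):
                scores = [ht.score_prediction(p, ht.call_genotype(post, ct).best_pair)
                          for post, p in posts
                          if ht.call_genotype(post, ct).called]
                if scores:
                    acc.append(np.mean(scores))
        assert np.mean(acc9) >= np.mean(acc0)

    def test_rare_alleles_flagged(self):
        pool = ht.build_founder_pool(8, 6, 200_000,
                                     [0.4, 0.3, 0.15, 0.1, 0.045, 0.005],
                                     (0.0, 0.0, 100_000), seed=41)
        ds = ht.simulate_cohort(pool, ht.SimulationConfig(n_samples=120, seed=42))
        rep = ht.cross_validate(ds, pool.locus, k=3, ct=0.0, seed=43, max_snps=2)
        counts = ds.hla[["allele1", "allele2"]].stack().value_counts()
        assert rep.rare_alleles == {c: int(n) for c, n in counts.items() if n < 3}


class TestKappa:
    def test_identical_calls(self):
        g = np.random.default_rng(1).integers(0, 3, size=500)
        rep = ht.cohens_kappa(g, g)
        assert rep.kappa == 1.0

    def test_hand_computed_two_category_case(self):
        a = np.array([0] * 25 + [1] * 25)
        b = np.array([0] * 20 + [1] * 5 + [0] * 10 + [1] * 15)
        rep = ht.cohens_kappa(a, b)
        assert rep.kappa == pytest.approx(0.4, abs=1e-12)  # p_o=0.7, p_e=0.5

    def test_chance_level_is_zero(self):
        # independent marginals: p_o equals p_e in expectation; exact construction
        a = np.array([0, 0, 1, 1])
        b = np.array([0, 1, 0, 1])
        assert ht.cohens_kappa(a, b).kappa == pytest.approx(0.0, abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(2)
        a = rng.integers(0, 3, size=300)
        b = np.where(rng.random(300) < 0.8, a, rng.integers(0, 3, size=300))
        assert ht.cohens_kappa(a, b).kappa == pytest.approx(
            cohen_kappa_score(a, b), abs=1e-12
        )

    def test_missing_cells_excluded_and_empty_rejected(self):
        a = np.array([0, 1, ht.MISSING])
        b = np.array([0, ht.MISSING, 2])
        assert ht.cohens_kappa(a, b).n_cells == 1
        with pytest.raises(ValueError):
            ht.cohens_kappa(np.array([ht.MISSING]), np.array([0]))

    def test_constant_and_equal_raters(self):
        assert ht.cohens_kappa(np.zeros(5), np.zeros(5)).kappa == 1.0


class TestVariation:
    @pytest.mark.parametrize(
        "a,b,expect",
        [({"a", "b", "c"}, {"a", "b", "c"}, 0.0),
         ({"a", "b"}, {"c", "d"}, 1.0),
         ({"a", "b", "c"}, {"b", "c", "d"}, 0.5)],
    )
    def test_union_minus_intersection_over_union(self, a, b, expect):
        assert ht.platform_variation(a, b) == expect

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            ht.platform_variation(set(), set())


class TestDprime:
    def _draw(self, hap_freqs, n=4000, seed=0):
        rng = np.random.default_rng(seed)
        haps = list(hap_freqs)
        p = np.array(list(hap_freqs.values()))
        idx = rng.choice(len(haps), size=(n, 2), p=p)
        g = np.array([haps[i][0] + haps[j][0] for i, j in idx])
        pairs = [ht.pair_key(haps[i][1], haps[j][1]) for i, j in idx]
        return g, pairs

    def test_complete_ld_is_one(self):
        g, pairs = self._draw({(0, "0101"): 0.5, (1, "0201"): 0.5})
        assert ht.multiallelic_dprime(g, pairs) == pytest.approx(1.0, abs=1e-6)

    def test_one_absent_haplotype_drives_dprime_to_one(self):
        g, pairs = self._draw({(0, "0101"): 0.5, (1, "0201"): 0.3, (0, "0201"): 0.2})
        assert ht.multiallelic_dprime(g, pairs) == pytest.approx(1.0, abs=0.02)

    def test_independent_loci_near_zero(self):
        rng = np.random.default_rng(3)
        g = rng.choice(2, 6000, p=[0.5, 0.5]) + rng.choice(2, 6000, p=[0.5, 0.5])
        al = rng.choice(["0101", "0201", "0301"], size=(6000, 2), p=[0.5, 0.3, 0.2])
        pairs = [ht.pair_key(a, b) for a, b in al]
        assert ht.multiallelic_dprime(g, pairs) < 0.1

    def test_monomorphic_snp_is_missing(self):
        g = np.zeros(100, dtype=int)
        pairs = [("0101", "0201")] * 100
        assert math.isnan(ht.multiallelic_dprime(g, pairs))

    def test_report_bounds(self, noisy_cohort):
        pool, ds = noisy_cohort
        rep = ht.ld_report(ds, pool.locus)
        vals = rep.dprime.dropna()
        assert ((vals >= 0) & (vals <= 1 + 1e-9)).all()
        assert rep.max_dprime == pytest.approx(vals.max())


def _hwe_oracle(n0, n1, n2):
    """Exact-fraction enumeration of the conditional het-count distribution."""
    n = n0 + n1 + n2
    nm = min(2 * n0 + n1, 2 * n2 + n1)
    probs = {}
    for het in range(nm % 2, nm + 1, 2):
        hom_min = (nm - het) // 2
        hom_maj = n - het - hom_min
        probs[het] = (
            Fraction(math.factorial(n), math.factorial(hom_min) * math.factorial(het)
                     * math.factorial(hom_maj))
            * Fraction(2**het)
            * Fraction(math.factorial(nm) * math.factorial(2 * n - nm),
                       math.factorial(2 * n))
        )
    p_obs = probs[n1]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestQc:
    def test_hwe_matches_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            n = int(rng.integers(5, 51))
            n0 = int(rng.integers(0, n + 1))
            n1 = int(rng.integers(0, n - n0 + 1))
            n2 = n - n0 - n1
            assert ht.hwe_exact_pvalue(n0, n1, n2) == pytest.approx(
                _hwe_oracle(n0, n1, n2), rel=1e-9, abs=1e-12
            )

    def test_balanced_genotypes_retained(self):
        # 25/50/25 sits exactly at HWE: p-value 1, SNP keeps all filters
        assert ht.hwe_exact_pvalue(25, 50, 25) > 0.999

    def _dataset(self, columns):
        import pandas as pd

        geno = np.column_stack(columns).astype(np.int8)
        n, m = geno.shape
        markers = pd.DataFrame({"id": [f"rs{k}" for k in range(m)], "chrom": "6",
                                "pos": np.arange(1, m + 1) * 100})
        hla = pd.DataFrame({"sample": [f"S{i}" for i in range(n)], "locus": "HLA-A",
                            "allele1": "0101", "allele2": "0101"})
        return ht.CohortDataset([f"S{i}" for i in range(n)], markers, geno, hla)

    def test_threshold_filters(self):
        n = 1000
        rng = np.random.default_rng(5)
        good = rng.choice([0, 1, 2], size=n, p=[0.49, 0.42, 0.09])
        low_maf = np.zeros(n, dtype=int)
        low_maf[:10] = 1  # MAF 0.005 < 0.01
        low_call = good.copy()
        low_call[: int(0.1 * n)] = ht.MISSING  # call rate 0.90 < 0.95
        hwe_fail = np.ones(n, dtype=int)  # all het: gross HWE violation
        ds = self._dataset([good, low_maf, low_call, hwe_fail])
        filtered, report = ht.qc_filter(ds)
        fate = dict(zip(report["id"], report["reason"]))
        assert fate["rs0"] == ""
        assert "maf" in fate["rs1"]
        assert "call_rate" in fate["rs2"]
        assert "hwe" in fate["rs3"]
        assert filtered.marker_ids() == ["rs0"]


class TestSpectrumComparison:
    def test_identical_counts_null_pvalue(self):
        fc = ht.compare_allele_frequencies([40, 30, 20, 10], [40, 30, 20, 10], seed=1)
        assert fc.mc_p >= 0.95

    def test_hand_computed_chi_square(self):
        fc = ht.compare_allele_frequencies([90, 10], [10, 90], seed=2)
        assert fc.chi2 == pytest.approx(128.0, abs=1e-9)  # expected counts all 50
        assert fc.mc_p == fc.min_p  # far beyond anything the null produces
        assert fc.asymptotic_p is not None and fc.asymptotic_p < 1e-10

    def test_seeded_determinism(self):
        a = ht.compare_allele_frequencies([50, 30, 5], [30, 40, 10], seed=7)
        b = ht.compare_allele_frequencies([50, 30, 5], [30, 40, 10], seed=7)
        assert a.mc_p == b.mc_p

    def test_sparse_table_suppresses_asymptotic_p(self):
        fc = ht.compare_allele_frequencies([50, 1], [48, 3], seed=3)
        assert fc.asymptotic_p is None

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            ht.compare_allele_frequencies([0, 0], [1, 2])
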