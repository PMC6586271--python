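import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from mixstock.io import MISSING, LocusInfo
from mixstock.popgen import (
    collinear_allele_bootstrap,
    fst_global,
    fst_pairwise,
    heterozygosities,
    hwe_chi2,
    hwe_test,
    multilocus_theta,
    sequential_bonferroni,
    temporal_pooling_test,
    weir_cockerham_components,
)
from mixstock.simulate import SimulationConfig, simulate

from conftest import make_matrix
from oracles import anova_theta, anova_theta_components, hwe_exact_pairing_p


class TestHeterozygosity:
    def test_balanced_sample(self):
        g = make_matrix(np.array([[0], [1], [2], [1]]), units=["U"] * 4)
        row = heterozygosities(g).iloc[0]
        assert row["H_obs"] == pytest.approx(0.5)
        assert row["H_exp"] == pytest.approx(0.5)
        assert row["F_IS"] == pytest.approx(0.0)

    def test_all_heterozygous_gives_negative_fis(self):
        g = make_matrix(np.ones((8, 1)), units=["U"] * 8)
        row = heterozygosities(g).iloc[0]
        assert row["H_obs"] == 1.0
        assert row["H_exp"] == pytest.approx(0.5)
        assert row["F_IS"] == pytest.approx(-1.0)

    def test_monomorphic_fis_flagged(self):
        g = make_matrix(np.zeros((5, 1)), units=["U"] * 5)
        row = heterozygosities(g).iloc[0]
        assert row["H_exp"] == 0.0
        assert np.isnan(row["F_IS"])

    def test_small_sample_correction_factor(self):
        g = make_matrix(np.array([[0], [1], [2], [1]]), units=["U"] * 4)
        plain = heterozygosities(g).iloc[0]["H_exp"]
        corrected = heterozygosities(g, small_sample_correction=True).iloc[0]["H_exp"]
        assert corrected == pytest.approx(plain * 8 / 7)


class TestHWE:
    def test_perfect_proportions_chi2_zero(self):
        assert hwe_chi2(25, 50, 25) == pytest.approx(0.0)

    def test_no_heterozygotes_chi2(self):
        assert hwe_chi2(50, 0, 50) == pytest.approx(100.0)

    def test_permutation_p_at_equilibrium_is_one_ish(self):
        calls = np.repeat([0, 1, 2], [25, 50, 25])
        g = make_matrix(calls[:, None], units=["U"] * 100)
        res = hwe_test(g, n_perm=200, seed=0)
        assert res.iloc[0]["chi2"] == pytest.approx(0.0)
        assert res.iloc[0]["p"] == pytest.approx(1.0)

    @pytest.mark.parametrize("calls", [
        [0, 1, 1, 2], [0, 0, 2, 2], [1, 1, 1, 1], [0, 2, 2, 2]])
    def test_permutation_matches_exhaustive_enumeration(self, calls):
        """With four individuals the allele-pairing null can be enumerated
        exactly; the Monte-Carlo p must agree within sampling error."""
        exact = hwe_exact_pairing_p(np.array(calls))
        g = make_matrix(np.array(calls)[:, None], units=["U"] * 4)
        n_perm = 20_000
        res = hwe_test(g, n_perm=n_perm, seed=1)
        mc_err = 4 * np.sqrt(exact * (1 - exact) / n_perm) + 2 / n_perm
        assert res.iloc[0]["p"] == pytest.approx(exact, abs=mc_err)

    def test_monomorphic_locus_flagged(self):
        g = make_matrix(np.zeros((6, 1)), units=["U"] * 6)
        res = hwe_test(g, n_perm=50, seed=0)
        assert not res.iloc[0]["tested"]

    def test_pooled_row_present(self, two_pop_small):
        res = hwe_test(two_pop_small, "sampling_unit", n_perm=50, seed=0,
                       include_pooled=True)
        assert "pooled" in set(res["group"])


class TestWeirCockerham:
    def test_fixed_difference_theta_one(self):
        calls = np.vstack([np.zeros((10, 5)), np.full((10, 5), 2)])
        g = make_matrix(calls, units=["A"] * 10 + ["B"] * 10)
        res = fst_global(g, "sampling_unit", n_boot=0)
        np.testing.assert_allclose(res["theta"], 1.0)

    def test_identical_groups_nonpositive_theta(self):
        block = np.repeat([[0, 1, 2, 1]], 5, axis=0).T.reshape(4, 5)[:, :1]
        block = np.array([[0], [1], [2], [1]])
        calls = np.vstack([block, block])
        g = make_matrix(calls, units=["A"] * 4 + ["B"] * 4)
        comp = weir_cockerham_components(g.calls, np.array([0] * 4 + [1] * 4))
        assert comp[0, 0] <= 0  # among-population component
        res = fst_global(g, "sampling_unit", n_boot=0)
        assert res.iloc[0]["theta"] <= 0

    def test_matches_anova_oracle_random_fixtures(self):
        """Closed-form frequency expressions must agree with the explicit
        nested-ANOVA route to near machine precision, including missing data
        and unbalanced groups."""
        rng = np.random.default_rng(123)
        for trial in range(30):
            r = rng.integers(2, 5)
            sizes = rng.integers(3, 12, size=r)
            codes = np.repeat(np.arange(r), sizes)
            p = rng.uniform(0.05, 0.95, size=(r, 6))
            calls = np.vstack([rng.binomial(2, p[c]) for c in codes]).astype(np.int8)
            calls[rng.random(calls.shape) < 0.1] = MISSING
            mine = weir_cockerham_components(calls, codes)
            oracle = anova_theta_components(calls, codes)
            np.testing.assert_allclose(mine, oracle, atol=1e-10, equal_nan=True)

    def test_multilocus_theta_is_ratio_of_sums(self):
        rng = np.random.default_rng(5)
        codes = np.repeat([0, 1], 10)
        diverged = np.where(codes == 0, rng.binomial(2, 0.9, 20),
                            rng.binomial(2, 0.2, 20))
        shared = rng.binomial(2, 0.5, 20)
        calls = np.stack([diverged, shared], axis=1).astype(np.int8)
        comp = weir_cockerham_components(calls, codes)
        expected = comp[:, 0].sum() / comp.sum()
        g = make_matrix(calls, units=["A"] * 10 + ["B"] * 10)
        assert multilocus_theta(g, "sampling_unit") == pytest.approx(expected, abs=1e-12)
        # and differs in general from the mean of per-locus ratios
        per_locus = comp[:, 0] / comp.sum(axis=1)
        assert multilocus_theta(g, "sampling_unit") != pytest.approx(
            np.nanmean(per_locus), abs=1e-6)

    def test_theta_invariant_to_allele_relabel_and_group_order(self, two_pop_small):
        g = two_pop_small
        base = multilocus_theta(g, "sampling_unit")
        flipped = np.where(g.calls == MISSING, MISSING, 2 - g.calls).astype(np.int8)
        g_flip = make_matrix(flipped, units=list(g.metadata["sampling_unit"]))
        assert multilocus_theta(g_flip, "sampling_unit") == pytest.approx(base, abs=1e-12)
        perm = np.random.default_rng(0).permutation(g.n_individuals)
        g_perm = g.subset(individuals=[g.individuals[i] for i in perm])
        assert multilocus_theta(g_perm, "sampling_unit") == pytest.approx(base, abs=1e-12)

    def test_pairwise_fixed_difference_degenerate_ci(self):
        calls = np.vstack([np.zeros((8, 4)), np.full((8, 4), 2)])
        g = make_matrix(calls, units=["A"] * 8 + ["B"] * 8)
        pw = fst_pairwise(g, "sampling_unit", n_boot=100, seed=0)
        assert pw.theta.loc["A", "B"] == pytest.approx(1.0)
        assert pw.ci_low.loc["A", "B"] == pytest.approx(1.0)
        assert pw.significant.loc["A", "B"]

    def test_panmictic_type_one_error(self):
        """Two groups cut from one panmictic population should rarely be
        called significant at nominal 95% CIs."""
        rng = np.random.default_rng(99)
        false_pos = 0
        n_rep = 60
        for rep in range(n_rep):
            p = rng.uniform(0.2, 0.8, size=12)
            calls = rng.binomial(2, p, size=(40, 12)).astype(np.int8)
            g = make_matrix(calls, units=["A"] * 20 + ["B"] * 20)
            pw = fst_pairwise(g, "sampling_unit", n_boot=300, seed=rep)
            false_pos += bool(pw.significant.loc["A", "B"])
        assert 1 - false_pos / n_rep >= 0.90

    def test_bootstrap_reproducible_with_seed(self, two_pop_small):
        a = fst_global(two_pop_small, "sampling_unit", n_boot=50, seed=11)
        b = fst_global(two_pop_small, "sampling_unit", n_boot=50, seed=11)
        pd.testing.assert_frame_equal(a, b)


class TestTemporalPooling:
    def test_identical_strata_pool(self):
        block = np.array([[0], [1], [2], [1], [0], [2]] * 3)
        calls = np.vstack([block, block])
        n = len(calls)
        g = make_matrix(calls, units=["SD26"] * n,
                        year=[2015] * (n // 2) + [2016] * (n // 2))
        res = temporal_pooling_test(g, "SD26", n_boot=100, seed=0)
        assert res["pool"]

    def test_divergent_strata_do_not_pool(self):
        rng = np.random.default_rng(3)
        a = rng.binomial(2, 0.85, size=(30, 15))
        b = rng.binomial(2, 0.15, size=(30, 15))
        g = make_matrix(np.vstack([a, b]), units=["SD26"] * 60,
                        year=[2015] * 30 + [2016] * 30)
        res = temporal_pooling_test(g, "SD26", n_boot=200, seed=0)
        assert not res["pool"]
        assert res["max_theta"] > 0.2

    def test_single_year_pools_trivially(self):
        g = make_matrix(np.array([[0], [1], [2]]), units=["SD26"] * 3,
                        year=[2015] * 3)
        res = temporal_pooling_test(g, "SD26", n_boot=10, seed=0)
        assert res["pool"] and res["matrix"] is None


class TestSequentialBonferroni:
    def test_worked_example(self):
        res = sequential_bonferroni([0.01, 0.04], alpha=0.05)
        assert res["reject"].all()

    def test_all_ones_rejected_none(self):
        res = sequential_bonferroni([1.0] * 5)
        assert not res["reject"].any()

    def test_matches_independent_holm(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            p = rng.uniform(0, 1, size=rng.integers(1, 15)) ** 2
            mine = sequential_bonferroni(p, alpha=0.05)
            ref_reject, ref_adj, *_ = multipletests(p, alpha=0.05, method="holm")
            np.testing.assert_array_equal(mine["reject"], ref_reject)
            np.testing.assert_allclose(mine["p_adjusted"], ref_adj, atol=1e-12)


class TestCollinearAllele:
    def _inversion_matrix(self, calls, units):
        loci = [LocusInfo.from_locus_id("LG02_18724285_I02")]
        return make_matrix(np.asarray(calls), units=units, loci=loci)

    def test_fixed_collinear_is_significant_overrepresentation(self):
        # collinear allele is ref; all hom-ref -> collinear frequency 1
        g = self._inversion_matrix(np.zeros((20, 1)), ["U"] * 20)
        res = collinear_allele_bootstrap(g, "sampling_unit", n_boot=500, seed=0)
        assert res.iloc[0]["collinear_freq"] == pytest.approx(1.0)
        assert res.iloc[0]["significant"]

    def test_balanced_group_rarely_significant(self):
        rng = np.random.default_rng(21)
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            calls = rng.binomial(2, 0.5, size=(60, 1))
            g = self._inversion_matrix(calls, ["U"] * 60)
            res = collinear_allele_bootstrap(g, "sampling_unit", n_boot=300,
                                             seed=rep)
            hits += bool(res.iloc[0]["significant"])
        assert 1 - hits / n_rep >= 0.90

    def test_single_individual_low_confidence(self):
        g = self._inversion_matrix([[0]], ["U"])
        res = collinear_allele_bootstrap(g, "sampling_unit", n_boot=50, seed=0)
        assert res.iloc[0]["low_confidence"]

    def test_requires_collinear_designation(self, two_pop_small):
        with pytest.raises(ValueError, match="no collinear allele"):
            collinear_allele_bootstrap(two_pop_small, "sampling_unit",
                                       loci=[two_pop_small.locus_ids[0]],
                                       n_boot=10, seed=0)


class TestWahlund:
    def test_pooling_divergent_populations_inflates_hwe_rejections(self):
        """Mechanical mixing of diverged populations produces a heterozygote
        deficit: pooled-sample HWE rejections at diagnostic loci exceed the
        within-population rate."""
        cfg = SimulationConfig(seed=31, n_diagnostic=30,
                               units={"W": (50, 1.0), "E": (50, 0.0)})
        g = simulate(cfg)
        res = hwe_test(g, "sampling_unit", n_perm=400, seed=2, include_pooled=True)
        rej = (res.assign(sig=res["p"] < 0.05)
               .groupby("group")["sig"].mean())
        assert rej["pooled"] > max(rej["W"], rej["E"])
        assert rej["pooled"] > 0.5
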