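import numpy as np
import pandas as pd
import pytest

from mixstock._tw_table import TW1_CDF, TW1_X
from mixstock.io import MISSING
from mixstock.pca import ReferencePCA, tracy_widom_test, tw_sf
from mixstock.simulate import SimulationConfig, simulate

from conftest import make_matrix


class TestNormalization:
    def test_direct_arithmetic(self):
        g = make_matrix(np.array([[0], [2]]), units=["U"] * 2)
        model = ReferencePCA(g, np.array([True, True]))
        x, p, scale = model.normalized()
        assert p[0] == pytest.approx(0.5)   # (1 + 2) / (2 + 4)
        np.testing.assert_allclose(x[:, 0], [-2.0, 2.0])

    def test_missing_entries_zero(self):
        g = make_matrix(np.array([[0], [2], [MISSING]]), units=["U"] * 3)
        model = ReferencePCA(g, np.array([True, True, False]))
        x, _, _ = model.normalized()
        assert x[2, 0] == 0.0

    def test_reference_column_means_near_zero(self):
        rng = np.random.default_rng(6)
        calls = rng.binomial(2, rng.uniform(0.2, 0.8, 30), size=(50, 30)).astype(np.int8)
        g = make_matrix(calls, units=["U"] * 50)
        x, _, _ = ReferencePCA(g, np.ones(50, bool)).normalized()
        # pseudocount shifts the mean by O(1/n)
        assert np.abs(x.mean(axis=0)).max() < 3 / 50 * 4


class TestReferencePCA:
    def test_fixed_difference_pc1_separates_with_zero_spread(self):
        calls = np.vstack([np.zeros((5, 8)), np.full((5, 8), 2)])
        g = make_matrix(calls, units=["A"] * 5 + ["B"] * 5)
        res = ReferencePCA(g, np.ones(10, bool)).fit()
        pc1 = res.coords[:, 0]
        assert np.sign(pc1[:5]).std() == 0 and np.sign(pc1[5:]).std() == 0
        assert np.sign(pc1[0]) != np.sign(pc1[5])
        assert np.std(pc1[:5]) < 1e-8 and np.std(pc1[5:]) < 1e-8

    def test_duplicate_individuals_identical_coords(self):
        rng = np.random.default_rng(7)
        row = rng.integers(0, 3, size=12).astype(np.int8)
        calls = np.vstack([row, row, rng.integers(0, 3, size=(6, 12))]).astype(np.int8)
        g = make_matrix(calls, units=["U"] * 8)
        res = ReferencePCA(g, np.ones(8, bool)).fit()
        np.testing.assert_allclose(res.coords[0], res.coords[1], atol=1e-8)

    def test_eigenvalues_match_eigh_oracle(self):
        rng = np.random.default_rng(8)
        calls = rng.binomial(2, rng.uniform(0.2, 0.8, 25), size=(20, 25)).astype(np.int8)
        g = make_matrix(calls, units=["U"] * 20)
        model = ReferencePCA(g, np.ones(20, bool))
        res = model.fit()
        x, _, _ = model.normalized()
        cov = x @ x.T / x.shape[1]
        oracle = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(res.eigenvalues, oracle[:len(res.eigenvalues)],
                                   atol=1e-8)

    def test_monomorphic_reference_rejected(self):
        g = make_matrix(np.zeros((4, 3)), units=["U"] * 4)
        with pytest.raises(ValueError, match="polymorphic"):
            ReferencePCA(g, np.ones(4, bool)).fit()

    def test_variance_explained_flat_without_structure(self):
        rng = np.random.default_rng(9)
        calls = rng.binomial(2, 0.5, size=(30, 200)).astype(np.int8)
        g = make_matrix(calls, units=["U"] * 30)
        res = ReferencePCA(g, np.ones(30, bool)).fit()
        assert res.variance_explained[0] < 3.0 / min(30, 200)
        assert res.variance_explained.sum() <= 1.0 + 1e-9


@pytest.fixture(scope="module")
def projection_fitted():
    cfg = SimulationConfig(seed=29, n_diagnostic=30,
                           units={"W": (25, 1.0), "E": (25, 0.0),
                                  "MIX": (30, 0.5)})
    g = simulate(cfg)
    mask = g.metadata["sampling_unit"].isin(["W", "E"]).to_numpy()
    return g, ReferencePCA(g, mask).fit()


class TestProjection:

    def test_reference_projection_self_consistent(self, projection_fitted):
        g, res = projection_fitted
        mask = res.model.reference_mask
        proj = res.project(g.calls[mask])
        np.testing.assert_allclose(proj, res.coords[mask], atol=1e-8)

    def test_heavy_missingness_stays_in_cluster(self, projection_fitted):
        g, res = projection_fitted
        east_rows = np.flatnonzero((g.metadata["true_origin"] == "east")
                                   & res.model.reference_mask)
        row = g.calls[east_rows[0]].copy()
        rng = np.random.default_rng(0)
        row[rng.random(row.size) < 0.4] = MISSING
        coord = res.project(row)[0, 0]
        east_range = res.coords[east_rows, 0]
        pad = 3 * east_range.std() + 1e-6
        assert east_range.min() - pad <= coord <= east_range.max() + pad

    def test_f1_hybrid_between_centroids(self, projection_fitted):
        g, res = projection_fitted
        unit = g.metadata["sampling_unit"].to_numpy()
        w_mean = res.coords[unit == "W", 0].mean()
        e_mean = res.coords[unit == "E", 0].mean()
        f1 = np.ones(g.n_loci, dtype=np.int8)
        coord = res.project(f1)[0, 0]
        lo, hi = sorted([w_mean, e_mean])
        assert lo < coord < hi

    def test_all_missing_individual_flagged(self, projection_fitted):
        g, res = projection_fitted
        coord = res.project(np.full(g.n_loci, MISSING, dtype=np.int8))
        assert np.isnan(coord).all()


class TestTracyWidom:
    def test_interpolation_identity_at_knots(self):
        np.testing.assert_allclose(tw_sf(TW1_X), np.clip(1 - TW1_CDF, 1e-6, 1.0),
                                   atol=1e-12)

    def test_below_range_reports_one(self):
        assert tw_sf(-10.0) == 1.0

    def test_far_above_range_floored(self):
        assert tw_sf(50.0) == pytest.approx(1e-6)

    def test_published_percentiles(self):
        # 95th and 99th percentiles of the TW1 law
        assert tw_sf(0.9793) == pytest.approx(0.05, abs=0.002)
        assert tw_sf(2.0234) == pytest.approx(0.01, abs=0.002)

    def test_structured_axis_one_significant_axis_two_not(self):
        hits = 0
        for rep in range(10):
            cfg = SimulationConfig(seed=200 + rep, n_diagnostic=0,
                                   n_candidate=200, candidate_F=0.05,
                                   units={"W": (50, 1.0), "E": (50, 0.0)})
            g = simulate(cfg)
            res = ReferencePCA(g, np.ones(g.n_individuals, bool)).fit()
            tw = res.tracy_widom()
            hits += (tw.loc[0, "p"] < 0.01) and not (tw.loc[1, "p"] < 0.01)
        assert hits >= 9

    def test_null_matrix_axis_one_rarely_significant(self):
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            rng = np.random.default_rng(3000 + rep)
            calls = rng.binomial(2, 0.5, size=(50, 150)).astype(np.int8)
            g = make_matrix(calls, units=["U"] * 50)
            tw = ReferencePCA(g, np.ones(50, bool)).fit().tracy_widom()
            hits += not (tw.loc[0, "p"] < 0.01)
        assert hits / n_rep >= 0.90


@pytest.fixture(scope="module")
def assignment_fitted():
    cfg = SimulationConfig(seed=37, n_diagnostic=20,
                           units={"W": (30, 1.0), "E": (30, 0.0),
                                  "MIX": (40, 0.4)})
    g = simulate(cfg)
    mask = g.metadata["sampling_unit"].isin(["W", "E"]).to_numpy()
    res = ReferencePCA(g, mask).fit()
    labels = g.metadata.loc[mask, "sampling_unit"]
    return g, res, labels


class TestAssignment:

    def test_individual_at_centroid_gets_cluster(self, assignment_fitted):
        g, res, labels = assignment_fitted
        calls = res.assign(labels, axes=[1], margin=0.2)
        unit = g.metadata["sampling_unit"]
        w_labels = calls.loc[(unit == "W").to_numpy(), "label"]
        assert (w_labels == "W").all()

    def test_mixed_unit_split_matches_truth(self, assignment_fitted):
        g, res, labels = assignment_fitted
        calls = res.assign(labels, axes=[1], margin=0.2)
        mix = (g.metadata["sampling_unit"] == "MIX").to_numpy()
        truth = np.where(g.metadata["true_origin"][mix] == "west", "W", "E")
        got = calls.loc[mix, "label"].to_numpy()
        assigned = got != "unassigned"
        assert assigned.mean() > 0.9
        assert (got[assigned] == truth[assigned]).mean() == 1.0

    def test_equidistant_individual_unassigned(self, assignment_fitted):
        g, res, labels = assignment_fitted
        # fabricate a coordinate exactly between the centroids
        res2 = res
        mid = np.full(g.n_loci, 1, dtype=np.int8)
        coord = res2.project(mid)
        df = res2.assign(labels, axes=[1], margin=0.2)
        # the synthetic mid-point genotype corresponds to a tiny margin
        pos = {ind: i for i, ind in enumerate(g.individuals)}
        centroids = {lab: res.coords[[pos[i] for i in labels.index[labels == lab]], 0].mean()
                     for lab in ("W", "E")}
        d = sorted(abs(coord[0, 0] - c) for c in centroids.values())
        assert (d[1] - d[0]) / d[1] < 0.5

    def test_label_invariance_under_locus_permutation_and_relabel(self):
        cfg = SimulationConfig(seed=41, n_diagnostic=15,
                               units={"W": (20, 1.0), "E": (20, 0.0),
                                      "MIX": (20, 0.5)})
        g = simulate(cfg)
        mask = g.metadata["sampling_unit"].isin(["W", "E"]).to_numpy()
        labels = g.metadata.loc[mask, "sampling_unit"]

        def run(gm):
            res = ReferencePCA(gm, mask).fit()
            return res.assign(labels, axes=[1], margin=0.2)["label"]

        base = run(g)
        perm = np.random.default_rng(0).permutation(g.n_loci)
        g_perm = g.subset(loci=[g.locus_ids[j] for j in perm])
        pd.testing.assert_series_equal(run(g_perm), base)
        from mixstock.io import GenotypeMatrix

        flipped = np.where(g.calls == MISSING, MISSING, 2 - g.calls).astype(np.int8)
        g_flip = GenotypeMatrix(g.individuals, g.loci, flipped, g.metadata)
        flip_labels = run(g_flip)
        assert (flip_labels.to_numpy() == base.to_numpy()).all()
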