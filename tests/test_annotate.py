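import numpy as np
import pandas as pd
import pytest

import rankatlas as ra
from rankatlas.annotate import _mww
from rankatlas.core_io import ValidationError
from oracles import bh_stepup, mww_exact_p, simplex_grid_best


class TestBuildCentroids:
    def test_single_sample_type_equals_its_rank_vector(self, built):
        model, ranks = built["model"], built["ranks"]
        table = model.sample_table.data.copy()
        lone = table.index[0]
        table.loc[lone, "cell_type"] = "lonely"
        model2 = ra.AtlasModel(
            gene_ids=model.gene_ids, gene_means=model.gene_means,
            loadings=model.loadings, explained_variance=model.explained_variance,
            coords=model.coords, sample_table=ra.SampleTable(table),
            gene_stats=model.gene_stats, config=model.config,
        )
        cents = ra.build_centroids(model2, ranks=ranks)
        np.testing.assert_allclose(
            cents.centroids["lonely"].to_numpy(),
            ranks.values.loc[model.gene_ids, lone].to_numpy(),
        )
        assert "lonely" in cents.low_confidence

    def test_two_sample_type_is_per_gene_mean(self, built):
        model, ranks = built["model"], built["ranks"]
        cents = ra.build_centroids(model, ranks=ranks)
        members = model.sample_table.data.index[
            model.sample_table.data["cell_type"] == "type0"
        ]
        np.testing.assert_allclose(
            cents.centroids["type0"].to_numpy(),
            ranks.values.loc[model.gene_ids, members].mean(axis=1).to_numpy(),
        )

    def test_each_centroid_closest_to_own_type_on_average(self, built):
        model, ranks = built["model"], built["ranks"]
        cents = ra.build_centroids(model, ranks=ranks)
        R = ranks.values.loc[model.gene_ids]
        types = model.sample_table.data["cell_type"]
        # brute-force Euclidean distances, sample-by-centroid
        for t in cents.types:
            mean_dists = {
                t2: np.linalg.norm(
                    R[types.index[types == t]].to_numpy()
                    - cents.centroids[t2].to_numpy()[:, None],
                    axis=0,
                ).mean()
                for t2 in cents.types
            }
            assert min(mean_dists, key=mean_dists.get) == t

    def test_values_in_unit_interval(self, built):
        cents = ra.build_centroids(built["model"])  # reconstruction path
        assert cents.centroids.to_numpy().min() >= 0.0
        assert cents.centroids.to_numpy().max() <= 1.0

    def test_unknown_field_is_error(self, built):
        with pytest.raises(ValidationError):
            ra.build_centroids(built["model"], by="no_such_column")


class TestSimilarityScores:
    def test_query_equal_centroid_scores_one(self, built):
        cents = ra.build_centroids(built["model"], ranks=built["ranks"])
        q = cents.centroids["type1"].rename("q")
        scores = ra.similarity_scores(cents, q)
        assert scores.loc["q", "type1"] == pytest.approx(1.0, abs=1e-12)
        assert scores.loc["q", "call"] == "type1"

    def test_reflected_query_scores_minus_one(self, built):
        # reflecting every deviation about the rank midpoint anti-correlates exactly
        cents = ra.build_centroids(built["model"], ranks=built["ranks"])
        q = (0.5 + (0.5 - cents.centroids["type2"])).rename("q")
        scores = ra.similarity_scores(cents, q)
        assert scores.loc["q", "type2"] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_hand_formula(self, built):
        cents = ra.build_centroids(built["model"], ranks=built["ranks"])
        rng = np.random.default_rng(13)
        q = pd.Series(rng.random(len(cents.centroids)), index=cents.centroids.index,
                      name="q")
        scores = ra.similarity_scores(cents, q)
        for t in cents.types:
            c = cents.centroids[t].to_numpy()
            qa = q.to_numpy()
            cov = ((qa - qa.mean()) * (c - c.mean())).mean()
            hand = cov / (qa.std() * c.std())
            assert scores.loc["q", t] == pytest.approx(hand, abs=1e-12)

    def test_zero_variance_query_is_error(self, built):
        cents = ra.build_centroids(built["model"], ranks=built["ranks"])
        q = pd.Series(0.5, index=cents.centroids.index, name="flat")
        with pytest.raises(ValidationError, match="zero variance"):
            ra.similarity_scores(cents, q)


class TestCapybaraWeights:
    def test_pure_centroid_recovers_unit_weight(self, built):
        cents = ra.build_centroids(built["model"], ranks=built["ranks"])
        q = cents.centroids["type3"].rename("q")
        w = ra.capybara_weights(cents, q)
        assert w.loc["q", "type3"] == pytest.approx(1.0, abs=1e-6)
        assert w.loc["q", "call"] == "type3"

    def test_noiseless_mixture_recovered_and_matches_grid_oracle(self, built):
        cents = ra.build_centroids(built["model"], ranks=built["ranks"])
        pair = cents.centroids[["type0", "type1"]]
        q = (0.6 * pair["type0"] + 0.4 * pair["type1"]).rename("mix")
        sub = ra.CentroidSet(centroids=pair, n_samples=cents.n_samples[["type0", "type1"]])
        w = ra.capybara_weights(sub, q)
        assert w.loc["mix", "type0"] == pytest.approx(0.6, abs=0.01)
        assert w.loc["mix", "type1"] == pytest.approx(0.4, abs=0.01)
        grid = simplex_grid_best(pair.to_numpy(), q.to_numpy())
        assert w.loc["mix", ["type0", "type1"]].to_numpy() == pytest.approx(
            grid, abs=0.01
        )
        assert w.loc["mix", "call"] == "type0"

    def test_balanced_mixture_called_hybrid(self, built):
        # no single weight can reach the 0.5 call threshold for a 3-way blend
        cents = ra.build_centroids(built["model"], ranks=built["ranks"])
        c = cents.centroids
        q = (0.4 * c["type0"] + 0.35 * c["type1"] + 0.25 * c["type2"]).rename("h")
        w = ra.capybara_weights(cents, q)
        assert w.loc["h", "call"].startswith("hybrid:")

    def test_weights_live_on_simplex(self, built):
        cents = ra.build_centroids(built["model"], ranks=built["ranks"])
        rng = np.random.default_rng(21)
        Q = pd.DataFrame(rng.random((len(cents.centroids), 20)),
                         index=cents.centroids.index,
                         columns=[f"q{i}" for i in range(20)])
        w = ra.capybara_weights(cents, Q)
        vals = w[cents.types].to_numpy()
        assert vals.min() >= 0.0
        np.testing.assert_allclose(vals.sum(axis=1), 1.0, atol=1e-8)

    def test_all_zero_solution_degenerate_uniform(self):
        cents = ra.CentroidSet(
            centroids=pd.DataFrame({"a": [0.1, 0.2], "b": [0.2, 0.1]},
                                   index=["g1", "g2"]),
            n_samples=pd.Series({"a": 3, "b": 3}),
        )
        # query orthogonal to the positive cone: NNLS returns all zeros
        q = pd.Series([-1.0, -1.0], index=["g1", "g2"], name="neg")
        w = ra.capybara_weights(cents, q)
        np.testing.assert_allclose(w.loc["neg", ["a", "b"]].astype(float), 0.5)
        assert "neg" in w.attrs["degenerate"]

    def test_identical_centroids_rejected(self):
        cents = ra.CentroidSet(
            centroids=pd.DataFrame({"a": [0.3, 0.6], "b": [0.3, 0.6]},
                                   index=["g1", "g2"]),
            n_samples=pd.Series({"a": 3, "b": 3}),
        )
        with pytest.raises(ValidationError, match="identical"):
            ra.capybara_weights(cents, pd.Series([0.3, 0.6], index=["g1", "g2"]))

    def test_holdout_identity_recovery(self, holdout):
        qranks = ra.rank_transform(
            holdout["matrix"].select_samples(holdout["test_ids"])
        )
        w = ra.capybara_weights(holdout["centroids"], qranks)
        pred = w[holdout["centroids"].types].astype(float).idxmax(axis=1)
        truth = holdout["truth"].true_type[holdout["test_ids"]]
        assert (pred == truth).mean() >= 0.95


def _rank_matrix_from(values_by_gene, sample_ids):
    df = pd.DataFrame(values_by_gene, index=sample_ids).T
    return ra.ExpressionMatrix(df, "rank")


def _de_table(sample_ids, groups):
    return ra.SampleTable(pd.DataFrame(
        {"dataset_id": "d", "platform": "p", "cell_type": groups,
         "sample_source": "in vivo", "tissue": "t"},
        index=pd.Index(sample_ids, name="sample_id")))


class TestRankSumDE:
    def test_worked_example_u0_p01(self):
        ids = [f"s{i}" for i in range(6)]
        ranks = _rank_matrix_from({"g": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]}, ids)
        table = _de_table(ids, ["a"] * 3 + ["b"] * 3)
        de = ra.rank_sum_de(ranks, table, {"cell_type": "a"}, {"cell_type": "b"})
        assert de.loc["g", "u_statistic"] == 0.0
        assert de.loc["g", "p_value"] == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_midpoint_u_p_one(self):
        ids = [f"s{i}" for i in range(6)]
        ranks = _rank_matrix_from({"g": [0.1, 0.2, 0.3, 0.1, 0.2, 0.3]}, ids)
        table = _de_table(ids, ["a"] * 3 + ["b"] * 3)
        de = ra.rank_sum_de(ranks, table, {"cell_type": "a"}, {"cell_type": "b"})
        assert de.loc["g", "u_statistic"] == pytest.approx(4.5)  # n_a*n_b/2
        assert de.loc["g", "p_value"] == pytest.approx(1.0)

    def test_exact_path_matches_full_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n_a = int(rng.integers(2, 8))
            n_b = int(rng.integers(2, 8))
            pooled = rng.permutation(np.arange(n_a + n_b, dtype=float) / (n_a + n_b))
            a, b = pooled[:n_a], pooled[n_a:]
            _, p = _mww(a, b)
            assert p == pytest.approx(mww_exact_p(a, b), abs=1e-12)

    def test_swap_symmetry(self, built):
        ranks, samples = built["ranks"], built["samples"]
        sub = ra.ExpressionMatrix(ranks.values.iloc[:40], "rank")
        ab = ra.rank_sum_de(sub, samples, {"cell_type": "type0"}, {"cell_type": "type1"})
        ba = ra.rank_sum_de(sub, samples, {"cell_type": "type1"}, {"cell_type": "type0"})
        np.testing.assert_array_equal(ab["p_value"], ba["p_value"])
        np.testing.assert_allclose(ab["delta_median_rank"], -ba["delta_median_rank"])

    def test_bh_matches_hand_stepup(self, built):
        sub = ra.ExpressionMatrix(built["ranks"].values.iloc[:60], "rank")
        de = ra.rank_sum_de(sub, built["samples"],
                            {"cell_type": "type0"}, {"cell_type": "type1"})
        hand = bh_stepup(de["p_value"].to_numpy())
        np.testing.assert_allclose(de["q_value"].to_numpy(), hand, atol=1e-12)
        # step-up property: q non-decreasing when sorted by p
        q_sorted = de.sort_values("p_value")["q_value"].to_numpy()
        assert (np.diff(q_sorted) >= -1e-12).all()

    def test_overlapping_groups_rejected(self, built):
        with pytest.raises(ValidationError, match="overlap"):
            ra.rank_sum_de(built["ranks"], built["samples"],
                           {"cell_type": "type0"}, {"platform": "platform0"})

    def test_empty_group_rejected(self, built):
        with pytest.raises(ValidationError, match="empty group"):
            ra.rank_sum_de(built["ranks"], built["samples"],
                           {"cell_type": "type0"}, {"cell_type": "no_such"})

    def test_string_filter_syntax(self, built):
        ids = ra.select_samples(built["samples"],
                                "cell_type=type0,sample_source=in vivo")
        ann = built["samples"].data.loc[ids]
        assert (ann["cell_type"] == "type0").all()
        assert (ann["sample_source"] == "in vivo").all()
        assert len(ids) > 0

    def test_platform_fraction_carried(self, built):
        sub = ra.ExpressionMatrix(built["ranks"].values.iloc[:10], "rank")
        de = ra.rank_sum_de(sub, built["samples"], {"cell_type": "type0"},
                            {"cell_type": "type1"}, gene_stats=built["stats"])
        assert "platform_fraction" in de.columns
        assert de["platform_fraction"].notna().all()
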