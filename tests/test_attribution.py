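"""Attribution correctness against closed forms and Shapley oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import glycopred as gp
from glycopred.attribution import (
    _forward_ops,
    _multipliers,
    model_ops,
    percentile_table,
)


def _linear_ops(w, b):
    return [("affine", np.asarray(w, dtype=float).reshape(-1, 1), np.asarray([b], dtype=float))]


class TestDeepAttribution:
    def test_linear_model_closed_form(self):
        w = np.array([2.0, -1.0, 0.5])
        ops = _linear_ops(w, 0.3)
        X = np.array([[1.0, 2.0, 3.0], [0.0, -1.0, 4.0]])
        r = np.array([0.5, 0.5, 0.5])
        m = _multipliers(ops, X, r)
        phi = m * (X - r)
        assert np.allclose(phi, w * (X - r))
        out = _forward_ops(ops, X)[-1][:, 0]
        assert np.allclose(phi.sum(axis=1), out - (w @ r + 0.3))

    def test_explaining_the_reference_itself_gives_zero(self, tiny_net):
        model = tiny_net(seed=0)
        x = np.random.default_rng(1).normal(size=(1, 8))
        attr = gp.deep_attribution(model, x, x)
        assert np.allclose(attr.phi, 0.0)

    def test_local_accuracy_on_trained_model(self, small_model, small_labeled):
        model, _ = small_model
        X = small_labeled.features
        attr = gp.deep_attribution(model, X[:60], X[60:100])
        pred = model.predict_proba(X[:60])
        gap = np.abs(attr.phi.sum(axis=1) - (pred - attr.base_value))
        assert gap.max() <= 1e-4

    def test_zero_weight_gene_receives_zero_attribution(self, tiny_net):
        model = tiny_net(seed=3, input_dim=6)
        model.W[0][2, :] = 0.0  # model ignores feature 2
        rng = np.random.default_rng(4)
        attr = gp.deep_attribution(model, rng.normal(size=(10, 6)), rng.normal(size=(4, 6)))
        assert np.all(attr.phi[:, 2] == 0.0)

    def test_agrees_with_exact_shapley_on_small_networks(self, tiny_net):
        """Deep attribution vs exhaustive Shapley enumeration on 8-input nets."""
        rng = np.random.default_rng(5)
        model = tiny_net(seed=11)
        X = rng.normal(size=(20, 8))
        B = rng.normal(size=(6, 8))
        attr = gp.deep_attribution(model, X, B)
        rs = []
        for i in range(20):
            oracle = gp.exact_shapley(model.predict_proba, X[i], B)
            rs.append(stats.pearsonr(attr.phi[i], oracle).statistic)
        assert np.mean(rs) >= 0.95

    def test_dimension_mismatch_raises(self, tiny_net):
        model = tiny_net(seed=0)
        with pytest.raises(ValueError):
            gp.deep_attribution(model, np.zeros((2, 8)), np.zeros((2, 5)))


class TestSamplingShapley:
    def test_linear_model_converges_to_closed_form(self):
        w = np.array([1.5, -2.0, 0.7, 0.0])

        def f(X):
            return X @ w

        rng = np.random.default_rng(6)
        x = rng.normal(size=4)
        B = rng.normal(size=(8, 4))
        phi, se = gp.sampling_shapley(f, x, B, n_draws=600, seed=1, return_se=True)
        expected = w * (x - B.mean(axis=0))
        assert np.all(np.abs(phi - expected) <= 3 * se + 1e-12)

    def test_symmetric_features_get_equal_attribution(self):
        def f(X):
            return X[:, 0] + X[:, 1]

        x = np.array([2.0, 2.0])
        B = np.zeros((1, 2))
        phi = gp.sampling_shapley(f, x, B, n_draws=50, seed=2)
        assert phi[0] == pytest.approx(phi[1])

    def test_matches_exact_enumeration(self, tiny_net):
        model = tiny_net(seed=21, input_dim=6)
        rng = np.random.default_rng(7)
        x = rng.normal(size=6)
        B = rng.normal(size=(5, 6))
        exact = gp.exact_shapley(model.predict_proba, x, B)
        phi, se = gp.sampling_shapley(model.predict_proba, x, B, n_draws=800, seed=3,
                                      return_se=True)
        assert np.all(np.abs(phi - exact) <= 3 * se + 1e-12)
        # exact values satisfy the efficiency axiom
        base = model.predict_proba(B).mean()
        assert exact.sum() == pytest.approx(model.predict_proba(x[None, :])[0] - base, abs=1e-10)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            gp.sampling_shapley(lambda X: X[:, 0], np.zeros(2), np.zeros((0, 2)), n_draws=5)


class TestEnsembleAverage:
    def _attr(self, phi, base=0.5):
        n, d = phi.shape
        return gp.AttributionMatrix(
            phi=phi, base_value=base,
            explain_cell_ids=[f"c{i}" for i in range(n)],
            background_cell_ids=["b0"],
            gene_ids=[f"g{j}" for j in range(d)],
        )

    def test_idempotent_on_identical_matrices(self):
        phi = np.arange(6.0).reshape(2, 3)
        out = gp.ensemble_average([self._attr(phi)] * 3)
        assert np.array_equal(out.phi, phi)

    def test_cancellation(self):
        phi = np.arange(6.0).reshape(2, 3)
        out = gp.ensemble_average([self._attr(phi), self._attr(-phi), self._attr(phi * 0)])
        assert np.allclose(out.phi, 0.0)

    def test_averaged_matrix_keeps_local_accuracy_for_the_mean_model(self, tiny_net, small_labeled):
        X = small_labeled.features[:10, :8]
        B = small_labeled.features[10:16, :8]
        models = [tiny_net(seed=s) for s in (31, 32, 33)]
        attrs = [gp.deep_attribution(m, X, B) for m in models]
        avg = gp.ensemble_average(attrs)
        mean_pred = np.mean([m.predict_proba(X) for m in models], axis=0)
        assert np.allclose(avg.phi.sum(axis=1), mean_pred - avg.base_value, atol=1e-10)

    def test_mismatched_cells_rejected(self):
        a = self._attr(np.zeros((2, 3)))
        b = self._attr(np.zeros((2, 3)))
        b.explain_cell_ids = ["x0", "x1"]
        with pytest.raises(ValueError):
            gp.ensemble_average([a, b])


class TestRanking:
    def _attr_from_phi(self, phi, gene_ids):
        n = phi.shape[0]
        return gp.AttributionMatrix(
            phi=phi, base_value=0.5,
            explain_cell_ids=[f"c{i}" for i in range(n)],
            background_cell_ids=["b"], gene_ids=gene_ids,
        )

    def test_sorting_and_percentiles(self):
        phi = np.tile([[0.5, -0.2, 0.9]], (5, 1))
        ranking = gp.rank_genes(self._attr_from_phi(phi, ["a", "b", "c"]))
        assert ranking["gene_id"].tolist() == ["c", "a", "b"]
        assert ranking["rank"].tolist() == [1, 2, 3]

    def test_null_gene_ranked_last_by_id_order(self):
        phi = np.zeros((4, 3))
        phi[:, 1] = 0.3
        ranking = gp.rank_genes(self._attr_from_phi(phi, ["g2", "g1", "g0"]))
        assert ranking["gene_id"].tolist() == ["g1", "g0", "g2"]  # zeros tie-broken by id

    def test_percentile_formula(self):
        phi = np.random.default_rng(8).normal(size=(3, 400))
        ranking = gp.rank_genes(self._attr_from_phi(phi, [f"g{i:03d}" for i in range(400)]))
        assert ranking.loc[ranking["rank"] == 4, "percentile"].item() == pytest.approx(1.0)

    @pytest.mark.parametrize("n,frac,expected", [(5160, 0.10, 516), (2050, 0.10, 205)])
    def test_top_fraction_counts(self, n, frac, expected):
        ranking = pd.DataFrame(
            {"gene_id": [f"g{i:04d}" for i in range(n)],
             "median_abs_shap": np.linspace(1, 0, n)}
        )
        assert len(gp.top_fraction(ranking, frac)) == expected

    def test_top_fraction_full_and_invalid(self):
        ranking = pd.DataFrame({"gene_id": list("abcde"), "median_abs_shap": range(5)})
        assert gp.top_fraction(ranking, 1.0) == list("abcde")
        with pytest.raises(ValueError):
            gp.top_fraction(ranking, 0.0)


class TestSubtypeRankings:
    def test_small_subtype_uses_all_cells_and_identical_cells_rank_identically(self, tiny_net):
        model = tiny_net(seed=41)
        rng = np.random.default_rng(9)
        base = rng.normal(size=(1, 8))
        X = np.vstack([np.tile(base, (40, 1)), np.tile(base, (40, 1))])
        labels = ["A"] * 40 + ["B"] * 40
        out = gp.subtype_rankings(
            [model], [rng.normal(size=(5, 8))], X,
            [f"c{i}" for i in range(80)], labels,
            [f"g{j}" for j in range(8)], cap=1000, seed=0,
        )
        pd.testing.assert_frame_equal(out["A"], out["B"])

    def test_cap_one_uses_a_single_cell(self, tiny_net):
        model = tiny_net(seed=42)
        rng = np.random.default_rng(10)
        X = rng.normal(size=(30, 8))
        out = gp.subtype_rankings(
            [model], [rng.normal(size=(4, 8))], X,
            [f"c{i}" for i in range(30)], ["A"] * 30,
            [f"g{j}" for j in range(8)], cap=1, seed=1,
        )
        assert len(out["A"]) == 8  # a ranking over all genes from one cell


class TestSpecificity:
    def _table(self, rows: dict[str, list[float]], subtypes: list[str]) -> pd.DataFrame:
        return pd.DataFrame.from_dict(rows, orient="index", columns=subtypes)

    def test_constant_row_is_specific_nowhere(self):
        table = self._table({"g": [1.0, 1.0, 1.0, 1.0]}, list("ABCD"))
        assert gp.specific_genes(table) == []

    def test_worked_example(self):
        table = self._table({"g": [0.5, 40.0, 50.0, 60.0]}, list("ABCD"))
        out = gp.specific_genes(table)
        assert len(out) == 1 and out[0].specific_in == ("A",)

    def test_top_everywhere_is_shared_not_specific(self):
        table = self._table({"g": [1.0, 1.0, 1.0, 1.0, 1.0]}, list("ABCDE"))
        assert gp.specific_genes(table) == []

    def test_single_subtype_rejected(self):
        with pytest.raises(ValueError):
            gp.specific_genes(self._table({"g": [1.0]}, ["A"]))

    def test_percentile_table_shape(self, tiny_net):
        model = tiny_net(seed=51)
        rng = np.random.default_rng(11)
        X = rng.normal(size=(40, 8))
        labels = ["A"] * 20 + ["B"] * 20
        ranks = gp.subtype_rankings(
            [model], [rng.normal(size=(4, 8))], X,
            [f"c{i}" for i in range(40)], labels,
            [f"g{j}" for j in range(8)], cap=10, seed=2,
        )
        table = percentile_table(ranks)
        assert table.shape == (8, 2)
        assert set(table.columns) == {"A", "B"}
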