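"""Permutation importance exactness, rank-sum DE against enumeration, BH."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import glycopred as gp


class TestPermutationImportance:
    def test_zero_weight_gene_has_exactly_zero_importance(self, tiny_net):
        model = tiny_net(seed=61, input_dim=6)
        model.W[0][4, :] = 0.0
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 6))
        y = rng.integers(0, 2, 40)
        out = gp.permutation_importance(model, X, y, [f"g{i}" for i in range(6)],
                                        n_permutations=5, seed=1)
        assert out.loc[out["gene_id"] == "g4", "importance"].item() == 0.0

    def test_constant_column_has_exactly_zero_importance(self, tiny_net):
        model = tiny_net(seed=62, input_dim=6)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 6))
        X[:, 2] = 1.7
        y = rng.integers(0, 2, 30)
        out = gp.permutation_importance(model, X, y, [f"g{i}" for i in range(6)],
                                        n_permutations=5, seed=2)
        assert out.loc[out["gene_id"] == "g2", "importance"].item() == 0.0

    def test_fast_path_matches_full_forward(self, tiny_net):
        """Scoring from the shifted first-layer pre-activation must equal a
        plain forward pass on the permuted matrix."""
        model = tiny_net(seed=63, input_dim=6)
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 6))
        perm = rng.permutation(25)
        Xp = X.copy()
        Xp[:, 3] = X[perm, 3]
        z1 = model.first_layer_preactivation(X)
        delta = Xp[:, 3] - X[:, 3]
        fast = model.predict_proba_from_z1(z1 + delta[:, None] * model.W[0][3][None, :])
        assert np.allclose(fast, model.predict_proba(Xp), atol=1e-12)

    def test_row_reordering_invariance(self, tiny_net):
        model = tiny_net(seed=64, input_dim=5)
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 5))
        y = rng.integers(0, 2, 30)
        a = gp.permutation_importance(model, X, y, list("abcde"), n_permutations=25, seed=5)
        order = rng.permutation(30)
        b = gp.permutation_importance(model, X[order], y[order], list("abcde"),
                                      n_permutations=25, seed=5)
        # same distribution of permuted columns; importances agree closely
        merged = a.merge(b, on="gene_id", suffixes=("_a", "_b"))
        assert np.allclose(merged["importance_a"], merged["importance_b"], atol=0.02)

    def test_invalid_permutation_count(self, tiny_net):
        model = tiny_net(seed=65, input_dim=4)
        with pytest.raises(ValueError):
            gp.permutation_importance(model, np.zeros((4, 4)), np.zeros(4),
                                      list("abcd"), n_permutations=0)


def _exact_ranksum_p(a, b):
    """Two-sided rank-sum p by full enumeration of label assignments."""
    pooled = np.concatenate([a, b])
    n = len(a)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    observed = ranks[:n].sum()
    stats_all = [
        sum(ranks[list(comb)]) for comb in itertools.combinations(range(len(pooled)), n)
    ]
    mean = np.mean(stats_all)
    extreme = sum(abs(s - mean) >= abs(observed - mean) - 1e-12 for s in stats_all)
    return extreme / len(stats_all)


class TestWilcoxonDE:
    def _run(self, a, b, **kw):
        X = np.concatenate([a, b])[:, None]
        y = np.array([1] * len(a) + [0] * len(b))
        # expression values enter on the log scale; use directly
        return gp.wilcoxon_de(X, y, ["g"], logfc_threshold=0.0, **kw)

    def test_three_vs_three_complete_separation(self):
        out = self._run(np.array([4.0, 5.0, 6.0]), np.array([1.0, 2.0, 3.0]))
        assert out["p_value"].item() == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize("n1,n2", [(3, 4), (5, 5), (4, 8), (8, 8)])
    def test_matches_exact_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        a = rng.normal(size=n1)
        b = rng.normal(0.8, size=n2)
        out = self._run(a, b)
        assert out["p_value"].item() == pytest.approx(_exact_ranksum_p(a, b), abs=1e-10)

    def test_fold_change_pre_filter(self):
        rng = np.random.default_rng(9)
        X = rng.normal(2.0, 0.01, size=(40, 2))
        X[:20, 1] += 1.0  # only gene 1 changes between groups
        y = np.array([1] * 20 + [0] * 20)
        out = gp.wilcoxon_de(X, y, ["same", "shifted"], logfc_threshold=0.25)
        assert np.isnan(out.loc[out["gene_id"] == "same", "p_value"].item())
        assert not out.loc[out["gene_id"] == "same", "significant"].item()
        assert out.loc[out["gene_id"] == "shifted", "significant"].item()

    def test_label_swap_flips_fold_change_keeps_p(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(30, 4))
        y = rng.integers(0, 2, 30)
        while y.sum() in (0, 30):
            y = rng.integers(0, 2, 30)
        a = gp.wilcoxon_de(X, y, list("abcd"), logfc_threshold=0.0)
        b = gp.wilcoxon_de(X, 1 - y, list("abcd"), logfc_threshold=0.0)
        assert np.allclose(a["log2_fold_change"], -b["log2_fold_change"])
        assert np.allclose(a["p_value"], b["p_value"])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            gp.wilcoxon_de(np.zeros((3, 2)), np.ones(3), ["a", "b"])

    def test_significance_requires_both_conditions(self, small_labeled):
        ds = small_labeled
        out = gp.wilcoxon_de(ds.features, ds.labels, ds.gene_ids)
        sig = out["significant"]
        assert (out.loc[sig, "adjusted_p"] < 0.05).all()
        assert (out.loc[sig, "log2_fold_change"].abs() >= 0.25).all()
        assert (out["adjusted_p"].dropna() >= out["p_value"].dropna()).all()


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert gp.bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_worked_step_up_case(self):
        out = gp.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_capped(self):
        assert np.allclose(gp.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gp.bh_adjust([0.1, 1.2])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_monotone_on_sorted_input(self, ps):
        out = gp.bh_adjust(sorted(ps))
        assert np.all(np.diff(out) >= -1e-12)


def test_low_abundance_drivers_reported_against_dea():
    """With low-abundance drivers planted, the pipeline reports which drivers
    the attribution ranking surfaces that differential expression misses."""
    from glycopred.pipeline import PipelineConfig, run_pipeline

    cfg = PipelineConfig(
        synthetic=gp.SyntheticConfig(
            n_cells=500, n_genes=120, n_drivers_pos=10, n_drivers_neg=2,
            low_abundance_drivers=True, seed=21,
        ),
        max_epochs=60, n_explain=120, n_background=25, subtype_cap=40,
        pfi_permutations=5, seed=21,
    )
    run = run_pipeline(cfg)
    rec = run.report["recovery"]
    assert "n_drivers_attribution_only" in rec
    assert set(rec["drivers_in_top_set_not_dea_significant"]) <= set(run.truth.driver_ids)
    dea_sig = set(run.dea.loc[run.dea["significant"], "gene_id"])
    for g in rec["drivers_in_top_set_not_dea_significant"]:
        assert g in run.shap_genes and g not in dea_sig


class TestOverlap:
    def test_reported_fraction_convention(self):
        a = {f"g{i}" for i in range(516)}
        b = {f"g{i}" for i in range(198)} | {f"x{i}" for i in range(319)}
        rep = gp.overlap_stats(a, b)
        assert rep.shared == 198
        assert rep.fraction_shared == pytest.approx(100 * 198 / 517)

    def test_identical_and_disjoint_sets(self):
        s = {"a", "b", "c"}
        same = gp.overlap_stats(s, s)
        assert same.fraction_shared == 100.0 and same.jaccard == 1.0
        disjoint = gp.overlap_stats(s, {"x", "y"})
        assert disjoint.fraction_shared == 0.0 and disjoint.jaccard == 0.0

    def test_empty_sets_define_zero_fractions(self):
        rep = gp.overlap_stats(set(), set())
        assert rep.fraction_shared == 0.0 and rep.jaccard == 0.0
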