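"""Soft thresholding, TOM, module detection, eigengenes and module prognosis."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from immunoscape import (GeneratorConfig, generate_cohort,
                         preprocess_expression)
from immunoscape.coexpression import (CoexpressionParams, adjacency_matrix,
                                      detect_modules, module_eigengenes,
                                      module_prognosis, scale_free_fit_index,
                                      soft_threshold_scan, tom_matrix)
from immunoscape.io_core import ExpressionMatrix
from immunoscape.survival_stats import median_split


@pytest.fixture(scope="module")
def block_bundle():
    """Two 40-gene blocks with within-block correlation ~0.8."""
    cfg = GeneratorConfig(
        n_samples=200, n_genes=200, n_subtypes=2, delta=0.0,
        module_sizes=(40, 40), module_loading=2.0, module_subtype_effect=0.0,
        log_hazard_by_subtype=(0.0, 0.0), tmb_mean_by_subtype=(30.0, 30.0),
        n_antigen_genes=0, include_favorable_gene=False,
        prognostic_module=0, module_log_hazard=0.5)
    return generate_cohort(cfg, 5)


@pytest.fixture(scope="module")
def block_expr(block_bundle):
    return preprocess_expression(block_bundle.expression)


class TestSoftThreshold:
    def test_power_law_connectivity_fits(self, rng):
        k = (1 - rng.random(5000)) ** (-1 / 1.5)   # Pareto, exponent 2.5
        fit, slope = scale_free_fit_index(k)
        assert fit >= 0.9
        assert slope < 0

    def test_discretized_power_law_fits(self, rng):
        k = np.round((1 - rng.random(5000)) ** (-1 / 1.5) * 10) / 10
        fit, _ = scale_free_fit_index(k)
        assert fit >= 0.9

    def test_beta_one_equals_abs_correlation(self, block_expr):
        a = adjacency_matrix(block_expr, beta=1)
        cor = np.abs(np.corrcoef(block_expr.values.to_numpy()))
        np.testing.assert_allclose(a.to_numpy(), cor, atol=1e-12)

    def test_fit_index_bounded_by_one(self, block_expr):
        scan = soft_threshold_scan(block_expr, powers=[1, 4, 8])
        assert (scan["scale_free_fit_r2"] <= 1.0).all()
        assert scan["mean_connectivity"].is_monotonic_decreasing

    def test_constant_gene_is_error(self, rng):
        vals = pd.DataFrame(rng.random((30, 12)),
                            index=[f"G{i}" for i in range(30)],
                            columns=[f"s{i}" for i in range(12)])
        vals.iloc[0] = 1.0
        m = ExpressionMatrix(values=vals, scale_tag="log2p1")
        with pytest.raises(ValueError, match="G0"):
            soft_threshold_scan(m)


class TestTom:
    def test_zero_adjacency_gives_zero_tom(self):
        a = np.eye(6)
        tom = tom_matrix(a)
        assert np.allclose(tom, np.eye(6))

    def test_complete_graph_gives_all_ones(self):
        m = 7
        a = np.ones((m, m))
        tom = tom_matrix(a)
        np.testing.assert_allclose(tom, np.ones((m, m)))

    def test_matches_triple_loop_oracle(self, rng):
        """Vectorized TOM equals the definition computed loop-by-loop."""
        for _ in range(3):
            m = 20
            a = rng.random((m, m))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            tom = tom_matrix(a)
            a0 = a.copy()
            np.fill_diagonal(a0, 0.0)
            k = a0.sum(axis=1)
            for i in range(m):
                for j in range(m):
                    if i == j:
                        assert tom[i, j] == 1.0
                        continue
                    l = sum(a0[i, u] * a0[u, j] for u in range(m)
                            if u != i and u != j)
                    expected = (l + a0[i, j]) / (min(k[i], k[j]) + 1 - a0[i, j])
                    assert tom[i, j] == pytest.approx(expected, abs=1e-12)

    def test_entries_in_unit_interval(self, rng):
        a = rng.random((15, 15))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = tom_matrix(a)
        assert tom.min() >= 0 and tom.max() <= 1

    def test_asymmetric_is_error(self, rng):
        a = rng.random((5, 5))
        with pytest.raises(ValueError, match="symmetric"):
            tom_matrix(a)


class TestDetectModules:
    def test_planted_blocks_recovered(self, block_bundle, block_expr):
        tom = tom_matrix(adjacency_matrix(block_expr, beta=4))
        labels = detect_modules(tom, block_expr.gene_ids)
        truth = pd.Series({g: block_bundle.truth.module_assignment[g]
                           for g in block_expr.gene_ids})
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_min_module_size_enforced(self, block_expr):
        tom = tom_matrix(adjacency_matrix(block_expr, beta=4))
        labels = detect_modules(tom, block_expr.gene_ids)
        sizes = labels[labels != "grey"].value_counts()
        assert (sizes >= 30).all()

    def test_small_block_goes_grey(self, rng):
        """A 10-gene block cannot form a module at min size 30."""
        n = 60
        f = rng.standard_normal(n)
        vals = 6.0 + np.vstack(
            [2.0 * f + rng.standard_normal(n) for _ in range(10)]
            + [rng.standard_normal(n) for _ in range(30)])
        vals = np.clip(vals, 0.0, None)
        m = ExpressionMatrix(
            values=pd.DataFrame(vals, index=[f"G{i}" for i in range(40)],
                                columns=[f"s{i}" for i in range(n)]),
            scale_tag="log2p1")
        tom = tom_matrix(adjacency_matrix(m, beta=4))
        labels = detect_modules(tom, m.gene_ids)
        assert (labels == "grey").all() or \
            (labels[:10] == "grey").all()


class TestEigengenes:
    def test_perfectly_correlated_module_all_hubs(self, rng):
        n = 50
        profile = rng.random(n) * 4
        vals = np.vstack([3 * profile + 5, 2 * profile + 1, profile])
        m = ExpressionMatrix(
            values=pd.DataFrame(vals, index=["G0", "G1", "G2"],
                                columns=[f"s{i}" for i in range(n)]),
            scale_tag="log2p1")
        labels = pd.Series(["M1"] * 3, index=m.values.index)
        mset = module_eigengenes(m, labels)
        np.testing.assert_allclose(mset.kme["M1"], 1.0, atol=1e-9)
        assert mset.hub_genes["M1"] == ["G0", "G1", "G2"]
        assert mset.variance_explained["M1"] == pytest.approx(1.0, abs=1e-9)

    def test_close_modules_merged(self, rng):
        n = 80
        f = rng.standard_normal(n)
        block_a = np.vstack([f + 0.1 * rng.standard_normal(n) for _ in range(5)])
        block_b = np.vstack([f + 0.1 * rng.standard_normal(n) for _ in range(5)])
        vals = np.clip(np.vstack([block_a, block_b]) + 6.0, 0.0, None)
        m = ExpressionMatrix(
            values=pd.DataFrame(vals, index=[f"G{i}" for i in range(10)],
                                columns=[f"s{i}" for i in range(n)]),
            scale_tag="log2p1")
        labels = pd.Series(["M1"] * 5 + ["M2"] * 5, index=m.values.index)
        mset = module_eigengenes(m, labels, merge_height=0.25)
        assert set(mset.assignment.unique()) == {"M1"}
        assert len(mset.merge_history) == 1

    def test_variance_explained_matches_svd_oracle(self, block_expr):
        tom = tom_matrix(adjacency_matrix(block_expr, beta=4))
        labels = detect_modules(tom, block_expr.gene_ids)
        mset = module_eigengenes(block_expr, labels)
        for mod in mset.eigengenes.columns:
            genes = mset.assignment.index[mset.assignment == mod]
            sub = block_expr.values.loc[genes].to_numpy()
            z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, keepdims=True)
            s = np.linalg.svd(z, compute_uv=False)
            assert mset.variance_explained[mod] == pytest.approx(
                s[0] ** 2 / (s**2).sum(), abs=1e-9)

    def test_eigengene_columns_unit_norm(self, block_expr):
        tom = tom_matrix(adjacency_matrix(block_expr, beta=4))
        labels = detect_modules(tom, block_expr.gene_ids)
        mset = module_eigengenes(block_expr, labels)
        norms = np.linalg.norm(mset.eigengenes.to_numpy(), axis=0)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)


class TestModulePrognosis:
    def test_planted_prognostic_module_detected(self, block_bundle, block_expr):
        tom = tom_matrix(adjacency_matrix(block_expr, beta=4))
        labels = detect_modules(tom, block_expr.gene_ids)
        mset = module_eigengenes(block_expr, labels)
        prog = module_prognosis(mset, block_expr, block_bundle.clinical)
        # the planted prognostic module (M planted index 0) carries hazard
        truth_mod = {g for g, m in block_bundle.truth.module_assignment.items()
                     if m == "M1"}
        best = None
        for mod in prog.index:
            genes = set(mset.assignment.index[mset.assignment == mod])
            if len(genes & truth_mod) / max(len(genes), 1) > 0.5:
                best = mod
        assert best is not None
        assert prog.loc[best, "logrank_p"] < 0.05

    def test_split_groups_are_median_split(self, block_bundle, block_expr):
        tom = tom_matrix(adjacency_matrix(block_expr, beta=4))
        labels = detect_modules(tom, block_expr.gene_ids)
        mset = module_eigengenes(block_expr, labels)
        mod = mset.eigengenes.columns[0]
        genes = mset.assignment.index[mset.assignment == mod]
        samples = [s for s in block_expr.sample_ids
                   if s in block_bundle.clinical.index]
        mean_score = block_expr.values.loc[genes, samples].mean(axis=0)
        grp = median_split(mean_score.to_numpy())
        assert set(np.unique(grp)) == {"high", "low"}
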