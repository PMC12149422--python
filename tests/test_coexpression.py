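"""Coexpression network construction, module detection and enrichment."""

import warnings

import numpy as np
import pandas as pd
import pytest

from habitatomics.coexpression import (
    adjacency_matrix,
    detect_modules,
    hub_genes,
    hypergeom_enrichment,
    module_eigengene,
    module_trait,
    pick_soft_threshold,
    tom_matrix,
)
from habitatomics.synthetic import CohortSpec, generate_expression
from oracles import hypergeom_upper_tail, pearson_p_bruteforce, tom_bruteforce


def _planted_expression(seed=0, n_samples=100, trait_cor=-0.5):
    rng = np.random.default_rng(seed)
    spec = CohortSpec(
        n_patients=n_samples, n_genes=500, module_sizes=(150, 120, 100),
        module_trait_cor=trait_cor, seed=seed,
    )
    score = rng.normal(size=n_samples)
    expr, truth = generate_expression(spec, score, rng)
    return expr, truth, score


class TestSoftThreshold:
    def test_orthogonal_genes_fall_back_without_error(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(40, 60)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            beta, r2s = pick_soft_threshold(expr, betas=range(1, 6))
        assert beta in r2s

    def test_adjacency_monotone_in_beta(self):
        expr, _, _ = _planted_expression()
        a2 = adjacency_matrix(expr, 2).to_numpy()
        a5 = adjacency_matrix(expr, 5).to_numpy()
        assert (a5 <= a2 + 1e-12).all()

    def test_planted_structure_gets_workable_beta(self):
        expr, _, _ = _planted_expression(seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            beta, r2s = pick_soft_threshold(expr)
        assert 1 <= beta <= 20

    def test_constant_gene_rejected(self):
        expr = pd.DataFrame(np.zeros((5, 30)))
        with pytest.raises(ValueError):
            pick_soft_threshold(expr)


class TestTOM:
    def test_exclusive_pair_full_overlap(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 1.0
        tom = tom_matrix(a)
        assert tom[0, 1] == pytest.approx(1.0)

    def test_uniform_half_adjacency(self):
        a = np.full((4, 4), 0.5)
        np.fill_diagonal(a, 0.0)
        tom = tom_matrix(a)
        off = tom[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 0.5, atol=1e-12)

    def test_zero_adjacency_gives_identity(self):
        tom = tom_matrix(np.zeros((5, 5)))
        np.testing.assert_allclose(tom, np.eye(5))

    def test_matches_triple_sum_oracle_on_random_graphs(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            a = rng.uniform(0, 1, (5, 5))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            np.testing.assert_allclose(tom_matrix(a), tom_bruteforce(a), atol=1e-12)

    def test_range_and_symmetry(self):
        expr, _, _ = _planted_expression(seed=3)
        adj = adjacency_matrix(expr.iloc[:80], 6).to_numpy()
        tom = tom_matrix(adj)
        assert tom.min() >= 0.0 and tom.max() <= 1.0 + 1e-12
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)

    def test_asymmetric_input_rejected(self):
        a = np.zeros((3, 3))
        a[0, 1] = 0.5
        with pytest.raises(ValueError):
            tom_matrix(a)


class TestDetectModules:
    def test_duplicate_genes_cluster_together(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(2, 50))
        expr = pd.DataFrame(
            np.vstack([np.tile(base[0], (110, 1)) + 1e-6 * rng.normal(size=(110, 50)),
                       np.tile(base[1], (110, 1)) + 1e-6 * rng.normal(size=(110, 50))]),
            index=[f"G{i}" for i in range(220)],
        )
        adj = adjacency_matrix(expr, 6)
        tom = tom_matrix(adj.to_numpy())
        mods = detect_modules(1 - tom, expr.index, min_module_size=100, expr=expr)
        assert mods.iloc[:110].nunique() == 1
        assert mods.iloc[110:].nunique() == 1
        assert mods.iloc[0] != mods.iloc[-1]

    def test_gene_order_permutation_preserves_partition(self):
        from sklearn.metrics import adjusted_rand_score

        expr, _, _ = _planted_expression(seed=5)
        adj = adjacency_matrix(expr, 6).to_numpy()
        tom = tom_matrix(adj)
        mods = detect_modules(1 - tom, expr.index, 100, expr=expr)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(expr))
        expr_p = expr.iloc[perm]
        tom_p = tom[np.ix_(perm, perm)]
        mods_p = detect_modules(1 - tom_p, expr_p.index, 100, expr=expr_p)
        aligned = mods_p.loc[mods.index]
        assert adjusted_rand_score(mods.to_numpy(), aligned.to_numpy()) == 1.0

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            detect_modules(np.zeros((50, 50)), [f"G{i}" for i in range(50)], 100)


class TestModuleTrait:
    def test_planted_trait_module_selected(self):
        expr, truth, score = _planted_expression(seed=6)
        adj = adjacency_matrix(expr, 6).to_numpy()
        mods = detect_modules(1 - tom_matrix(adj), expr.index, 100, expr=expr)
        traits = pd.DataFrame({"radscore": score}, index=expr.columns)
        eig, mt, selected = module_trait(mods, expr, traits)
        planted = mods[truth == "module_1"].mode()[0]
        assert selected == planted
        r = mt.loc[mt["module"] == selected, "r"].iloc[0]
        assert abs(r - (-0.5)) < 0.15

    def test_uncorrelated_trait_not_significant(self):
        expr, truth, score = _planted_expression(seed=7, trait_cor=0.0)
        adj = adjacency_matrix(expr, 6).to_numpy()
        mods = detect_modules(1 - tom_matrix(adj), expr.index, 100, expr=expr)
        rng = np.random.default_rng(8)
        traits = pd.DataFrame({"radscore": rng.normal(size=expr.shape[1])},
                              index=expr.columns)
        _, mt, _ = module_trait(mods, expr, traits)
        assert mt["p"].min() > 0.001

    def test_eigengene_sign_flip_invariance(self):
        expr, truth, score = _planted_expression(seed=9)
        sub = expr.loc[truth == "module_2"]
        e = module_eigengene(sub)
        member_cor = np.mean([np.corrcoef(sub.loc[g], e)[0, 1] for g in sub.index[:20]])
        assert member_cor > 0  # orientation convention
        r1 = abs(np.corrcoef(e, score)[0, 1])
        r2 = abs(np.corrcoef(-e, score)[0, 1])
        assert r1 == pytest.approx(r2)

    def test_p_values_match_t_closed_form(self):
        expr, truth, score = _planted_expression(seed=10)
        adj = adjacency_matrix(expr, 6).to_numpy()
        mods = detect_modules(1 - tom_matrix(adj), expr.index, 100, expr=expr)
        traits = pd.DataFrame({"radscore": score}, index=expr.columns)
        _, mt, _ = module_trait(mods, expr, traits)
        for _, row in mt.iterrows():
            assert row["p"] == pytest.approx(
                pearson_p_bruteforce(row["r"], expr.shape[1]), abs=1e-10
            )

    def test_misaligned_samples_rejected(self):
        expr, _, score = _planted_expression(seed=11)
        traits = pd.DataFrame(
            {"radscore": score}, index=[f"Z{i}" for i in range(len(score))]
        )
        mods = pd.Series("turquoise", index=expr.index)
        with pytest.raises(ValueError):
            module_trait(mods, expr, traits)


class TestHubGenes:
    def test_star_graph_center_first(self):
        edges = pd.DataFrame(
            {"gene_a": ["hub"] * 4, "gene_b": ["a", "b", "c", "d"]}
        )
        top = hub_genes(["hub", "a", "b", "c", "d"], edge_list=edges)
        assert top[0] == "hub"

    def test_degree_ranking(self):
        edges = pd.DataFrame(
            {
                "gene_a": ["g1", "g1", "g1", "g1", "g2", "g2", "g3"],
                "gene_b": ["g2", "g3", "g4", "g5", "g3", "g4", "g5"],
            }
        )
        top = hub_genes(["g1", "g2", "g3", "g4", "g5"], edge_list=edges)
        assert top == ["g1", "g2"]  # degrees 4 and 3

    def test_isolated_gene_changes_nothing(self):
        edges = pd.DataFrame({"gene_a": ["a", "a"], "gene_b": ["b", "c"]})
        t1 = hub_genes(["a", "b", "c"], edge_list=edges)
        t2 = hub_genes(["a", "b", "c", "zzz"], edge_list=edges)
        assert t1 == t2

    def test_edge_list_outside_module_falls_back_to_adjacency(self):
        adj = pd.DataFrame(
            [[0.0, 0.9, 0.1], [0.9, 0.0, 0.2], [0.1, 0.2, 0.0]],
            index=["a", "b", "c"], columns=["a", "b", "c"],
        )
        edges = pd.DataFrame({"gene_a": ["x"], "gene_b": ["y"]})
        with pytest.warns(UserWarning):
            top = hub_genes(["a", "b", "c"], adjacency=adj, edge_list=edges)
        assert top == ["b", "a"]


class TestEnrichment:
    def _annotation(self):
        rows = []
        for t in range(5):
            for g in range(20):
                rows.append(
                    {"term_id": f"T{t}", "term_name": f"term {t}",
                     "gene": f"G{t * 20 + g:03d}"}
                )
        return pd.DataFrame(rows)

    def test_exact_term_ranks_first(self):
        ann = self._annotation()
        universe = [f"G{i:03d}" for i in range(200)]
        module = [f"G{i:03d}" for i in range(20)]  # exactly term T0
        table, report = hypergeom_enrichment(module, ann, universe)
        assert table.iloc[0]["term_id"] == "T0"
        assert report.iloc[0]["overlap"] == 20

    def test_p_equals_tail_sum(self):
        ann = pd.DataFrame(
            {"term_id": ["T"] * 20, "term_name": ["t"] * 20,
             "gene": [f"G{i:03d}" for i in range(20)]}
        )
        universe = [f"G{i:03d}" for i in range(100)]
        module = [f"G{i:03d}" for i in (0, 1, 2, 50, 51, 52, 53, 54, 55, 56)]
        table, _ = hypergeom_enrichment(module, ann, universe)
        p = table.iloc[0]["p"]
        assert table.iloc[0]["overlap"] == 3
        assert p == pytest.approx(hypergeom_upper_tail(3, 100, 20, 10), abs=1e-12)

    def test_random_modules_rarely_pass_fdr(self):
        ann = self._annotation()
        universe = [f"G{i:03d}" for i in range(200)]
        rng = np.random.default_rng(12)
        calm = 0
        for _ in range(50):
            module = list(rng.choice(universe, size=15, replace=False))
            table, _ = hypergeom_enrichment(module, ann, universe)
            calm += table["fdr_bh"].min() >= 0.05
        assert calm >= 30  # most replicates show no significant enrichment

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(["a"], pd.DataFrame(), ["a"])
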