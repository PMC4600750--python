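"""Expressed-gene filter, GP dosage compensation, graph conditioning."""

import numpy as np
import pandas as pd
import pytest

from xshadow.errors import MixtureUnfitError, SampleSizeError
from xshadow.io import ExpressionMatrix, InfluenceGraph, MutationTable
from xshadow.preprocess import (
    combine_cohort_tests,
    compensate_cnv_cis,
    condition_influence_graph,
    detect_expressed_genes,
)


def _expr_from_columns(cols: dict, patients=None):
    n = len(next(iter(cols.values())))
    patients = patients or [f"P{i}" for i in range(n)]
    return ExpressionMatrix(pd.DataFrame(cols, index=patients))


class TestExpressedGenes:
    def _two_group_matrix(self, seed=0, n_each=500, n_pat=40):
        rng = np.random.default_rng(seed)
        low = rng.normal(2.0, 0.5, size=n_each)
        high = rng.normal(10.0, 0.5, size=n_each)
        cols = {}
        for i, centre in enumerate(np.concatenate([low, high])):
            cols[f"g{i}"] = rng.normal(centre, 0.3, size=n_pat)
        return _expr_from_columns(cols)

    def test_two_clear_groups_are_partitioned(self):
        expr = self._two_group_matrix()
        calls = detect_expressed_genes(expr)
        truth = np.array([False] * 500 + [True] * 500)
        agreement = (calls["is_expressed"].to_numpy() == truth).mean()
        assert agreement >= 0.99

    def test_high_outlier_gets_posterior_one(self):
        expr = self._two_group_matrix(seed=1)
        frame = expr.frame.copy()
        frame["blowup"] = 50.0 + np.random.default_rng(2).normal(0, 0.1, len(frame))
        calls = detect_expressed_genes(ExpressionMatrix(frame))
        assert calls.loc["blowup", "outlier_flag"] == "high"
        assert calls.loc["blowup", "posterior_high"] == 1.0
        assert bool(calls.loc["blowup", "is_expressed"])

    def test_identical_percentiles_raise(self):
        cols = {f"g{i}": np.full(20, 5.0) for i in range(60)}
        with pytest.raises(MixtureUnfitError):
            detect_expressed_genes(_expr_from_columns(cols))

    def test_too_few_genes_raise(self):
        rng = np.random.default_rng(0)
        cols = {f"g{i}": rng.normal(size=20) for i in range(10)}
        with pytest.raises(MixtureUnfitError):
            detect_expressed_genes(_expr_from_columns(cols))

    def test_unimodal_percentiles_leave_filter_inert(self):
        rng = np.random.default_rng(3)
        cols = {f"g{i}": rng.normal(8.0, 1.0, size=30) for i in range(200)}
        calls = detect_expressed_genes(_expr_from_columns(cols))
        assert calls.loc[calls["outlier_flag"] == "none", "is_expressed"].all()


class TestGPCompensation:
    def test_linear_dosage_effect_is_removed(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        y = 2.0 * x + rng.normal(0, 0.1, size=200)
        res, gp = compensate_cnv_cis(y, x)
        assert gp is not None
        assert abs(np.corrcoef(res, x)[0, 1]) < 0.1
        assert abs(res.mean()) < 0.05

    def test_independent_expression_keeps_its_variance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        res, _ = compensate_cnv_cis(y, x)
        assert np.var(res) == pytest.approx(np.var(y), rel=0.10)

    def test_constant_copy_number_returns_centred_expression(self):
        y = np.arange(20.0)
        res, gp = compensate_cnv_cis(y, np.full(20, 1.0))
        assert gp is None
        np.testing.assert_allclose(res, y - y.mean(), atol=1e-12)

    def test_residuals_invariant_to_patient_order(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=60)
        y = 1.5 * x + rng.normal(0, 0.2, size=60)
        res1, _ = compensate_cnv_cis(y, x)
        perm = rng.permutation(60)
        res2, _ = compensate_cnv_cis(y[perm], x[perm])
        np.testing.assert_allclose(res1[perm], res2, atol=1e-8)

    def test_too_few_observations_rejected(self):
        with pytest.raises(SampleSizeError):
            compensate_cnv_cis(np.ones(5), np.arange(5.0))


class TestGraphConditioning:
    def _setup(self, shift_neighbours=5, n_neigh=20, n_mut=30, n_tot=100, seed=0, floor_edge=False):
        rng = np.random.default_rng(seed)
        patients = [f"P{i}" for i in range(n_tot)]
        mut_pats = patients[:n_mut]
        cols = {}
        for j in range(n_neigh):
            base = rng.normal(8.0, 1.0, size=n_tot)
            if j < shift_neighbours:
                base[:n_mut] += 2.0  # 2 SD shift in mutated patients
            cols[f"n{j}"] = base
        cols["driver"] = rng.normal(8.0, 1.0, size=n_tot)
        expr = _expr_from_columns(cols, patients)
        edges = [("driver", f"n{j}", 0.8) for j in range(n_neigh)]
        if floor_edge:
            edges.append(("driver", "weak", 0.3))
            cols["weak"] = rng.normal(size=n_tot)
        graph = InfluenceGraph(edges)
        mut = MutationTable(
            pd.DataFrame(
                {
                    "patient": mut_pats,
                    "gene": ["driver"] * n_mut,
                    "mut_class": ["missense"] * n_mut,
                    "position": [np.nan] * n_mut,
                }
            )
        )
        return graph, expr, mut

    def test_differentially_expressed_neighbours_promoted_to_weight_one(self):
        graph, expr, mut = self._setup()
        lists = condition_influence_graph(graph, expr, mut)
        kept = lists["driver"]
        assert set(kept["neighbour"]) == {f"n{j}" for j in range(5)}
        assert (kept["weight"] == 1.0).all()

    def test_no_signal_keeps_the_original_weighted_list(self):
        graph, expr, mut = self._setup(shift_neighbours=0)
        lists = condition_influence_graph(graph, expr, mut)
        kept = lists["driver"]
        assert len(kept) == 20
        assert (kept["weight"] == 0.8).all()

    def test_low_confidence_edges_are_dropped_first(self):
        graph, expr, mut = self._setup(shift_neighbours=0, floor_edge=True)
        lists = condition_influence_graph(graph, expr, mut)
        assert "weak" not in set(lists["driver"]["neighbour"])

    def test_few_mutated_patients_skip_the_test(self):
        graph, expr, mut = self._setup(shift_neighbours=5, n_mut=2)
        lists = condition_influence_graph(graph, expr, mut)
        assert (lists["driver"]["weight"] == 0.8).all()

    def test_mutated_gene_absent_from_graph_gets_empty_list(self):
        graph, expr, mut = self._setup()
        df = mut.records.copy()
        df["gene"] = "notingraph"
        lists = condition_influence_graph(graph, expr, MutationTable(df))
        assert lists["notingraph"].empty

    def test_output_weights_come_from_input_or_one(self):
        graph, expr, mut = self._setup(shift_neighbours=3, seed=4)
        lists = condition_influence_graph(graph, expr, mut)
        assert set(lists["driver"]["weight"]).issubset({0.8, 1.0})


class TestFisherCombination:
    def test_pair_significant_only_jointly(self):
        tables = {
            "cohortA": pd.DataFrame({"gene": ["g"], "neighbour": ["n"], "p": [0.03]}),
            "cohortB": pd.DataFrame({"gene": ["g"], "neighbour": ["n"], "p": [0.04]}),
        }
        out = combine_cohort_tests(tables)
        assert out.loc[0, "p_combined"] < 0.03
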