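"""Condition-wise correlation, p-critic, differential pairs, modules."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from dicoexnet import (
    CoexpressionModule,
    ConditionCorrelation,
    DifferentialCoexpressionModel,
    PCritic,
    build_network,
    compute_pcritic,
    correlation_pattern_summary,
    detect_modules,
    network_density,
    pairwise_scc,
    select_differential_pairs,
)

from conftest import spearman_oracle


def frame(rows, genes=None):
    rows = np.asarray(rows, dtype=float)
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    return pd.DataFrame(
        rows, index=genes, columns=[f"s{j}" for j in range(rows.shape[1])]
    )


def corr_from_matrix(matrix, condition="disease", n_samples=10):
    return ConditionCorrelation(
        genes=[f"g{i}" for i in range(len(matrix))],
        scc=np.asarray(matrix, dtype=float),
        condition=condition,
        n_samples=n_samples,
    )


class TestPairwiseSCC:
    def test_perfect_monotone_and_antimonotone(self):
        corr = pairwise_scc(frame([[1, 2, 3], [2, 4, 6]]), "disease")
        assert corr.scc[0, 1] == pytest.approx(1.0)
        corr = pairwise_scc(frame([[1, 2, 3], [3, 2, 1]]), "disease")
        assert corr.scc[0, 1] == pytest.approx(-1.0)

    def test_tied_input_matches_rank_pearson_oracle(self):
        x, y = [1, 1, 2, 3], [1, 2, 3, 4]
        corr = pairwise_scc(frame([x, y]), "control")
        assert corr.scc[0, 1] == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_matches_oracle_on_random_small_matrices(self):
        # ties injected by rounding; every pair of every matrix is checked
        rng = np.random.default_rng(42)
        for _ in range(200):
            n_genes = rng.integers(2, 7)
            n_samples = rng.integers(3, 9)
            data = np.round(rng.normal(0, 1, size=(n_genes, n_samples)), 1)
            corr = pairwise_scc(frame(data), "disease")
            for i, j in itertools.combinations(range(n_genes), 2):
                expected = spearman_oracle(data[i], data[j])
                if np.isnan(expected):  # constant row: correlation undefined
                    continue
                assert corr.scc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(1)
        corr = pairwise_scc(frame(rng.normal(size=(5, 8))), "disease")
        np.testing.assert_allclose(corr.scc, corr.scc.T, atol=1e-15)
        np.testing.assert_allclose(np.diag(corr.scc), 1.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            pairwise_scc(frame([[1, 2], [2, 1]]), "disease")


class TestComputePCritic:
    def test_hand_example(self):
        # pairs {0.1, 0.2, 0.3}: mean 0.2, sample sd 0.1 -> 0.396
        corr = corr_from_matrix(
            [[1, 0.1, 0.2], [0.1, 1, 0.3], [0.2, 0.3, 1]]
        )
        pc = compute_pcritic(corr)
        assert pc.value == pytest.approx(0.396)

    def test_constant_pairs_degenerate_to_their_value(self):
        c = 0.42
        corr = corr_from_matrix([[1, c, c], [c, 1, c], [c, c, 1]])
        assert compute_pcritic(corr).value == pytest.approx(c)

    def test_multiplier_is_1_96(self):
        from dicoexnet.diffcoexp import PCRITIC_MULTIPLIER

        assert PCRITIC_MULTIPLIER == 1.96
        pc = PCritic(condition="disease", mean_scc=0.1, std_scc=0.2)
        assert pc.value == pytest.approx(0.1 + 1.96 * 0.2)

    def test_single_pair_rejected(self):
        corr = corr_from_matrix([[1, 0.5], [0.5, 1]])
        with pytest.raises(ValueError):
            compute_pcritic(corr)


class TestSelectDifferentialPairs:
    def _pcritic(self, value, condition="disease"):
        return PCritic(condition=condition, mean_scc=value, std_scc=0.0)

    def test_rule_application(self):
        corr_d = corr_from_matrix([[1, 0.9], [0.9, 1]])
        corr_h = corr_from_matrix([[1, 0.2], [0.2, 1]], "control")
        pairs = select_differential_pairs(
            corr_d, corr_h, self._pcritic(0.5), 0.5,
            pcritic_h=self._pcritic(0.5, "control"),
        )
        assert len(pairs) == 1
        row = pairs.iloc[0]
        assert row["epsilon"] == pytest.approx(0.7)
        assert row["significant_d"] and not row["significant_h"]

    def test_equal_correlations_excluded(self):
        corr_d = corr_from_matrix([[1, 0.9], [0.9, 1]])
        corr_h = corr_from_matrix([[1, 0.9], [0.9, 1]], "control")
        pairs = select_differential_pairs(
            corr_d, corr_h, self._pcritic(0.1), 0.5,
            pcritic_h=self._pcritic(0.1, "control"),
        )
        assert len(pairs) == 0

    def test_truth_table_over_grid(self):
        # exhaustive agreement with |SCCd|>pcritic and |SCCd-SCCh|>0.5
        grid = np.arange(-1, 1.01, 0.25)
        for scc_d, scc_h, pcritic in itertools.product(grid, grid, (0.2, 0.5, 0.8)):
            corr_d = corr_from_matrix([[1, scc_d], [scc_d, 1]])
            corr_h = corr_from_matrix([[1, scc_h], [scc_h, 1]], "control")
            pairs = select_differential_pairs(
                corr_d, corr_h, self._pcritic(pcritic), 0.5,
                pcritic_h=self._pcritic(pcritic, "control"),
            )
            expected = abs(scc_d) > pcritic and abs(scc_d - scc_h) > 0.5
            assert (len(pairs) == 1) == expected, (scc_d, scc_h, pcritic)

    def test_monotone_in_epsilon_threshold(self):
        rng = np.random.default_rng(9)
        raw = rng.uniform(-1, 1, size=(6, 6))
        scc_d = np.clip((raw + raw.T) / 2, -1, 1)
        np.fill_diagonal(scc_d, 1.0)
        corr_d = corr_from_matrix(scc_d)
        corr_h = corr_from_matrix(np.eye(6), "control")
        counts = []
        for eps in (0.1, 0.3, 0.5, 0.7, 0.9):
            counts.append(
                len(
                    select_differential_pairs(
                        corr_d, corr_h, self._pcritic(0.1), eps,
                        pcritic_h=self._pcritic(0.1, "control"),
                    )
                )
            )
        assert counts == sorted(counts, reverse=True)

    def test_mismatched_gene_universe_rejected(self):
        corr_d = corr_from_matrix([[1, 0.5], [0.5, 1]])
        corr_h = ConditionCorrelation(
            genes=["x", "y"], scc=np.eye(2), condition="control", n_samples=5
        )
        with pytest.raises(ValueError, match="different genes"):
            select_differential_pairs(corr_d, corr_h, self._pcritic(0.1))


class TestBuildNetwork:
    @staticmethod
    def _pairs(rows):
        return pd.DataFrame(
            rows,
            columns=["gene_a", "gene_b", "scc_d", "scc_h", "epsilon",
                     "significant_d", "significant_h"],
        )

    def test_empty_and_path(self):
        assert build_network(self._pairs([])).number_of_nodes() == 0
        g = build_network(
            self._pairs(
                [("A", "B", 0.9, 0.1, 0.8, True, False),
                 ("B", "C", 0.8, 0.1, 0.7, True, False)]
            )
        )
        assert sorted(g.nodes) == ["A", "B", "C"] and g.number_of_edges() == 2
        assert g.edges["A", "B"]["epsilon"] == pytest.approx(0.8)

    def test_duplicate_pair_collapses_to_one_edge(self):
        g = build_network(
            self._pairs(
                [("A", "B", 0.9, 0.1, 0.8, True, False),
                 ("B", "A", 0.9, 0.1, 0.8, True, False)]
            )
        )
        assert g.number_of_edges() == 1


class TestNetworkDensity:
    @pytest.mark.parametrize("n", range(2, 11))
    def test_complete_graph_density_one(self, n):
        assert network_density(n, n * (n - 1) // 2) == pytest.approx(1.0)

    def test_values(self):
        assert network_density(5, 10) == pytest.approx(1.0)
        assert network_density(21, 45) == pytest.approx(45 / 210)
        assert network_density(2, 0) == 0.0

    def test_out_of_range_edges_rejected(self):
        with pytest.raises(ValueError):
            network_density(3, 4)
        with pytest.raises(ValueError):
            network_density(1, 0)


class TestDetectModules:
    def test_two_cliques_with_bridge(self):
        g = nx.compose(
            nx.complete_graph([f"a{i}" for i in range(6)]),
            nx.complete_graph([f"b{i}" for i in range(5)]),
        )
        g.add_edge("a0", "b0")
        modules = detect_modules(g, min_size=3, density_threshold=0.9)
        assert len(modules) == 2
        assert {m.n_nodes for m in modules} == {6, 5}
        assert all(m.density == pytest.approx(1.0) for m in modules)

    def test_star_graph_yields_nothing_at_density_half(self):
        g = nx.star_graph(10)
        assert detect_modules(g, min_size=3, density_threshold=0.5) == []

    def test_empty_graph(self):
        assert detect_modules(nx.Graph()) == []

    def test_dense_component_kept_whole(self):
        # a clique missing a few edges should not be fragmented
        g = nx.complete_graph(12)
        g.remove_edges_from([(0, 1), (2, 3), (4, 5)])
        modules = detect_modules(g, min_size=5, density_threshold=0.5)
        assert len(modules) == 1 and modules[0].n_nodes == 12

    def test_deterministic_under_relabelling(self):
        g = nx.complete_graph([f"n{i}" for i in range(7)])
        m1 = detect_modules(g, min_size=3, density_threshold=0.5)
        g2 = nx.relabel_nodes(g, {f"n{i}": f"n{6 - i}" for i in range(7)})
        m2 = detect_modules(g2, min_size=3, density_threshold=0.5)
        assert [m.nodes for m in m1] == [m.nodes for m in m2]


class TestCorrelationPatternSummary:
    def _module(self, genes):
        return CoexpressionModule(
            module_id="M1", nodes=tuple(genes),
            edges=frozenset(), density=1.0,
        )

    def test_all_positive(self):
        scc = np.full((4, 4), 0.9)
        np.fill_diagonal(scc, 1.0)
        corr_d = ConditionCorrelation(list("abcd"), scc, "disease", 10)
        corr_h = ConditionCorrelation(list("abcd"), np.eye(4), "control", 10)
        pc = PCritic("disease", 0.5, 0.0)
        pch = PCritic("control", 0.5, 0.0)
        summary = correlation_pattern_summary(
            self._module("abcd"), corr_d, corr_h, pc, pch
        )
        d = summary["conditions"]["disease"]
        assert d["positive"] == 6 and d["negative"] == 0
        assert d["pct_positive_of_total"] == pytest.approx(100.0)

    def test_counts_match_exhaustive_loop(self):
        rng = np.random.default_rng(5)
        raw = rng.uniform(-1, 1, size=(6, 6))
        scc = (raw + raw.T) / 2
        np.fill_diagonal(scc, 1.0)
        genes = list("abcdef")
        corr_d = ConditionCorrelation(genes, scc, "disease", 10)
        corr_h = ConditionCorrelation(genes, -scc, "control", 10)
        pc = PCritic("disease", 0.2, 0.0)
        pch = PCritic("control", 0.2, 0.0)
        summary = correlation_pattern_summary(
            self._module(genes), corr_d, corr_h, pc, pch
        )
        pos = neg = 0
        for i in range(6):
            for j in range(i + 1, 6):
                if scc[i, j] > 0.2:
                    pos += 1
                elif scc[i, j] < -0.2:
                    neg += 1
        d = summary["conditions"]["disease"]
        assert (d["positive"], d["negative"]) == (pos, neg)
        h = summary["conditions"]["control"]
        assert (h["positive"], h["negative"]) == (neg, pos)

    def test_no_significant_pairs(self):
        corr = ConditionCorrelation(list("abc"), np.eye(3), "disease", 10)
        corr_h = ConditionCorrelation(list("abc"), np.eye(3), "control", 10)
        pc = PCritic("disease", 0.9, 0.0)
        summary = correlation_pattern_summary(
            self._module("abc"), corr, corr_h, pc,
            PCritic("control", 0.9, 0.0),
        )
        d = summary["conditions"]["disease"]
        assert d["positive"] == 0 and d["pct_positive_of_significant"] is None


class TestModelFit:
    def test_planted_module_recovered(self, small_sim):
        config, studies, truth = small_sim
        results = DifferentialCoexpressionModel(
            studies, genes=truth.planted_degs
        ).fit()
        assert results.modules, results.summary()
        top = set(results.modules[0].nodes)
        planted = set(truth.module_genes)
        assert len(top & planted) / len(top | planted) >= 0.8

    def test_summary_mentions_key_quantities(self, small_sim):
        config, studies, truth = small_sim
        results = DifferentialCoexpressionModel(
            studies, genes=truth.planted_degs
        ).fit()
        text = results.summary()
        assert "p-critic" in text and "epsilon" in text
        assert f"{len(truth.planted_degs)}" in text

    def test_exports(self, small_sim, tmp_path):
        config, studies, truth = small_sim
        results = DifferentialCoexpressionModel(
            studies, genes=truth.planted_degs
        ).fit()
        results.to_graphml(tmp_path / "net.graphml")
        results.to_sif(tmp_path / "net.sif")
        g = nx.read_graphml(tmp_path / "net.graphml")
        assert g.number_of_edges() == results.network.number_of_edges()
        assert (tmp_path / "net.sif").read_text().count("coexp") == g.number_of_edges()
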