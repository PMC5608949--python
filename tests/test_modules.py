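"""Module representatives, scoring, greedy search, consolidation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fluidmap import modules, synth, hierarchy
from fluidmap.datatypes import CorrelationNetwork, Module, PhenotypeTable


class TestRepresentative:
    def test_single_metabolite_is_its_zscore(self):
        data = pd.DataFrame({"m": [1.0, 3.0, 5.0, 7.0]})
        rep = modules.module_representative(data, ["m"])
        z = (data["m"] - 4.0) / data["m"].std(ddof=1)
        assert np.allclose(rep, z)

    def test_identical_members_equal_one_zscore(self):
        data = pd.DataFrame({"a": [1.0, 2.0, 4.0], "b": [1.0, 2.0, 4.0]})
        rep = modules.module_representative(data, ["a", "b"])
        z = (data["a"] - data["a"].mean()) / data["a"].std(ddof=1)
        assert np.allclose(rep, z)

    def test_set_union_mean_against_hand_computation(self):
        # two pathway nodes with 3 + 2 members over 4 samples
        raw = pd.DataFrame(
            {
                "a1": [1.0, 2.0, 3.0, 4.0],
                "a2": [2.0, 2.0, 4.0, 4.0],
                "a3": [0.0, 1.0, 1.0, 2.0],
                "b1": [5.0, 4.0, 3.0, 2.0],
                "b2": [1.0, 1.0, 2.0, 8.0],
            }
        )
        members = ["a1", "a2", "a3", "b1", "b2"]
        rep = modules.module_representative(raw, members)
        z = (raw - raw.mean()) / raw.std(ddof=1)
        assert np.allclose(rep, z[members].mean(axis=1))

    def test_empty_member_set_errors(self):
        with pytest.raises(ValueError):
            modules.module_representative(pd.DataFrame({"m": [1.0, 2.0]}), [])


class TestScoring:
    def test_perfect_fit_hits_score_cap(self):
        rng = np.random.default_rng(0)
        P = rng.standard_normal(50)
        score, p = modules.score_module(P.copy(), P)
        assert score == modules.SCORE_CAP and p == 0.0

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(1)
        pvals = []
        for _ in range(200):
            y = rng.standard_normal(1000)
            P = rng.standard_normal(1000)
            _, p = modules.score_module(y, P)
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_matches_statsmodels_ols(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(2)
        n = 200
        cov = rng.standard_normal((n, 3))
        P = rng.standard_normal(n)
        y = 0.2 * P + cov @ [0.3, -0.1, 0.5] + rng.standard_normal(n)
        score, p = modules.score_module(y, P, cov)
        X = sm.add_constant(np.column_stack([P, cov]))
        ref = sm.OLS(y, X).fit()
        assert p == pytest.approx(ref.pvalues[1], rel=1e-10)
        assert score == pytest.approx(-np.log10(ref.pvalues[1]), rel=1e-10)

    def test_constant_inputs_error(self):
        with pytest.raises(ValueError):
            modules.score_module(np.ones(20), np.random.default_rng(0).standard_normal(20))
        with pytest.raises(ValueError):
            modules.score_module(np.random.default_rng(0).standard_normal(20), np.ones(20))

    def test_collinear_design_errors(self):
        rng = np.random.default_rng(3)
        P = rng.standard_normal(30)
        with pytest.raises(ValueError, match="rank"):
            modules.score_module(rng.standard_normal(30), P, np.column_stack([P, P]))

    def test_phenotype_never_its_own_covariate(self):
        t = pd.DataFrame(
            {
                "gender": np.random.default_rng(0).integers(0, 2, 30).astype(float),
                "age": np.random.default_rng(1).normal(50, 10, 30),
                "BMI": np.random.default_rng(2).normal(27, 4, 30),
            },
            index=[f"s{i}" for i in range(30)],
        )
        phen = PhenotypeTable(t, phenotype="gender",
                              covariates=("age", "gender", "BMI"))
        assert "gender" not in phen.covariates


def _stub_scorer(table: dict):
    def scorer(nodes: frozenset):
        score = table[frozenset(nodes)]
        return score, 10.0 ** (-score)
    return scorer


class TestGreedy:
    def test_isolated_seed_stays_alone(self):
        net = CorrelationNetwork("metabolite", ["a", "b"], {})
        scorer = _stub_scorer({frozenset("a"): 2.0, frozenset("b"): 1.0})
        m = modules.greedy_search(net, "a", scorer)
        assert m.nodes == frozenset("a") and m.status == "optimal"

    def test_path_example_rejects_diluting_third_node(self):
        net = CorrelationNetwork(
            "metabolite", ["A", "B", "C"], {("A", "B"): None, ("B", "C"): None}
        )
        table = {
            frozenset("A"): 1.0, frozenset("B"): 1.0, frozenset("C"): 1.0,
            frozenset("AB"): 3.0, frozenset("BC"): 3.0, frozenset("ABC"): 2.5,
        }
        m = modules.greedy_search(net, "A", _stub_scorer(table))
        assert m.nodes == frozenset("AB") and m.score == 3.0

    def test_missing_seed_errors(self):
        net = CorrelationNetwork("metabolite", ["a"], {})
        with pytest.raises(ValueError):
            modules.greedy_search(net, "zz", _stub_scorer({frozenset("a"): 1.0}))

    def test_dominance_blocks_growth(self):
        # pair would improve on the seed but not beat the stronger single
        net = CorrelationNetwork("metabolite", ["a", "b"], {("a", "b"): None})
        table = {
            frozenset("a"): 1.0, frozenset("b"): 5.0, frozenset("ab"): 4.0,
        }
        m = modules.greedy_search(net, "a", _stub_scorer(table))
        assert m.nodes == frozenset("a")


def _enumerate_connected_subsets(adj: dict):
    nodes = sorted(adj)
    out = []
    for r in range(1, len(nodes) + 1):
        for combo in itertools.combinations(nodes, r):
            # connectivity check by BFS
            todo, seen = [combo[0]], {combo[0]}
            sub = set(combo)
            while todo:
                u = todo.pop()
                for v in adj[u] & sub - seen:
                    seen.add(v)
                    todo.append(v)
            if seen == sub:
                out.append(frozenset(combo))
    return out


class TestGreedyVsExhaustive:
    def test_never_beats_brute_force_on_small_graphs(self):
        """On random graphs <= 8 nodes with random subset scores the greedy
        optimum never exceeds the exhaustive optimum, and every result is
        connected."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(2, 9))
            nodes = [f"n{i}" for i in range(n)]
            edges = {}
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.4:
                        edges[(nodes[i], nodes[j])] = None
            net = CorrelationNetwork("metabolite", nodes, edges)
            adj = net.adjacency()
            subsets = _enumerate_connected_subsets(adj)
            table = {s: float(rng.random() * 10) for s in subsets}
            scorer = _stub_scorer(table)
            best = max(table.values())
            for seed in nodes:
                m = modules.greedy_search(net, seed, scorer)
                assert m.score <= best + 1e-12
                assert m.nodes in table  # connected by construction
                assert m.score >= table[frozenset([seed])] - 1e-12


class TestConsolidate:
    def _scorer(self):
        return _stub_scorer(
            {
                frozenset("AB"): 1.0, frozenset("BC"): 1.0, frozenset("D"): 1.0,
                frozenset("ABC"): 2.0,
            }
        )

    def _module(self, nodes, seeds=None):
        return Module(
            nodes=frozenset(nodes), score=1.0, p_value=0.1,
            seeds=frozenset(seeds or list(nodes)[:1]),
        )

    def test_overlapping_chain_merges(self):
        out = modules.consolidate(
            [self._module("AB"), self._module("BC"), self._module("D")],
            self._scorer(),
        )
        assert {m.nodes for m in out} == {frozenset("ABC"), frozenset("D")}
        assert all(m.status == "maximal" for m in out)
        # merged module was rescored
        merged = next(m for m in out if m.nodes == frozenset("ABC"))
        assert merged.score == 2.0

    def test_identical_optima_collapse_to_one(self):
        scorer = _stub_scorer({frozenset("AB"): 1.5})
        out = modules.consolidate(
            [self._module("AB", "A"), self._module("AB", "B")], scorer
        )
        assert len(out) == 1 and out[0].seeds == frozenset("AB")

    def test_disjoint_optima_unchanged(self):
        scorer = _stub_scorer({frozenset("AB"): 1.0, frozenset("D"): 1.0})
        out = modules.consolidate(
            [self._module("AB"), self._module("D")], scorer
        )
        assert {m.nodes for m in out} == {frozenset("AB"), frozenset("D")}

    def test_maximal_modules_pairwise_disjoint(self):
        rng = np.random.default_rng(5)
        universe = [f"n{i}" for i in range(12)]
        mods = []
        table = {}
        for _ in range(8):
            pick = frozenset(rng.choice(universe, size=3, replace=False))
            table[pick] = 1.0
            mods.append(self._module(pick))
        # score any union the consolidation may request
        def scorer(nodes):
            return 1.0, 0.1
        out = modules.consolidate(mods, scorer)
        for a, b in itertools.combinations(out, 2):
            assert not (a.nodes & b.nodes)


class TestFilterSignificant:
    def _scorer(self, singles):
        def scorer(nodes):
            nodes = frozenset(nodes)
            if len(nodes) == 1:
                s = singles[next(iter(nodes))]
                return s, 10.0 ** (-s)
            raise AssertionError("filter should only rescore singles")
        return scorer

    def test_bonferroni_threshold_arithmetic(self):
        singles = {"a": 0.5, "b": 0.5, "c": 0.5, "d": 0.5}
        keep = Module(frozenset("ab"), score=-np.log10(5e-4), p_value=5e-4,
                      seeds=frozenset("a"), status="maximal")
        drop = Module(frozenset("cd"), score=-np.log10(2e-3), p_value=2e-3,
                      seeds=frozenset("c"), status="maximal")
        report = modules.filter_significant(
            [keep, drop], n_nodes=50, scorer=self._scorer(singles)
        )
        assert report.bonferroni_threshold == pytest.approx(1e-3)
        assert [m.nodes for m in report.modules] == [frozenset("ab")]

    def test_dominant_member_disqualifies_module(self):
        singles = {"a": 9.0, "b": 0.1}
        m = Module(frozenset("ab"), score=5.0, p_value=1e-5,
                   seeds=frozenset("a"), status="maximal")
        report = modules.filter_significant(
            [m], n_nodes=10, scorer=self._scorer(singles)
        )
        assert report.modules == []

    def test_empty_candidates_empty_report(self):
        report = modules.filter_significant([], n_nodes=5, scorer=None)
        assert report.modules == []

    def test_zero_nodes_errors(self):
        with pytest.raises(ValueError):
            modules.filter_significant([], n_nodes=0, scorer=None)


class TestEndToEnd:
    def test_permuted_phenotype_yields_no_modules(self):
        cfg = synth.sparse_phenotype_config(seed=0)
        x, ann, phen, _ = synth.generate(cfg, seed=0)
        hmap = hierarchy.build_hierarchical_map(
            np.log2(x.values), ann, covariates=phen.covariate_matrix()
        )
        clean = 0
        for s in range(10):
            rng = np.random.default_rng(777 + s)
            t = phen.table.copy()
            t["P"] = rng.permutation(t["P"].to_numpy())
            rep = modules.run_module_identification(
                hmap, PhenotypeTable(t, "P", phen.covariates), level="metabolite"
            )
            clean += len(rep.modules) == 0
        assert clean >= 9

    def test_dense_phenotype_finds_more_metabolite_than_subpathway_modules(self):
        cfg = synth.make_cohort_config(n_samples=906, scale=0.15, seed=2)
        cfg.censor_quantile = 0.0
        x0, _, _, _ = synth.generate(cfg, seed=2)
        feats = list(x0.values.columns)
        rng = np.random.default_rng(2)
        dense = sorted(rng.choice(feats, size=len(feats) // 2, replace=False))
        cfg.planted_effects = {f: 0.12 for f in dense}
        x, ann, phen, _ = synth.generate(cfg, seed=2)
        hmap = hierarchy.build_hierarchical_map(
            np.log2(x.values), ann, covariates=phen.covariate_matrix()
        )
        rep_met = modules.run_module_identification(hmap, phen, level="metabolite")
        rep_sub = modules.run_module_identification(hmap, phen, level="sub_pathway")
        assert len(rep_met.modules) > len(rep_sub.modules)

    def test_reported_modules_satisfy_invariants(self):
        cfg = synth.sparse_phenotype_config(seed=1)
        x, ann, phen, truth = synth.generate(cfg, seed=1)
        hmap = hierarchy.build_hierarchical_map(
            np.log2(x.values), ann, covariates=phen.covariate_matrix()
        )
        rep = modules.run_module_identification(hmap, phen, level="metabolite")
        adj = hmap.metabolite.adjacency()
        for m in rep.modules:
            # connected in the network
            nodes = set(m.nodes)
            todo, seen = [next(iter(nodes))], {next(iter(nodes))}
            while todo:
                u = todo.pop()
                for v in adj[u] & nodes - seen:
                    seen.add(v)
                    todo.append(v)
            assert seen == nodes
            assert m.p_value < rep.bonferroni_threshold
            assert m.score == pytest.approx(-np.log10(m.p_value))
        for a, b in itertools.combinations(rep.modules, 2):
            assert not (a.nodes & b.nodes)
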