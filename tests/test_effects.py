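"""Tests for direct-effect selection, classification and total effects."""

import itertools

import numpy as np
import pandas as pd
import pytest

from causalome.containers import PhenotypeTable
from causalome.effects import (
    DirectEffectAnalyzer,
    attach_risk_factor,
    bootstrap_se,
    classify_indirect,
    fit_edge_coefficients,
    identify_direct,
    per_visit_analysis,
    total_effect,
    total_effect_matrix,
)
from causalome.network import CausalGraph


def _paths_total_effect(B: pd.DataFrame, source: str, target: str) -> float:
    """Oracle: brute-force enumeration of directed paths source -> target."""
    children = {
        p: [c for c in B.index if B.loc[c, p] != 0.0] for p in B.columns
    }

    def walk(node, product):
        total = 0.0
        for child in children[node]:
            contrib = product * B.loc[child, node]
            if child == target:
                total += contrib
            else:
                total += walk(child, contrib)
        return total

    return walk(source, 1.0)


def _exact_cov_data(sigma: np.ndarray, n: int, columns, rng) -> pd.DataFrame:
    """Data whose *sample* covariance equals sigma exactly: whiten a
    random draw, then color with the Cholesky factor of sigma."""
    X = rng.standard_normal((n, sigma.shape[0]))
    X -= X.mean(axis=0)
    C = np.cov(X, rowvar=False)
    X = X @ np.linalg.inv(np.linalg.cholesky(C)).T
    X = X @ np.linalg.cholesky(sigma).T
    return pd.DataFrame(X, columns=columns)


class TestIdentifyDirect:
    def test_recovers_planted_parents(self):
        rng = np.random.default_rng(0)
        n, m = 2479, 10
        X = pd.DataFrame(
            rng.standard_normal((n, m)), columns=[f"M{i:02d}" for i in range(m)]
        )
        y = 0.3 * X["M02"] - 0.25 * X["M07"] + rng.standard_normal(n)
        direct, pvals = identify_direct(X, y, alpha=0.001)
        assert direct == ["M02", "M07"]
        assert (pvals < 0.001).all()

    def test_mediated_parent_excluded(self):
        # M3 -> M1 -> y: only the mediator M1 is in the Markov boundary
        rng = np.random.default_rng(1)
        n = 20000
        m3 = rng.standard_normal(n)
        m1 = 0.8 * m3 + rng.standard_normal(n)
        m2 = rng.standard_normal(n)
        X = pd.DataFrame({"M1": m1, "M2": m2, "M3": m3})
        y = 0.5 * m1 + rng.standard_normal(n)
        direct, _ = identify_direct(X, y, alpha=0.001)
        assert direct == ["M1"]

    def test_covariates_remove_confounded_candidate(self):
        # C drives both M1 and y; adjusting for C empties the selection
        rng = np.random.default_rng(2)
        n = 20000
        c = rng.standard_normal(n)
        X = pd.DataFrame({"M1": 0.7 * c + rng.standard_normal(n)})
        y = 0.7 * c + rng.standard_normal(n)
        unadj, _ = identify_direct(X, pd.Series(y), alpha=0.001)
        assert unadj == ["M1"]
        adj, _ = identify_direct(
            X, pd.Series(y), alpha=0.001, covariates=pd.DataFrame({"C": c})
        )
        assert adj == []

    def test_candidates_restriction(self):
        rng = np.random.default_rng(3)
        n = 5000
        X = pd.DataFrame(rng.standard_normal((n, 3)), columns=["A", "B", "C"])
        y = 0.5 * X["A"] + 0.5 * X["B"] + rng.standard_normal(n)
        direct, _ = identify_direct(X, y, alpha=0.001, candidates=["A", "C"])
        assert direct == ["A"]

    def test_zero_variance_outcome_rejected(self):
        X = pd.DataFrame({"A": np.arange(10.0)})
        with pytest.raises(ValueError, match="variance"):
            identify_direct(X, pd.Series(np.ones(10)))


class TestClassification:
    def _graph(self):
        # M3 -> M1, M4 isolated, M1 is the direct metabolite
        g = CausalGraph(["M1", "M2", "M3", "M4"])
        g.add_directed("M3", "M1")
        g.add_undirected("M2", "M4")
        return g

    def test_partition(self):
        status = classify_indirect(self._graph(), ["M1"])
        assert status == {"M1": "direct", "M3": "indirect", "M2": "none", "M4": "none"}

    def test_undirected_edges_do_not_establish_ancestry(self):
        g = CausalGraph(["A", "B"])
        g.add_undirected("A", "B")
        status = classify_indirect(g, ["B"])
        assert status["A"] == "none"

    def test_direct_wins_over_indirect(self):
        g = CausalGraph(["A", "B"])
        g.add_directed("A", "B")
        status = classify_indirect(g, ["A", "B"])
        assert status == {"A": "direct", "B": "direct"}

    def test_attach_risk_factor_sink(self):
        g = attach_risk_factor(self._graph(), ["M1"])
        assert ("M1", "TG") in g.directed
        assert g.in_degree("TG") == 1
        assert g.children("TG") == []


class TestEdgeCoefficients:
    def test_single_edge_recovery(self):
        rng = np.random.default_rng(4)
        n = 20000
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        g = CausalGraph(["X", "Y"])
        g.add_directed("X", "Y")
        B, resid = fit_edge_coefficients(g, pd.DataFrame({"X": x, "Y": y}))
        assert B.loc["Y", "X"] == pytest.approx(0.5, abs=3 / np.sqrt(n))
        assert resid["Y"] == pytest.approx(1.0, abs=0.05)
        assert resid["X"] == pytest.approx(1.0, abs=0.05)

    def test_population_exact_recovery(self):
        # sample covariance forced to the SEM's population covariance:
        # OLS per node returns the structural coefficients exactly
        Bm = np.array(
            [[0.0, 0.0, 0.0], [0.5, 0.0, 0.0], [0.3, -0.4, 0.0]]
        )
        A = np.linalg.inv(np.eye(3) - Bm)
        sigma = A @ A.T
        data = _exact_cov_data(sigma, 500, ["a", "b", "c"], np.random.default_rng(5))
        g = CausalGraph(["a", "b", "c"])
        g.add_directed("a", "b")
        g.add_directed("a", "c")
        g.add_directed("b", "c")
        B, _ = fit_edge_coefficients(g, data)
        assert B.loc["b", "a"] == pytest.approx(0.5, abs=1e-10)
        assert B.loc["c", "a"] == pytest.approx(0.3, abs=1e-10)
        assert B.loc["c", "b"] == pytest.approx(-0.4, abs=1e-10)

    def test_collinear_parents_error_names_node(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(100)
        data = pd.DataFrame({"P1": x, "P2": x, "C": rng.standard_normal(100)})
        g = CausalGraph(["P1", "P2", "C"])
        g.add_directed("P1", "C")
        g.add_directed("P2", "C")
        with pytest.raises(ValueError, match="C"):
            fit_edge_coefficients(g, data)

    def test_instrument_nodes_excluded(self):
        rng = np.random.default_rng(7)
        data = pd.DataFrame({"X": rng.standard_normal(50), "Y": rng.standard_normal(50)})
        g = CausalGraph(["X", "Y", "IV_X"])
        g.instrument_nodes.add("IV_X")
        g.add_directed("IV_X", "X")
        g.add_directed("X", "Y")
        B, _ = fit_edge_coefficients(g, data)
        assert list(B.index) == ["X", "Y"]


class TestTotalEffects:
    def test_chain_product(self):
        B = pd.DataFrame(0.0, index=["a", "b", "c"], columns=["a", "b", "c"])
        B.loc["b", "a"] = 0.5
        B.loc["c", "b"] = 0.4
        assert total_effect(B, "a", "c") == pytest.approx(0.2, abs=1e-15)
        assert total_effect(B, "a", "b") == pytest.approx(0.5, abs=1e-15)
        assert total_effect(B, "c", "a") == 0.0  # no path against the flow

    def test_matches_path_enumeration_on_random_dags(self):
        rng = np.random.default_rng(8)
        names = list("abcde")
        for _ in range(20):
            B = pd.DataFrame(0.0, index=names, columns=names)
            for i, j in itertools.combinations(range(5), 2):
                if rng.random() < 0.5:
                    B.iloc[j, i] = rng.uniform(-0.8, 0.8)
            T = total_effect_matrix(B)
            # second oracle: matrix power series sum_k B^k, k >= 1
            Bm = B.to_numpy()
            series = np.zeros_like(Bm)
            P = np.eye(5)
            for _ in range(5):
                P = P @ Bm
                series += P
            assert np.allclose(T.to_numpy(), series, atol=1e-12)
            for s in names:
                for t in names:
                    if s == t:
                        continue
                    assert T.loc[t, s] == pytest.approx(
                        _paths_total_effect(B, s, t), abs=1e-12
                    )

    def test_unknown_node_error(self):
        B = pd.DataFrame(0.0, index=["a"], columns=["a"])
        with pytest.raises(ValueError, match="z"):
            total_effect(B, "a", "z")


class TestBootstrap:
    def _single_edge(self, rng, n=2479, beta=0.5, noise=1.0):
        x = rng.standard_normal(n)
        y = beta * x + noise * rng.standard_normal(n)
        data = pd.DataFrame({"X": x, "TG": y})
        g = CausalGraph(["X", "TG"])
        g.add_directed("X", "TG")
        return g, data

    def test_deterministic_given_seed(self):
        g, data = self._single_edge(np.random.default_rng(9))
        se1, d1 = bootstrap_se(g, data, ["X"], n_boot=60, seed=42)
        se2, d2 = bootstrap_se(g, data, ["X"], n_boot=60, seed=42)
        assert se1.equals(se2) and d1 == d2
        se3, _ = bootstrap_se(g, data, ["X"], n_boot=60, seed=43)
        assert not se1.equals(se3)

    def test_matches_analytic_ols_se(self):
        g, data = self._single_edge(np.random.default_rng(10))
        se, dropped = bootstrap_se(g, data, ["X"], n_boot=200, seed=0)
        x = data["X"].to_numpy()
        y = data["TG"].to_numpy()
        xc = x - x.mean()
        beta = xc @ (y - y.mean()) / (xc @ xc)
        resid = (y - y.mean()) - beta * xc
        analytic = np.sqrt(resid @ resid / (len(x) - 2) / (xc @ xc))
        assert dropped == 0
        assert abs(se["X"] - analytic) / analytic < 0.30

    def test_noiseless_fit_gives_zero_se(self):
        g, data = self._single_edge(np.random.default_rng(11), noise=0.0)
        se, _ = bootstrap_se(g, data, ["X"], n_boot=60, seed=1)
        assert se["X"] < 1e-8

    def test_too_few_replicates_rejected(self):
        g, data = self._single_edge(np.random.default_rng(12))
        with pytest.raises(ValueError):
            bootstrap_se(g, data, ["X"], n_boot=10)


class TestPerVisit:
    def _study(self, rng, n=3000, attenuation=1.0):
        m1 = rng.standard_normal(n)
        m2 = 0.8 * m1 + rng.standard_normal(n)
        m3 = rng.standard_normal(n)
        idx = pd.Index([f"S{i}" for i in range(n)])
        X = pd.DataFrame({"M1": m1, "M2": m2, "M3": m3}, index=idx)
        g = CausalGraph(["M1", "M2", "M3"])
        g.add_directed("M1", "M2")
        visits = {}
        for v, size in enumerate((n, n // 2, 50), start=1):
            y = np.exp(
                attenuation ** (v - 1) * 0.6 * (m2 - m2.mean()) / m2.std()
                + 0.5 * rng.standard_normal(n)
            )
            col = np.full(n, np.nan)
            col[:size] = y[:size]
            visits[f"V{v}"] = col
        phen = PhenotypeTable(visits=pd.DataFrame(visits, index=idx))
        return X, g, phen

    def test_table_shape_and_status(self):
        rng = np.random.default_rng(13)
        X, g, phen = self._study(rng)
        with pytest.warns(UserWarning, match="skipped"):
            table = per_visit_analysis(g, X, phen, n_boot=60, min_visit_n=100)
        # visit 3 (50 samples) skipped; 3 metabolites x 2 visits
        assert sorted(table["visit"].unique()) == ["V1", "V2"]
        assert len(table) == 6
        v1 = table[table["visit"] == "V1"].set_index("metabolite")
        assert v1.loc["M2", "status"] == "direct"
        assert v1.loc["M1", "status"] == "indirect"
        assert v1.loc["M3", "status"] == "none"
        assert v1.loc["M2", "p_direct"] < 0.001
        # indirect effect is attenuated through the 0.8 edge
        assert abs(v1.loc["M1", "total_effect"]) < abs(v1.loc["M2", "total_effect"])

    def test_vanished_effect_not_direct_at_later_visit(self):
        rng = np.random.default_rng(14)
        X, g, phen = self._study(rng, attenuation=0.0)
        with pytest.warns(UserWarning, match="skipped"):
            table = per_visit_analysis(g, X, phen, n_boot=60, min_visit_n=100)
        v2 = table[table["visit"] == "V2"].set_index("metabolite")
        assert (v2["status"] != "direct").all() or v2.loc["M2", "p_direct"] >= 0.001

    def test_analyzer_estimator_interface(self):
        from sklearn.base import clone

        rng = np.random.default_rng(15)
        X, g, phen = self._study(rng)
        est = DirectEffectAnalyzer(n_boot=60, min_visit_n=100)
        assert clone(est).get_params()["n_boot"] == 60
        with pytest.warns(UserWarning, match="skipped"):
            est.fit(X, phen, graph=g)
        assert est.direct_ == ["M2"]
        assert est.indirect_ == ["M1"]
        assert est.status_["M3"] == "none"
        assert ("M2", "TG") in est.graph_tg_.directed
        assert set(est.effect_table_.columns) >= {
            "metabolite", "visit", "status", "p_direct", "total_effect",
            "se", "p_total", "p_adjusted", "n",
        }

    def test_analyzer_accepts_plain_series(self):
        rng = np.random.default_rng(16)
        n = 2000
        X = pd.DataFrame({"A": rng.standard_normal(n)})
        y = pd.Series(np.exp(0.5 * X["A"] + 0.5 * rng.standard_normal(n)))
        est = DirectEffectAnalyzer(n_boot=60).fit(X, np.exp(np.log(y)))
        assert est.direct_ == ["A"]
        assert len(est.effect_table_) == 1
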