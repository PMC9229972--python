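"""Penalized DAG learner: scoring, descent, constraints, solution path."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

import triomics as t
from triomics.dag import IllPosedError, penalized_score

from _oracles import all_dags, exhaustive_best_score
from conftest import random_typed_dag_edges, random_typed_meta


def _mm_meta(p):
    return [t.NodeMeta(f"x{i}", "MM", timepoint="fasting") for i in range(p)]


def _chain_data(rng, n=500, slope=0.9):
    x = rng.normal(size=n)
    y = slope * x + rng.normal(size=n)
    return pd.DataFrame({"x0": x, "x1": y})


class TestPenalizedScore:
    def test_empty_graph_closed_form(self, rng):
        n, p = 400, 3
        X = rng.normal(size=(n, p))
        X = (X - X.mean(0)) / X.std(0)
        got = penalized_score(np.zeros((p, p)), X, lam=5.0)
        sig2 = (X**2).sum(0) / n
        expect = sum(0.5 * n * (1 + math.log(2 * math.pi * s)) for s in sig2)
        assert got == pytest.approx(expect, abs=1e-8)

    def test_lam_zero_likelihood_improves_with_true_parent(self, rng):
        n = 500
        x = rng.normal(size=n)
        y = 0.8 * x + rng.normal(size=n)
        X = np.column_stack([x, y])
        X = X - X.mean(0)
        empty = penalized_score(np.zeros((2, 2)), X, lam=0.0)
        B = np.zeros((2, 2))
        B[0, 1] = float(np.linalg.lstsq(X[:, :1], X[:, 1], rcond=None)[0][0])
        assert penalized_score(B, X, lam=0.0) < empty

    def test_three_node_hand_oracle(self):
        # explicit residual-sum-of-squares arithmetic at fixed weights
        rng = np.random.default_rng(5)
        n = 50
        X = rng.normal(size=(n, 3))
        X = X - X.mean(0)
        B = np.zeros((3, 3))
        B[0, 1], B[1, 2] = 0.7, -0.4
        lam, gam = 3.0, 2.0
        r1 = X[:, 1] - 0.7 * X[:, 0]
        r2 = X[:, 2] + 0.4 * X[:, 1]
        rss = [float(X[:, 0] @ X[:, 0]), float(r1 @ r1), float(r2 @ r2)]
        nll = sum(0.5 * n * (1 + math.log(2 * math.pi * s / n)) for s in rss)
        mu = lam / math.sqrt(n)

        def mcp(v):
            v = abs(v)
            return mu * v - v * v / (2 * gam) if v <= gam * mu else gam * mu * mu / 2

        expect = nll + n * (mcp(0.7) + mcp(-0.4))
        assert penalized_score(B, X, lam, "mcp", gam) == pytest.approx(expect, abs=1e-10)

    def test_too_many_parents_error(self):
        X = np.random.default_rng(0).normal(size=(3, 4))
        B = np.zeros((4, 4))
        B[[0, 1, 2], 3] = 1.0
        with pytest.raises(IllPosedError):
            penalized_score(B, X, 1.0)


class TestLearnDag:
    def test_large_lambda_gives_empty_graph(self, rng):
        n = 300
        df = pd.DataFrame(rng.normal(size=(n, 4)), columns=[f"x{i}" for i in range(4)])
        df["x1"] += 0.9 * df["x0"]
        meta = _mm_meta(4)
        model = t.GaussianDAGModel(df, meta, blocklist=t.empty_blocklist())
        res = model.fit(model.lambda_max() + 0.5)
        assert res.n_edges == 0

    def test_blocklist_forces_direction(self, rng):
        # forbid x0 -> x1; learner may use the reverse or nothing
        df = _chain_data(rng)
        meta = _mm_meta(2)
        bl = t.Blocklist(forbidden_type_rules=frozenset(), extra_predicates=(
            ("no_forward", lambda a, b: (a.node_id, b.node_id) == ("x0", "x1")),
        ))
        res = t.learn_dag(df, meta, blocklist=bl, lam=5.0)
        assert ("x0", "x1") not in {(u, v) for u, v, _ in res.edges()}

    def test_unpenalized_two_node_equals_ols(self, rng):
        df = _chain_data(rng)
        meta = _mm_meta(2)
        res = t.learn_dag(df, meta, blocklist=t.empty_blocklist(), lam=0.0,
                          standardize=False)
        edges = res.edges()
        assert len(edges) == 1
        u, v, w = edges[0]
        x = df[u] - df[u].mean()
        y = df[v] - df[v].mean()
        ols = float((x @ y) / (x @ x))
        assert w == pytest.approx(ols, abs=1e-8)

    def test_monotone_descent_per_sweep(self, rng):
        model_true = t.structure_recovery_model()
        c = t.simulate_cohort(model_true, 400, seed=17)
        gm = t.GaussianDAGModel(c.analysis_frame("fasting"), model_true.meta)
        trace = []
        gm.fit(4.0, debug_score_trace=trace)
        assert all(b <= a + 1e-7 for a, b in zip(trace, trace[1:]))

    def test_score_not_above_init(self, rng):
        model_true = t.structure_recovery_model()
        c = t.simulate_cohort(model_true, 400, seed=23)
        gm = t.GaussianDAGModel(c.analysis_frame("fasting"), model_true.meta)
        coarse = gm.fit(9.0)
        refit = gm.fit(4.0, init=coarse)
        init_score = penalized_score(coarse.B, gm.X, 4.0, gm.penalty, gm.gamma)
        assert refit.score <= init_score + 1e-6

    def test_nonfinite_data_rejected(self):
        df = pd.DataFrame({"x0": [1.0, np.nan, 2.0], "x1": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="finite"):
            t.GaussianDAGModel(df, _mm_meta(2))

    def test_exhaustive_oracle_small(self, rng):
        # spot check (5 seeds) of the full 20-seed acceptance benchmark
        dags = all_dags(3)
        meta = _mm_meta(3)
        for seed in range(5):
            srng = np.random.default_rng(900 + seed)
            n = 400
            B = np.zeros((3, 3))
            B[0, 1] = 0.8
            B[1, 2] = -0.8
            X = np.zeros((n, 3))
            for j in range(3):
                X[:, j] = X @ B[:, j] + srng.normal(size=n)
            df = pd.DataFrame(X, columns=[m.node_id for m in meta])
            model = t.GaussianDAGModel(df, meta, blocklist=t.empty_blocklist())
            res = model.fit(6.0)
            oracle = exhaustive_best_score(model.X, 6.0, dags=dags)
            assert res.score <= oracle + 1e-6 * (1 + abs(oracle))
            assert res.score >= oracle - 1e-6 * (1 + abs(oracle))

    def test_l1_penalty_also_supported(self, rng):
        model_true = t.structure_recovery_model()
        c = t.simulate_cohort(model_true, 600, seed=2)
        res = t.learn_dag(c.analysis_frame("fasting"), model_true.meta,
                          lam=8.0, penalty="l1")
        res.validate(t.build_blocklist(model_true.meta))
        assert res.n_edges > 0


@pytest.fixture(scope="module")
def fixture_path():
    model_true = t.structure_recovery_model()
    c = t.simulate_cohort(model_true, 800, seed=31)
    gm = t.GaussianDAGModel(c.analysis_frame("fasting"), model_true.meta)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model_true, gm, gm.fit_path(range(15, 0, -1))


class TestSolutionPath:
    def test_endpoint_sparsity_ordering(self, fixture_path):
        _, _, path = fixture_path
        counts = path.edge_counts()
        assert counts[15.0] <= counts[1.0]

    def test_single_lambda_path_matches_learn_dag(self, rng):
        model_true = t.structure_recovery_model()
        c = t.simulate_cohort(model_true, 500, seed=3)
        gm = t.GaussianDAGModel(c.analysis_frame("fasting"), model_true.meta)
        path = gm.fit_path([7.0])
        direct = gm.fit(7.0)
        assert path.models[7.0].edges() == direct.edges()

    def test_every_model_valid(self, fixture_path):
        model_true, gm, path = fixture_path
        bl = t.build_blocklist(model_true.meta)
        for lam in path.lambdas:
            path.models[lam].validate(bl)

    def test_nondecreasing_lambdas_rejected(self, rng):
        model_true = t.structure_recovery_model()
        c = t.simulate_cohort(model_true, 300, seed=4)
        gm = t.GaussianDAGModel(c.analysis_frame("fasting"), model_true.meta)
        with pytest.raises(ValueError):
            gm.fit_path([3.0, 3.0])

    def test_summary_frame_counts_touched_nodes(self, fixture_path):
        _, _, path = fixture_path
        df = path.summary_frame()
        assert set(df.columns) == {"lambda", "n_edges", "n_nodes_with_edges"}
        row15 = df[df["lambda"] == 15.0].iloc[0]
        assert row15["n_nodes_with_edges"] <= 12


class TestConstraintInvariants:
    def test_random_inputs_acyclic_and_blocklist_clean(self, rng):
        # 15 randomized instances here; the acceptance suite runs 100
        for trial in range(15):
            trng = np.random.default_rng(5000 + trial)
            meta = random_typed_meta(trng, 8)
            edges = random_typed_dag_edges(trng, meta)
            n = 150
            cols = {m.node_id: trng.normal(size=n) for m in meta}
            for u, v in edges:
                cols[v] = cols[v] + 0.7 * cols[u]
            df = pd.DataFrame(cols)
            lam = float(trng.uniform(1, 10))
            res = t.learn_dag(df, meta, lam=lam)
            res.validate(t.build_blocklist(meta))  # raises on violation

    def test_cross_chromosome_rule_enforced(self, rng):
        # two perfectly correlated SNPs on different chromosomes must not connect
        meta = [
            t.NodeMeta("s1", "MG", chromosome="1"),
            t.NodeMeta("s2", "MG", chromosome="2"),
        ]
        g = rng.binomial(2, 0.4, 300).astype(float)
        df = pd.DataFrame({"s1": g, "s2": g + rng.normal(0, 0.05, 300)})
        res = t.learn_dag(df, meta, lam=1.0)
        assert res.n_edges == 0


def test_structural_hamming_distance_counts():
    a = [("a", "b"), ("b", "c")]
    assert t.structural_hamming_distance(a, a) == 0
    assert t.structural_hamming_distance(a, [("b", "a"), ("b", "c")]) == 1  # reversal
    assert t.structural_hamming_distance(a, [("a", "b")]) == 1  # deletion
    assert t.structural_hamming_distance(a, a + [("a", "c")]) == 1  # addition
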