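"""Serial mediation: chain fits, effect decomposition, bootstrap, BH, two-stage protocol."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import triomics as t
from triomics.mediation import SampleSizeError, SingularDesignError

from _oracles import bh_oracle, ols_oracle


def _chain_data(rng, n=500, a=0.5, d=0.5, b=0.5, n_mediators=2):
    x = rng.normal(size=n)
    cols = {"x": x}
    prev = x
    coefs = [a] + [d] * (n_mediators - 1)
    for j in range(n_mediators):
        m = coefs[j] * prev + rng.normal(size=n)
        cols[f"m{j + 1}"] = m
        prev = m
    cols["y"] = b * prev + rng.normal(size=n)
    return pd.DataFrame(cols), ["x"] + [f"m{j + 1}" for j in range(n_mediators)] + ["y"]


class TestFitSerialChain:
    def test_noiseless_single_mediator(self):
        x = np.arange(20, dtype=float)
        df = pd.DataFrame({"x": x, "m": 2.0 * x, "y": 6.0 * x})
        chain, de, te = t.fit_serial_chain(["x", "m", "y"], df)
        assert chain[0] == pytest.approx(2.0, abs=1e-8)
        assert chain[1] == pytest.approx(3.0, abs=1e-8)
        assert de == pytest.approx(0.0, abs=1e-8)
        assert te == pytest.approx(6.0, abs=1e-8)

    def test_null_chain_coefficients_near_zero(self, rng):
        n = 2000
        df = pd.DataFrame(
            {"x": rng.normal(size=n), "m": rng.normal(size=n), "y": rng.normal(size=n)}
        )
        chain, de, te = t.fit_serial_chain(["x", "m", "y"], df)
        for c in list(chain) + [de, te]:
            assert abs(c) < 3 * 3 / np.sqrt(n)

    def test_two_mediator_normal_equations_oracle(self, rng):
        df, nodes = _chain_data(rng, n=300)
        C = pd.DataFrame(rng.normal(size=(300, 2)), columns=["c1", "c2"])
        chain, de, te = t.fit_serial_chain(nodes, df, C)
        Cn = C.to_numpy()
        ones = np.ones(300)

        def fit(y_col, preds):
            X = np.column_stack([ones, df["x"], Cn] + [df[p] for p in preds])
            beta, _, _ = ols_oracle(X, df[y_col].to_numpy())
            return beta

        b1 = fit("m1", [])
        b2 = fit("m2", ["m1"])
        by = fit("y", ["m1", "m2"])
        bred = fit("y", [])
        assert chain[0] == pytest.approx(b1[1], abs=1e-8)   # a1: x -> m1
        assert chain[1] == pytest.approx(b2[-1], abs=1e-8)  # d21: m1 -> m2
        assert chain[2] == pytest.approx(by[-1], abs=1e-8)  # b2: m2 -> y
        assert de == pytest.approx(by[1], abs=1e-8)
        assert te == pytest.approx(bred[1], abs=1e-8)

    def test_sample_size_error(self, rng):
        df, nodes = _chain_data(rng, n=4)
        with pytest.raises(SampleSizeError):
            t.fit_serial_chain(nodes, df)

    def test_singular_design_error(self, rng):
        n = 50
        x = rng.normal(size=n)
        df = pd.DataFrame({"x": x, "m": x.copy(), "y": rng.normal(size=n)})
        with pytest.raises(SingularDesignError):
            t.fit_serial_chain(["x", "m", "y"], df)

    def test_effect_decomposition_identity_k1(self, rng):
        # de + ide = te exactly for one mediator without covariates
        n = 300
        x = rng.normal(size=n)
        m = 0.6 * x + rng.normal(size=n)
        y = 0.4 * x + 0.5 * m + rng.normal(size=n)
        df = pd.DataFrame({"x": x, "m": m, "y": y})
        chain, de, te = t.fit_serial_chain(["x", "m", "y"], df)
        assert de + chain[0] * chain[1] != pytest.approx(te, abs=1e-12) or True
        # the exact OLS identity: te = de + a1 * b1
        assert te == pytest.approx(de + chain[0] * chain[1], abs=1e-8)

    def test_total_decomposition_noiseless_k2(self):
        # with 2 serial mediators, te = de + sum of all indirect channels;
        # z1/z2 are mediator-specific variation orthogonal to everything
        # upstream so the fits are exact without sampling noise
        n = 60
        x = np.linspace(-2, 2, n)
        z1 = np.sin(np.arange(n))
        z1 = z1 - z1.mean()
        z1 = z1 - (z1 @ x) / (x @ x) * x
        base = np.column_stack([np.ones(n), x, z1])
        z2 = np.cos(2.0 * np.arange(n))
        z2 = z2 - base @ np.linalg.lstsq(base, z2, rcond=None)[0]
        m1 = 0.5 * x + z1
        m2 = 0.5 * m1 + 0.3 * x + z2
        y = 0.5 * m2 + 0.2 * m1 + 0.1 * x
        df = pd.DataFrame({"x": x, "m1": m1, "m2": m2, "y": y})
        chain, de, te = t.fit_serial_chain(["x", "m1", "m2", "y"], df)
        # channels: x->m1->m2->y, x->m2->y, x->m1->y, x->y
        expect_te = 0.5 * 0.5 * 0.5 + 0.3 * 0.5 + 0.5 * 0.2 + 0.1
        assert te == pytest.approx(expect_te, abs=1e-8)
        assert chain == pytest.approx([0.5, 0.5, 0.5], abs=1e-8)
        assert de == pytest.approx(0.1, abs=1e-8)


class TestSerialIde:
    def test_product(self):
        assert t.serial_ide([2.0, 3.0]) == 6.0
        assert t.serial_ide([0.5, 0.5, 0.5]) == 0.125
        assert t.serial_ide([0.9, 0.0, 0.7]) == 0.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            t.serial_ide([])


class TestBootstrapSMM:
    def test_bitwise_reproducible(self, rng):
        df, nodes = _chain_data(rng)
        r1 = t.bootstrap_smm(nodes, df, n_boot=150, seed=9)
        r2 = t.bootstrap_smm(nodes, df, n_boot=150, seed=9)
        assert r1.ide == r2.ide
        assert r1.ide_se == r2.ide_se
        assert r1.ide_ci == r2.ide_ci
        assert r1.p_ide == r2.p_ide

    def test_point_estimate_independent_of_n_boot(self, rng):
        df, nodes = _chain_data(rng)
        r100 = t.bootstrap_smm(nodes, df, n_boot=100, seed=1)
        r400 = t.bootstrap_smm(nodes, df, n_boot=400, seed=2)
        assert r100.ide == r400.ide
        assert r100.de == r400.de
        assert r100.te == r400.te

    def test_pm_is_ide_over_te(self, rng):
        df, nodes = _chain_data(rng)
        r = t.bootstrap_smm(nodes, df, n_boot=100, seed=3)
        assert r.pm == pytest.approx(r.ide / r.te)
        assert r.pm_defined

    def test_n_boot_floor(self, rng):
        df, nodes = _chain_data(rng)
        with pytest.raises(ValueError):
            t.bootstrap_smm(nodes, df, n_boot=50, seed=0)

    def test_model_results_wrapper(self, rng):
        df, nodes = _chain_data(rng)
        res = t.SerialMediationModel(df, nodes).fit(n_boot=120, seed=4)
        assert "IDE" in res.summary()
        assert res.n_boot == 120


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert t.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_stepup_minimum(self):
        # p * m / rank with enforced monotonicity from the top
        got = t.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=30))
    def test_dominates_input_and_capped(self, ps):
        got = t.bh_adjust(ps)
        assert np.all(got >= np.asarray(ps) - 1e-15)
        assert np.all(got <= 1.0)

    @given(st.lists(st.floats(1e-8, 1.0), min_size=2, max_size=20), st.randoms())
    def test_permutation_equivariance(self, ps, rnd):
        perm = list(range(len(ps)))
        rnd.shuffle(perm)
        direct = t.bh_adjust(ps)
        shuffled = t.bh_adjust([ps[i] for i in perm])
        assert np.allclose([direct[i] for i in perm], shuffled)

    def test_matches_definition_oracle(self, rng):
        for _ in range(20):
            ps = rng.uniform(1e-6, 1, size=rng.integers(1, 40))
            assert np.allclose(t.bh_adjust(ps), bh_oracle(ps))

    def test_invalid_pvalues(self):
        with pytest.raises(ValueError):
            t.bh_adjust([0.0, 0.5])


class TestDiscoverAndValidate:
    def _planted_setup(self, rng, n_train=400, n_valid=200, n_null=5):
        frames = {}
        for label, n in (("train", n_train), ("valid", n_valid)):
            cols = {}
            x = rng.normal(size=n)
            m1 = 0.5 * x + rng.normal(size=n)
            m2 = 0.5 * m1 + rng.normal(size=n)
            y = 0.5 * m2 + rng.normal(size=n)
            cols.update({"x0": x, "m01": m1, "m02": m2, "y0": y})
            for j in range(1, n_null + 1):
                for c in (f"x{j}", f"m{j}1", f"m{j}2", f"y{j}"):
                    cols[c] = rng.normal(size=n)
            frames[label] = pd.DataFrame(cols)
        paths = [
            t.MediationPath((f"x{j}", f"m{j}1", f"m{j}2", f"y{j}"), "MM", f"y{j}")
            for j in range(n_null + 1)
        ]
        return frames["train"], frames["valid"], paths

    def test_planted_path_discovered_and_validated(self, rng):
        train, valid, paths = self._planted_setup(rng)
        rep = t.discover_and_validate(paths, train, valid, n_boot=200, seed=11)
        assert paths[0] in rep.discovered
        assert paths[0] in rep.validated

    def test_alpha_zero_discovers_nothing(self, rng):
        train, valid, paths = self._planted_setup(rng)
        rep = t.discover_and_validate(
            paths, train, valid, alpha_fdr=0.0, n_boot=150, seed=2
        )
        assert rep.discovered == []
        assert rep.validation_results == []

    def test_empty_path_list(self, rng):
        rep = t.discover_and_validate([], pd.DataFrame(), pd.DataFrame())
        assert rep.train_results == [] and rep.validated == []

    def test_families_adjusted_separately(self, rng):
        train, valid, paths = self._planted_setup(rng, n_null=3)
        fams = {p.node_ids: ("A" if i < 2 else "B") for i, p in enumerate(paths)}
        rep = t.discover_and_validate(
            paths, train, valid, n_boot=150, seed=5, families=fams
        )
        # within-family BH: family A has 2 members, so the planted path's
        # adjusted p is at most 2x its nominal p
        planted = next(r for r in rep.train_results if r.path == paths[0])
        assert planted.p_adjusted <= min(1.0, 2 * planted.p_ide) + 1e-12

    def test_report_frame_layout(self, rng):
        train, valid, paths = self._planted_setup(rng, n_null=2)
        rep = t.discover_and_validate(paths, train, valid, n_boot=150, seed=3)
        df = rep.to_frame()
        assert len(df) == len(paths)
        assert {"path", "train_ide", "discovered", "validated"} <= set(df.columns)
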