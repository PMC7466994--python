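"""Mixed-model association scan: REML, GLS oracles, q-values, stepwise."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from poolgp import (
    fit_null_mm,
    prune_by_correlation,
    qvalues,
    run_gwas,
    significant,
    stepwise_model,
    variance_explained,
)
from poolgp.gwas import _restricted_loglik

from conftest import toy_matrix


@pytest.fixture(scope="module")
def gwas_fixture(small_imputed, small_G, small_trait):
    from poolgp.phenostats import adjusted_means, fit_model2

    records, truth = small_trait
    y = adjusted_means(fit_model2(records, "sim_trait")).values
    return small_imputed, small_G, y.reindex(small_imputed.pop_ids).to_numpy(), truth


class TestNullReml:
    def test_variance_ratio_recovery(self):
        """y simulated with sigma_g2 = sigma_e2 = 1 on a simulated G (n=200):
        the central tendency of delta-hat over 20 seeds sits in [0.5, 2]."""
        from poolgp import generate_panel, kinship, simulate_frequencies

        panel = generate_panel(200, seed=55)
        freqs = simulate_frequencies(panel, n_scaffolds=50, markers_per_scaffold=10, seed=56)
        G = kinship(freqs)
        rng = np.random.default_rng(0)
        lam, U = np.linalg.eigh(G.G)
        lam = np.clip(lam, 0, None)
        deltas = []
        for _ in range(20):
            u = U @ (np.sqrt(lam) * rng.standard_normal(G.n))
            y = 2.0 + u + rng.standard_normal(G.n)
            deltas.append(fit_null_mm(y, G).delta)
        gm = np.exp(np.mean(np.log(deltas)))
        assert 0.5 < gm < 2.0

    def test_identity_G_degeneracy(self):
        """G = I: only sigma_g2 + sigma_e2 is identified; the sum must match
        the REML variance estimate of an intercept-only model."""
        rng = np.random.default_rng(1)
        y = rng.normal(3.0, 2.0, size=80)
        fit = fit_null_mm(y, np.eye(80))
        total = fit.sigma_g2 + fit.sigma_e2
        assert total == pytest.approx(np.var(y, ddof=1), rel=1e-6)

    def test_delta_is_grid_global_max(self, gwas_fixture):
        freqs, G, y, _ = gwas_fixture
        fit = fit_null_mm(y, G)
        # recompute the restricted spectrum exactly as the fit does
        n = y.size
        X = np.ones((n, 1))
        Q, _ = np.linalg.qr(X)
        S = np.eye(n) - Q @ Q.T
        SGS = S @ G.G @ S
        xi_all, V = np.linalg.eigh(0.5 * (SGS + SGS.T))
        order = np.argsort(xi_all)[::-1][: n - 1]
        xi = np.clip(xi_all[order], 0, None)
        eta2 = (V[:, order].T @ y) ** 2
        ll_hat = _restricted_loglik(fit.delta, xi, eta2)
        grid = np.logspace(-5, 5, 1000)
        ll_grid = np.array([_restricted_loglik(d, xi, eta2) for d in grid])
        assert ll_hat >= ll_grid.max() - 1e-4

    def test_non_psd_rejected(self):
        G = np.diag([1.0, 1.0, -0.5, 1.0, 1.0])
        with pytest.raises(ValueError, match="PSD"):
            fit_null_mm(np.arange(5.0), G)


class TestRunGwas:
    def test_perfect_fit_marker(self, small_imputed):
        x = small_imputed.values[:, 7]
        y = 2.5 * x + 1.0
        res = run_gwas(y, small_imputed, model="naive")
        row = res.table.iloc[7]
        assert row["r2_ols"] == pytest.approx(1.0, abs=1e-10)
        assert row["p"] < 1e-30
        assert row["beta"] == pytest.approx(2.5, abs=1e-8)

    def test_kinship_p_matches_dense_gls_oracle(self, small_imputed, small_G):
        """P3D p-values equal an explicit H^{-1} GLS solve (30 x 100, 1e-8)."""
        sub = small_imputed.subset_pops(small_imputed.pop_ids[:30]).subset_markers(
            small_imputed.marker_ids[:100]
        )
        from poolgp.grm import kinship

        G = kinship(small_imputed.subset_pops(small_imputed.pop_ids[:30]))
        rng = np.random.default_rng(2)
        y = sub.values[:, 3] * 2 + rng.normal(0, 0.3, 30)
        res = run_gwas(y, sub, model="kinship", G=G)

        H = res.sigma_g2 * G.G + res.sigma_e2 * np.eye(30)
        Hinv = np.linalg.inv(H)
        for j in range(0, 100, 7):
            X = np.column_stack([np.ones(30), sub.values[:, j]])
            XtHiX = X.T @ Hinv @ X
            beta = np.linalg.solve(XtHiX, X.T @ Hinv @ y)
            r = y - X @ beta
            df = 30 - 2
            s2 = float(r @ Hinv @ r) / df
            se = np.sqrt(s2 * np.linalg.inv(XtHiX)[1, 1])
            t = beta[1] / se
            p_oracle = 2 * stats.t.sf(abs(t), df)
            assert res.table["p"].iloc[j] == pytest.approx(p_oracle, abs=1e-8)
            assert res.table["beta"].iloc[j] == pytest.approx(beta[1], abs=1e-8)

    def test_gls_reduces_to_ols_when_no_genetic_variance(self, small_imputed):
        """H proportional to I reproduces the naive scan exactly."""
        rng = np.random.default_rng(3)
        y = rng.normal(size=small_imputed.n_pops)  # pure noise, delta -> large
        naive = run_gwas(y, small_imputed, model="naive")
        from poolgp.grm import KinshipMatrix

        G_eye = KinshipMatrix(list(small_imputed.pop_ids), np.eye(small_imputed.n_pops), 1.0)
        kin = run_gwas(y, small_imputed, model="kinship", G=G_eye)
        np.testing.assert_allclose(kin.table["p"], naive.table["p"], atol=1e-10)
        np.testing.assert_allclose(kin.table["beta"], naive.table["beta"], atol=1e-10)

    def test_structure_model_uses_cluster_dummies(self, small_panel, small_imputed):
        """A trait driven by geographic group membership inflates the naive
        scan (frequencies share the geography); cluster dummies absorb it."""
        rng = np.random.default_rng(4)
        clusters = (small_panel.lat > np.median(small_panel.lat)).astype(int).astype(str)
        shift = np.where(clusters == "1", 5.0, 0.0)
        y = shift + rng.normal(0, 0.5, small_imputed.n_pops)
        naive = run_gwas(y, small_imputed, model="naive")
        struct = run_gwas(y, small_imputed, model="structure", clusters=clusters)
        assert np.median(struct.table["p"]) > np.median(naive.table["p"])

    def test_p3d_and_exact_agree_in_rank(self, small_imputed, small_G, gwas_fixture):
        _, _, y, _ = gwas_fixture
        sub = small_imputed.subset_pops(small_imputed.pop_ids[:30]).subset_markers(
            small_imputed.marker_ids[:200]
        )
        from poolgp.grm import kinship

        G = kinship(small_imputed.subset_pops(small_imputed.pop_ids[:30]))
        y30 = y[:30]
        p3d = run_gwas(y30, sub, model="kinship", G=G, p3d=True)
        exact = run_gwas(y30, sub, model="kinship", G=G, p3d=False)
        rho = stats.spearmanr(p3d.table["p"], exact.table["p"]).statistic
        assert rho > 0.99

    def test_constant_marker_flagged(self):
        values = np.column_stack([np.full(12, 0.5), np.linspace(0.1, 0.9, 12)])
        freqs = toy_matrix(values)
        y = np.linspace(0, 1, 12)
        res = run_gwas(y, freqs, model="naive")
        assert bool(res.table["flagged"].iloc[0])
        assert res.table["p"].iloc[0] == 1.0
        assert res.table["beta"].iloc[0] == 0.0


class TestQvalues:
    def test_hand_bh_example(self):
        np.testing.assert_allclose(qvalues(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        np.testing.assert_array_equal(qvalues(np.ones(5)), np.ones(5))

    def test_matches_definition_oracle(self):
        """q_i = min over {j : p_j >= p_i} of p_j * m / rank_j."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            m = int(rng.integers(1, 40))
            p = rng.uniform(size=m)
            q = qvalues(p)
            order = np.argsort(p)
            ranks = np.empty(m, dtype=int)
            ranks[order] = np.arange(1, m + 1)
            oracle = np.array(
                [min(min(p[j] * m / ranks[j] for j in range(m) if p[j] >= p[i]), 1.0) for i in range(m)]
            )
            np.testing.assert_allclose(q, oracle, atol=1e-12)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=50)
        q = qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all()


class TestSignificant:
    def test_thresholds(self, small_imputed):
        rng = np.random.default_rng(7)
        y = rng.normal(size=small_imputed.n_pops)
        res = run_gwas(y, small_imputed, model="naive")
        res.table["q"] = 1.0
        assert significant(res, q_max=0.10) == []
        res.table["q"] = 0.0
        assert len(significant(res, q_max=0.10)) == small_imputed.n_markers


class TestVarianceExplained:
    def test_perfect_marker(self, small_imputed):
        x = small_imputed.values[:, 5]
        r2_ols, _ = variance_explained(x.copy(), x)
        assert r2_ols == pytest.approx(1.0)

    def test_identity_limit_recovers_ols(self, small_imputed):
        """With G = I the whitened partial R^2 equals the plain R^2."""
        rng = np.random.default_rng(8)
        y = small_imputed.values[:, 5] + rng.normal(0, 0.1, small_imputed.n_pops)
        from poolgp.grm import KinshipMatrix

        G_eye = KinshipMatrix(list(small_imputed.pop_ids), np.eye(small_imputed.n_pops), 1.0)
        r2_ols, r2_kin = variance_explained(y, small_imputed.values[:, 5], G=G_eye)
        assert r2_kin == pytest.approx(r2_ols, abs=1e-6)

    def test_kinship_discounts_structure_tracking_markers(self, small_imputed, small_G, gwas_fixture):
        """Markers that track overall structure explain less once kinship is
        accounted for (the red-vs-green bar contrast)."""
        _, _, y, _ = gwas_fixture
        from poolgp.gwas import fit_null_mm

        null = fit_null_mm(y, small_G)
        # markers most correlated with the leading kinship eigenvector
        lead = small_G.eigvec if hasattr(small_G, "eigvec") else np.linalg.eigh(small_G.G)[1][:, -1]
        corr = np.abs(
            np.corrcoef(small_imputed.values.T, lead)[:-1, -1]
        )
        top = np.argsort(corr)[-20:]
        worse = 0
        for j in top:
            r2_ols, r2_kin = variance_explained(y, small_imputed.values[:, j], null_fit=null)
            worse += r2_kin <= r2_ols + 1e-9
        assert worse >= 15  # structure-confounded markers lose explanatory power

    def test_constant_marker(self, small_imputed):
        y = np.linspace(0, 1, small_imputed.n_pops)
        assert variance_explained(y, np.full(small_imputed.n_pops, 0.3)) == (0.0, 0.0)


class TestPrune:
    def test_single_marker(self, small_imputed):
        count, subset = prune_by_correlation([small_imputed.marker_ids[0]], small_imputed, 0.1)
        assert count == 1 and subset == [small_imputed.marker_ids[0]]

    def test_duplicated_pair_never_unlinked(self):
        rng = np.random.default_rng(9)
        col = rng.uniform(0.1, 0.9, 15)
        freqs = toy_matrix(np.column_stack([col, col]))
        count, subset = prune_by_correlation(["m0", "m1"], freqs, 1.0)
        assert count == 0 and subset == []

    def test_matches_double_loop_oracle(self, small_imputed):
        markers = small_imputed.marker_ids[:50]
        for t in (0.9, 0.5, 0.1):
            count, subset = prune_by_correlation(markers, small_imputed, t)
            oracle = []
            for a in markers:
                xa = small_imputed.values[:, small_imputed.marker_ids.index(a)]
                linked = False
                for b in markers:
                    if a == b:
                        continue
                    xb = small_imputed.values[:, small_imputed.marker_ids.index(b)]
                    if abs(np.corrcoef(xa, xb)[0, 1]) >= t:
                        linked = True
                        break
                if not linked:
                    oracle.append(a)
            assert subset == oracle and count == len(oracle)


class TestStepwise:
    def test_single_marker_model(self, small_imputed):
        rng = np.random.default_rng(10)
        x = small_imputed.values[:, 3]
        y = 2 * x + rng.normal(0, 0.2, small_imputed.n_pops)
        model = stepwise_model(y, [small_imputed.marker_ids[3]], small_imputed)
        assert model.markers == [small_imputed.marker_ids[3]]
        assert model.r2 == pytest.approx(np.corrcoef(y, x)[0, 1] ** 2, abs=1e-10)

    def test_duplicate_never_reenters(self):
        rng = np.random.default_rng(11)
        col = rng.uniform(0.1, 0.9, 30)
        freqs = toy_matrix(np.column_stack([col, col]))
        y = 3 * col + rng.normal(0, 0.1, 30)
        model = stepwise_model(y, ["m0", "m1"], freqs)
        assert model.markers == ["m0"]

    def test_two_independent_qtl_both_enter(self):
        rng = np.random.default_rng(12)
        x1 = rng.uniform(0.1, 0.9, 60)
        x2 = rng.uniform(0.1, 0.9, 60)
        freqs = toy_matrix(np.column_stack([x1, x2]))
        y = 2 * x1 + 2 * x2 + rng.normal(0, 0.1, 60)
        model = stepwise_model(y, ["m0", "m1"], freqs)
        assert set(model.markers) == {"m0", "m1"}
        r2_single = max(np.corrcoef(y, x1)[0, 1] ** 2, np.corrcoef(y, x2)[0, 1] ** 2)
        assert model.r2 > r2_single
        assert (np.diff(model.r2_path) >= -1e-12).all()
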