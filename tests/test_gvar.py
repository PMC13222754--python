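"""Panel GVAR: Lyapunov solver, implied covariance, ML fit, pruning,
fit indices, bootstrap stability, standardization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelnet import gvar as gv
from panelnet.gvar import (NODES, BootstrapSummary, GVARError, Pattern,
                           bootstrap_edges, fit_indices, fit_panel_gvar,
                           implied_covariance, prune, stable_network,
                           stationary_within_cov, temporal_std)
from panelnet.synthetic import benchmark_truth, simulate_panel


def random_stable_system(rng, p):
    B = rng.normal(size=(p, p)) * 0.2
    rho = np.max(np.abs(np.linalg.eigvals(B)))
    if rho > 0.7:
        B *= 0.6 / rho
    A = rng.normal(size=(p, p)) * 0.3
    Q = A @ A.T + np.eye(p) * 0.5
    return B, Q


def lyap_series(B, Q, k=200):
    S = np.zeros_like(Q)
    Bk = np.eye(B.shape[0])
    for _ in range(k + 1):
        S += Bk @ Q @ Bk.T
        Bk = B @ Bk
    return S


class TestStationaryCov:
    def test_zero_temporal_matrix(self, rng):
        Q = np.diag([1.0, 2.0, 3.0])
        assert np.allclose(stationary_within_cov(np.zeros((3, 3)), Q), Q)

    def test_scalar_ar1_closed_form(self):
        S = stationary_within_cov(np.array([[0.5]]), np.array([[1.0]]))
        assert S[0, 0] == pytest.approx(4 / 3)

    def test_matches_truncated_series(self, rng):
        B, Q = random_stable_system(rng, 4)
        S = stationary_within_cov(B, Q)
        assert np.abs(S - lyap_series(B, Q)).max() < 1e-8

    def test_matches_scipy_reference(self, rng):
        from scipy.linalg import solve_discrete_lyapunov
        B, Q = random_stable_system(rng, 5)
        assert np.allclose(stationary_within_cov(B, Q),
                           solve_discrete_lyapunov(B, Q), atol=1e-10)

    def test_nonstationary_rejected(self):
        with pytest.raises(GVARError, match="non-stationary"):
            stationary_within_cov(np.eye(2) * 1.01, np.eye(2))


class TestImpliedCovariance:
    def test_no_dynamics_no_trait_is_block_diagonal(self):
        par = gv.GVARParameters(list("abc"), np.zeros((3, 3)),
                                np.zeros((3, 3)), np.ones(3) * 0.9,
                                np.zeros((3, 3)), np.full(3, 1e-6))
        Sig = implied_covariance(par, 3)
        Sz = par.sigma_zeta
        off = Sig.copy()
        for t in range(3):
            blk = Sig[t * 3:(t + 1) * 3, t * 3:(t + 1) * 3]
            assert np.allclose(blk, Sz, atol=1e-9)
            off[t * 3:(t + 1) * 3, t * 3:(t + 1) * 3] = 0
        assert np.abs(off).max() < 1e-10

    def test_pure_trait_model(self):
        # B = 0, between component only: every off-wave block = Sigma_b
        par = gv.GVARParameters(list("ab"), np.zeros((2, 2)),
                                np.zeros((2, 2)), np.ones(2),
                                np.zeros((2, 2)), np.ones(2) * 0.8)
        Sig = implied_covariance(par, 3)
        Sb = par.sigma_b
        assert np.allclose(Sig[2:4, 0:2], Sb)
        assert np.allclose(Sig[4:6, 0:2], Sb)

    def test_generator_round_trip(self, benchmark_panel):
        panel, truth = benchmark_panel
        gt = truth.groups["G1"]
        Sig = implied_covariance(gt.params(), 3)
        sc = panel.scores[panel.scores.group == "G1"]
        S = np.cov(gv.scores_to_wide(sc), rowvar=False)
        assert np.abs(Sig - S).max() < 0.12  # n = 1000 sampling error

    @given(st.integers(0, 10000))
    @settings(max_examples=25)
    def test_symmetric_pd_over_random_stable_draws(self, seed):
        rng = np.random.default_rng(seed)
        B, Q = random_stable_system(rng, 3)
        from panelnet.gvar import cov_to_network
        oz, dz = cov_to_network(Q)
        A = rng.normal(size=(3, 3)) * 0.3
        ob, db = cov_to_network(A @ A.T + np.eye(3) * 0.3)
        par = gv.GVARParameters(list("abc"), B, oz, dz, ob, db)
        Sig = implied_covariance(par, 3)
        assert np.allclose(Sig, Sig.T)
        assert np.linalg.eigvalsh(Sig)[0] > 0


class TestObjectiveGradient:
    def test_analytic_gradient_matches_finite_differences(self, rng):
        from scipy.optimize import approx_fprime
        truth = benchmark_truth({"G1": 300, "G2": 60, "G3": 60}, seed=1)
        panel = simulate_panel(truth, seed=2, clip=False)
        sc = panel.scores[panel.scores.group == "G1"]
        Y = gv.scores_to_wide(sc)
        S = np.cov(Y, rowvar=False)
        pat = Pattern.saturated(6)
        theta = gv._pack(truth.groups["G1"].params(), pat)
        theta = theta + rng.normal(size=len(theta)) * 0.02
        F, g = gv._objective_grad(theta, S, pat, 6, 3, NODES)
        f = lambda th: gv._objective_grad(th, S, pat, 6, 3, NODES,
                                          want_grad=False)[0]
        g_num = approx_fprime(theta, f, 1e-7)
        assert np.abs(g - g_num).max() / np.abs(g_num).max() < 1e-4


class TestFit:
    def test_recovery_and_loglik_improves(self, benchmark_panel):
        panel, truth = benchmark_panel
        gt = truth.groups["G1"]
        sc = panel.scores[panel.scores.group == "G1"]
        fit = fit_panel_gvar(sc)
        assert np.abs(fit.params.beta - gt.beta).mean() < 0.05
        par = gt.params()
        assert np.abs(fit.params.omega_zeta - par.omega_zeta).mean() < 0.05
        # optimizer contract: optimum at least as good as the truth values
        pat = Pattern.saturated(6)
        S = fit.sample_cov
        F_truth = gv._objective_grad(gv._pack(par, pat), S, pat, 6, 3,
                                     NODES, want_grad=False)[0]
        _, logdetS = np.linalg.slogdet(S)
        assert fit.discrepancy <= F_truth - logdetS - 18 + 1e-9

    def test_self_consistency_on_own_parameters(self, g1_fit):
        # simulate from the fitted model, refit at large n, re-estimate
        from panelnet.synthetic import GroupTruth, StudyTruth
        p = g1_fit.params
        gt = GroupTruth(p.beta, p.sigma_zeta, p.sigma_b,
                        np.zeros(6), 50000)
        truth = StudyTruth(groups={"G1": gt, "G2": GroupTruth(
            p.beta, p.sigma_zeta, p.sigma_b, np.zeros(6), 50),
            "G3": GroupTruth(p.beta, p.sigma_zeta, p.sigma_b,
                             np.zeros(6), 50)}, scenario="self")
        panel = simulate_panel(truth, seed=9, clip=False)
        sc = panel.scores[panel.scores.group == "G1"]
        refit = fit_panel_gvar(sc, compute_se=False)
        assert np.abs(refit.params.beta - p.beta).mean() < 0.02
        assert np.abs(refit.params.omega_zeta - p.omega_zeta).mean() < 0.02

    def test_pooled_lag_structure_by_construction(self, g1_fit):
        # stationarity: one temporal matrix serves both wave transitions
        Sig = implied_covariance(g1_fit.params, 3)
        S0 = stationary_within_cov(g1_fit.params.beta,
                                   g1_fit.params.sigma_zeta)
        Sb = g1_fit.params.sigma_b
        lag1a = Sig[6:12, 0:6] - Sb
        lag1b = Sig[12:18, 6:12] - Sb
        assert np.allclose(lag1a, lag1b, atol=1e-12)

    def test_too_few_cases_rejected(self, shared_panel):
        panel, _ = shared_panel
        sc = panel.scores[panel.scores.group == "G1"].head(60)
        with pytest.raises(GVARError):
            fit_panel_gvar(sc)

    def test_fiml_agrees_with_complete_case_when_complete(self,
                                                          benchmark_panel):
        panel, truth = benchmark_panel
        sc = panel.scores[panel.scores.group == "G1"].iloc[:900]
        cc = fit_panel_gvar(sc, compute_se=False)
        with pytest.warns(UserWarning, match="slower"):
            fi = fit_panel_gvar(sc, missing="fiml", compute_se=False)
        # both estimate the same optimum; small O(1/n) divisor differences
        assert np.abs(cc.params.beta - fi.params.beta).max() < 0.03


class TestPrune:
    def test_alpha_one_prunes_nothing(self, g1_fit):
        pruned = prune(g1_fit, alpha=1.0 + 1e-9)
        assert pruned.df == g1_fit.df
        assert np.array_equal(pruned.params.beta, g1_fit.params.beta)

    def test_df_increases_loglik_decreases(self, g1_fit):
        pruned = prune(g1_fit, alpha=0.01)
        assert pruned.df > g1_fit.df
        assert pruned.loglik <= g1_fit.loglik + 1e-6
        # fixed parameters are exactly zero
        assert np.all(pruned.params.beta[~pruned.pattern.free_beta] == 0)


class TestFitIndices:
    def test_saturated_model(self):
        idx = fit_indices(0.0, 0, 1000.0, 60, 1001)
        assert idx["chi2"] == 0.0
        assert idx["cfi"] == 1.0
        assert idx["rmsea"] == 0.0
        assert np.isnan(idx["tli"])  # undefined, flagged

    def test_arithmetic_example(self):
        idx = fit_indices(100.0, 50, 1000.0, 60, 1001)
        assert idx["rmsea"] == pytest.approx(np.sqrt(50 / (50 * 1000)))
        assert idx["rmsea"] == pytest.approx(0.0316, abs=5e-4)
        assert idx["cfi"] == pytest.approx(1 - 50 / 940)
        tli = ((1000 / 60) - (100 / 50)) / ((1000 / 60) - 1)
        assert idx["tli"] == pytest.approx(tli)

    def test_better_than_baseline_floor(self):
        idx = fit_indices(30.0, 50, 1000.0, 60, 500)
        assert idx["rmsea"] == 0.0
        assert idx["cfi"] == 1.0


class TestBootstrapAndStability:
    def test_single_replicate_deterministic(self, shared_panel):
        panel, _ = shared_panel
        sc = panel.scores[panel.scores.group == "G2"]
        a = bootstrap_edges(sc, R=1, seed=42)
        b = bootstrap_edges(sc, R=1, seed=42)
        assert np.array_equal(a.proportions, b.proportions)
        assert a.n_success == 1

    def test_stable_network_boundary_inclusive(self, g1_fit):
        edges = gv.edge_list(NODES)
        props = np.full(len(edges), 0.49)
        props[0] = 0.5    # exactly at the threshold: survives
        props[1] = 0.51
        boots = BootstrapSummary(edges, props, 100, 100, 0)
        masked = stable_network(g1_fit, boots)
        kind0, frm0, to0 = edges[0]
        assert masked.beta[NODES.index(to0), NODES.index(frm0)] == \
            g1_fit.params.beta[NODES.index(to0), NODES.index(frm0)]
        # a below-threshold edge is zeroed
        kind2, frm2, to2 = edges[2]
        assert masked.beta[NODES.index(to2), NODES.index(frm2)] == 0.0

    def test_all_proportions_one_keeps_everything(self, g1_fit):
        edges = gv.edge_list(NODES)
        boots = BootstrapSummary(edges, np.ones(len(edges)), 10, 10, 0)
        masked = stable_network(g1_fit, boots)
        assert np.array_equal(masked.beta, g1_fit.params.beta)

    def test_all_proportions_zero_empties_network(self, g1_fit):
        edges = gv.edge_list(NODES)
        boots = BootstrapSummary(edges, np.zeros(len(edges)), 10, 10, 0)
        masked = stable_network(g1_fit, boots)
        assert np.abs(masked.beta).max() == 0.0
        assert np.abs(masked.omega_zeta).max() == 0.0


class TestTemporalStd:
    def test_zero_matrix(self):
        par = gv.GVARParameters(list("ab"), np.zeros((2, 2)),
                                np.zeros((2, 2)), np.ones(2),
                                np.zeros((2, 2)), np.ones(2))
        assert np.abs(temporal_std(par)).max() == 0.0

    def test_ar1_diagonal_is_autocorrelation(self):
        B = np.diag([0.4, 0.6])
        par = gv.GVARParameters(list("ab"), B, np.zeros((2, 2)),
                                np.array([1.0, 2.0]), np.zeros((2, 2)),
                                np.ones(2))
        assert np.allclose(np.diag(temporal_std(par)), [0.4, 0.6])

    def test_unit_variance_process_equals_raw(self, rng):
        B, Q = random_stable_system(rng, 3)
        S0 = stationary_within_cov(B, Q)
        d = np.sqrt(np.diag(S0))
        # rescale system to unit stationary variances
        Bs = B * np.outer(1 / d, d)
        Qs = Q / np.outer(d, d)
        from panelnet.gvar import cov_to_network
        oz, dz = cov_to_network(Qs)
        par = gv.GVARParameters(list("abc"), Bs, oz, dz, np.zeros((3, 3)),
                                np.ones(3))
        assert np.allclose(temporal_std(par), Bs, atol=1e-6)

    def test_invariant_to_input_units(self, rng):
        B, Q = random_stable_system(rng, 3)
        from panelnet.gvar import cov_to_network
        oz, dz = cov_to_network(Q)
        par = gv.GVARParameters(list("abc"), B, oz, dz, np.zeros((3, 3)),
                                np.ones(3))
        ref = temporal_std(par)
        # rescale node units by c: B' = C B C^-1, Sigma' = C Sigma C
        c = np.array([2.0, 0.5, 3.0])
        B2 = B * np.outer(c, 1 / c)
        Q2 = Q * np.outer(c, c)
        oz2, dz2 = cov_to_network(Q2)
        par2 = gv.GVARParameters(list("abc"), B2, oz2, dz2,
                                 np.zeros((3, 3)), np.ones(3))
        assert np.allclose(temporal_std(par2), ref, atol=1e-10)
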