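"""Spatiotemporal model: structures, posterior density, MCMC, DIC, RR."""

import numpy as np
import pandas as pd
import pytest

import pestmap as pm
from pestmap.panel import PanelCounts
from pestmap.stmodel import (
    STModelSpec,
    STPosterior,
    _Chain,
    icar_structure,
    interaction_structure,
    rw2_structure,
)


def _numerical_rank(Q, tol=1e-8):
    lam = np.linalg.eigvalsh(np.asarray(Q.toarray() if hasattr(Q, "toarray") else Q))
    return int(np.sum(lam > tol * max(lam.max(), 1.0)))


class TestStructures:
    def test_two_node_path_laplacian(self):
        lat = pm.make_lattice(1, 2, 1, seed=0)
        Q = icar_structure(lat).toarray()
        np.testing.assert_array_equal(Q, [[1.0, -1.0], [-1.0, 1.0]])

    def test_icar_rank_and_nullspace(self, grid33):
        Q = icar_structure(grid33)
        assert _numerical_rank(Q) == 8
        np.testing.assert_allclose(Q @ np.ones(9), 0.0, atol=1e-12)

    def test_icar_disconnected_rank(self):
        lat = pm.make_lattice(2, 2, 2, seed=0)
        assert _numerical_rank(icar_structure(lat)) == 8 - 2

    def test_rw2_nullspace(self):
        Q = rw2_structure(4)
        np.testing.assert_allclose(Q @ np.ones(4), 0.0, atol=1e-12)
        np.testing.assert_allclose(Q @ np.arange(4.0), 0.0, atol=1e-12)

    def test_rw2_interior_row(self):
        row = rw2_structure(5).toarray()[2]
        np.testing.assert_array_equal(row, [1.0, -4.0, 6.0, -4.0, 1.0])

    @pytest.mark.parametrize("T", [4, 7, 12, 30])
    def test_rw2_psd_and_rank(self, T):
        Q = rw2_structure(T)
        lam = np.linalg.eigvalsh(Q.toarray())
        assert lam.min() >= -1e-10
        assert _numerical_rank(Q) == T - 2

    def test_rw2_too_short_rejected(self):
        with pytest.raises(ValueError):
            rw2_structure(3)

    def test_interaction_type_i_identity(self):
        lat = pm.make_lattice(2, 2, 1, seed=0)
        Q, rank = interaction_structure(STModelSpec(interaction_type="I"), lat, 3)
        assert rank == 12
        np.testing.assert_array_equal(Q.toarray(), np.eye(12))

    def test_interaction_type_ii_rank(self):
        lat = pm.make_lattice(1, 2, 1, seed=0)
        Q, rank = interaction_structure(STModelSpec(interaction_type="II"), lat, 4)
        assert rank == 2 * (4 - 2)
        assert _numerical_rank(Q) == rank

    def test_interaction_type_iii_rank(self, grid33):
        Q, rank = interaction_structure(
            STModelSpec(interaction_type="III"), grid33, 2
        )
        assert rank == 2 * 8
        assert _numerical_rank(Q) == rank

    def test_interaction_none_rejected(self):
        lat = pm.make_lattice(2, 2, 1, seed=0)
        with pytest.raises(ValueError):
            interaction_structure(STModelSpec(interaction_type="none"), lat, 4)


# --------------------------------------------------------------------------
# independent dense-matrix oracle for the log posterior
# --------------------------------------------------------------------------

def _dense_log_posterior(state, panel, spec, lattice):
    """Independently coded density: dense matrices, explicit loops."""
    n, T = panel.y.shape
    has_delta = spec.interaction_type != "none"
    eta = np.empty((n, T))
    for i in range(n):
        for t in range(T):
            eta[i, t] = (
                state["b0"]
                + state["u"][i]
                + state["v"][i]
                + state["gamma"][t]
                + state["phi"][t]
                + (state["delta"][i, t] if has_delta else 0.0)
            )
    lp = 0.0
    for i in range(n):
        for t in range(T):
            lp += panel.y[i, t] * eta[i, t] - panel.expected[i, t] * np.exp(eta[i, t])
    # graph Laplacian from scratch
    W = lattice.adjacency.toarray()
    Qu = np.diag(W.sum(axis=1)) - W
    # RW2 penalty from scratch (empty below 3 periods)
    D2 = np.zeros((max(T - 2, 0), T))
    for k in range(max(T - 2, 0)):
        D2[k, k : k + 3] = [1.0, -2.0, 1.0]
    Qg = D2.T @ D2
    if spec.interaction_type == "I":
        Qd = np.eye(n * T)
        rank_d = n * T
    elif spec.interaction_type == "II":
        Qd = np.kron(np.eye(n), Qg)
        rank_d = n * max(T - 2, 0)
    elif spec.interaction_type == "III":
        Qd = np.kron(Qu, np.eye(T))
        rank_d = T * (n - lattice.n_components)
    else:
        Qd, rank_d = None, 0
    blocks = [
        ("u", state["u"], Qu, n - lattice.n_components),
        ("v", state["v"], np.eye(n), n),
        ("gamma", state["gamma"], Qg, max(T - 2, 0)),
        ("phi", state["phi"], np.eye(T), T),
    ]
    if Qd is not None:
        blocks.append(("delta", state["delta"].ravel(), Qd, rank_d))
    for name, x, Q, rank in blocks:
        tau = state[f"tau_{name}"]
        a, b = spec.hyperpriors[name]
        lp += 0.5 * rank * np.log(tau) - 0.5 * tau * float(x @ Q @ x)
        lp += (a - 1.0) * np.log(tau) - b * tau
    return lp


class TestLogPosterior:
    @pytest.mark.parametrize("itype", ["I", "II", "III", "none"])
    def test_matches_dense_oracle_on_toy(self, toy_panel, toy_state, itype):
        lattice, panel = toy_panel
        spec = STModelSpec(interaction_type=itype)
        got = pm.log_posterior(toy_state, panel, spec, lattice)
        want = _dense_log_posterior(toy_state, panel, spec, lattice)
        assert got == pytest.approx(want, abs=1e-10)

    def test_zero_state_hand_computation(self, toy_panel):
        lattice, panel = toy_panel
        spec = STModelSpec(interaction_type="none")
        state = {
            "b0": 0.0,
            "u": np.zeros(4), "v": np.zeros(4),
            "gamma": np.zeros(2), "phi": np.zeros(2),
            "tau_u": 1.0, "tau_v": 1.0, "tau_gamma": 1.0, "tau_phi": 1.0,
            "tau_delta": 1.0,
        }
        got = pm.log_posterior(state, panel, spec, lattice)
        # Poisson part is -sum(E); every quadratic is 0; log tau terms are 0;
        # Gamma priors contribute (a-1)*0 - b per precision (a=1, rate b)
        b = 5e-4
        want = -panel.expected.sum() - 4 * b
        assert got == pytest.approx(want, abs=1e-10)

    def test_linearity_in_counts(self, toy_panel, toy_state):
        lattice, panel = toy_panel
        spec = STModelSpec(interaction_type="I")
        doubled = PanelCounts(
            panel.area_ids, panel.periods, 2 * panel.y, panel.population,
            panel.expected,
        )
        lp1 = pm.log_posterior(toy_state, panel, spec, lattice)
        lp2 = pm.log_posterior(toy_state, doubled, spec, lattice)
        eta = (
            toy_state["b0"]
            + toy_state["u"][:, None] + toy_state["v"][:, None]
            + toy_state["gamma"][None, :] + toy_state["phi"][None, :]
            + toy_state["delta"]
        )
        assert lp2 - lp1 == pytest.approx(float(np.sum(panel.y * eta)), rel=1e-12)

    def test_finite_for_finite_state(self, toy_panel, toy_state):
        lattice, panel = toy_panel
        lp = pm.log_posterior(
            toy_state, panel, STModelSpec(interaction_type="II"), lattice
        )
        assert np.isfinite(lp)


class TestConjugatePrecisionUpdate:
    def test_matches_closed_form_gamma_posterior(self, toy_panel):
        # hold the fields fixed; repeated conjugate draws must follow the
        # 1-d closed-form Gamma(a + rank/2, b + x'Qx/2) posterior
        lattice, panel = toy_panel
        spec = STModelSpec(interaction_type="none", n_iter=10, n_burn=5, seed=0)
        chain = _Chain(panel, lattice, spec, seed=123)
        chain.v = np.array([0.5, -0.5, 0.25, -0.25])
        draws = []
        for _ in range(20_000):
            chain._update_precisions()
            draws.append(chain.tau["v"])
        draws = np.asarray(draws)
        a, b = spec.hyperpriors["v"]
        shape = a + 0.5 * 4
        rate = b + 0.5 * float(chain.v @ chain.v)
        assert draws.mean() == pytest.approx(shape / rate, rel=0.03)
        assert draws.var() == pytest.approx(shape / rate**2, rel=0.08)


def _tiny_posterior(delta_draws, y=None, E=None):
    S, n, T = delta_draws.shape
    zeros_s = np.zeros(S)
    return STPosterior(
        spec=STModelSpec(interaction_type="I"),
        area_ids=[f"A{i}" for i in range(n)],
        periods=list(range(T)),
        b0=zeros_s,
        u=np.zeros((S, n)), v=np.zeros((S, n)),
        gamma=np.zeros((S, T)), phi=np.zeros((S, T)),
        delta=delta_draws,
        tau={k: np.ones(S) for k in ("u", "v", "gamma", "phi", "delta")},
        deviance=zeros_s.copy(),
        acceptance={},
        constraint_residuals=zeros_s.copy(),
        seed=0,
    )


class TestDic:
    def _fitted(self, itype="none", seed=0, n_iter=600, n_burn=200):
        lat = pm.make_lattice(3, 3, 1, seed=seed)
        cfg = pm.SimulationConfig(grid_rows=3, grid_cols=3, b0=0.1, seed=seed)
        panel, _ = pm.simulate_panel(lat, cfg, T=6)
        spec = STModelSpec(
            interaction_type=itype, n_iter=n_iter, n_burn=n_burn, seed=seed
        )
        return pm.fit(panel, lat, spec), panel

    def test_degenerate_posterior_zero_pd(self):
        post, panel = self._fitted()
        one = {
            "b0": post.b0[:1], "u": post.u[:1], "v": post.v[:1],
            "gamma": post.gamma[:1], "phi": post.phi[:1],
        }
        rep = STPosterior(
            spec=post.spec, area_ids=post.area_ids, periods=post.periods,
            b0=np.repeat(one["b0"], 50),
            u=np.repeat(one["u"], 50, axis=0),
            v=np.repeat(one["v"], 50, axis=0),
            gamma=np.repeat(one["gamma"], 50, axis=0),
            phi=np.repeat(one["phi"], 50, axis=0),
            delta=None,
            tau={k: np.ones(50) for k in ("u", "v", "gamma", "phi")},
            deviance=np.repeat(post.deviance[:1], 50),
            acceptance={}, constraint_residuals=np.zeros(50), seed=0,
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # p_d may round below zero
            d, p_d, d_bar = pm.dic(rep, panel)
        assert p_d == pytest.approx(0.0, abs=1e-8)
        assert d == pytest.approx(d_bar, abs=1e-8)

    def test_richer_model_fits_no_worse(self):
        post0, panel = self._fitted("none", seed=3, n_iter=1200, n_burn=400)
        post1, _ = self._fitted("I", seed=3, n_iter=1200, n_burn=400)
        _, _, dbar0 = pm.dic(post0, panel)
        _, _, dbar1 = pm.dic(post1, panel)
        assert dbar1 <= dbar0 + 5.0  # within MC error

    def test_recomputation_oracle_from_draws(self):
        from scipy import stats

        post, panel = self._fitted(seed=4)
        d, p_d, d_bar = pm.dic(post, panel)
        # brute force from the stored draw arrays
        eta = post.eta_draws()
        mu = panel.expected[None] * np.exp(eta)
        dev = -2.0 * stats.poisson.logpmf(panel.y[None], mu).sum(axis=(1, 2))
        d_bar2 = dev.mean()
        d_hat2 = -2.0 * stats.poisson.logpmf(
            panel.y, panel.expected * np.exp(eta.mean(axis=0))
        ).sum()
        assert d_bar == pytest.approx(d_bar2, abs=1e-8)
        assert d == pytest.approx(2 * d_bar2 - d_hat2, abs=1e-8)

    def test_too_few_draws_rejected(self):
        post, panel = self._fitted()
        short = _tiny_posterior(np.zeros((5, 4, 2)))
        with pytest.raises(ValueError, match="10"):
            pm.dic(short, panel)


class TestRelativeRisk:
    def test_zero_delta_gives_unit_rr(self):
        post = _tiny_posterior(np.zeros((20, 3, 2)))
        rr = pm.relative_risk(post, "interaction")
        np.testing.assert_allclose(rr["rr"], 1.0)

    def test_single_draw_log2_cell(self):
        delta = np.zeros((1, 2, 2))
        delta[0, 1, 0] = np.log(2.0)
        rr = pm.relative_risk(_tiny_posterior(delta), "interaction")
        rr_mat = rr["rr"].to_numpy().reshape(2, 2)
        assert rr_mat[1, 0] == pytest.approx(2.0)
        assert rr_mat[0, 0] == pytest.approx(1.0)

    def test_jensen_mean_exp_vs_exp_mean(self):
        rng = np.random.default_rng(0)
        delta = rng.normal(0, 1.0, (200, 3, 2))
        post = _tiny_posterior(delta)
        rr = pm.relative_risk(post, "interaction")["rr"].to_numpy().reshape(3, 2)
        exp_of_mean = np.exp(delta.mean(axis=0))
        assert np.all(rr >= exp_of_mean)

    def test_interaction_mode_requires_delta(self):
        lat = pm.make_lattice(3, 3, 1, seed=5)
        cfg = pm.SimulationConfig(grid_rows=3, grid_cols=3, seed=5)
        panel, _ = pm.simulate_panel(lat, cfg, T=6)
        post = pm.fit(
            panel, lat, STModelSpec(interaction_type="none", n_iter=60, n_burn=30)
        )
        with pytest.raises(ValueError, match="interaction"):
            pm.relative_risk(post, "interaction")
        rr = pm.relative_risk(post, "full")
        assert np.all(rr["rr"] > 0)


class TestFit:
    def test_null_data_recovers_intercept(self):
        lat = pm.make_lattice(6, 6, 1, seed=0)
        cfg = pm.SimulationConfig(
            grid_rows=6, grid_cols=6, b0=np.log(2.0),
            tau_u=np.inf, tau_v=np.inf, tau_gamma=np.inf, tau_phi=np.inf,
            seed=0,
        )
        panel, _ = pm.simulate_panel(lat, cfg, T=12)
        post = pm.fit(panel, lat, STModelSpec(n_iter=800, n_burn=300, seed=1))
        assert abs(post.b0.mean() - np.log(2.0)) < 3 * post.b0.std()

    def test_null_recovery_rr_near_one(self):
        lat = pm.make_lattice(5, 5, 1, population_range=(2e5, 2e5), seed=2)
        cfg = pm.SimulationConfig(
            grid_rows=5, grid_cols=5, b0=0.0, population_range=(2e5, 2e5),
            tau_u=np.inf, tau_v=np.inf, tau_gamma=np.inf, tau_phi=np.inf,
            seed=2,
        )
        panel, _ = pm.simulate_panel(lat, cfg, T=8)
        post = pm.fit(panel, lat, STModelSpec(n_iter=1200, n_burn=400, seed=3))
        for name in ("u", "v", "gamma", "phi"):
            assert np.median(post.tau[name]) > 50.0
        rr = pm.relative_risk(post, "full")["rr"].to_numpy()
        assert np.mean((rr > 0.8) & (rr < 1.25)) >= 0.95

    def test_fixed_seed_bit_identical_summary(self):
        lat = pm.make_lattice(3, 3, 1, seed=6)
        cfg = pm.SimulationConfig(grid_rows=3, grid_cols=3, seed=6)
        panel, _ = pm.simulate_panel(lat, cfg, T=6)
        spec = STModelSpec(interaction_type="I", n_iter=300, n_burn=100, seed=9)
        s1 = pm.fit(panel, lat, spec).summary().to_csv(index=False)
        s2 = pm.fit(panel, lat, spec).summary().to_csv(index=False)
        assert s1 == s2

    @pytest.mark.parametrize("itype", ["none", "I", "II", "III"])
    def test_constraints_hold_in_every_draw(self, itype):
        lat = pm.make_lattice(2, 2, 2, seed=7)  # disconnected lattice
        cfg = pm.SimulationConfig(
            grid_rows=2, grid_cols=2, n_components=2,
            interaction_type=itype, seed=7,
        )
        panel, _ = pm.simulate_panel(lat, cfg, T=6)
        spec = STModelSpec(interaction_type=itype, n_iter=250, n_burn=100, seed=8)
        post = pm.fit(panel, lat, spec)
        for comp in range(lat.n_components):
            idx = np.flatnonzero(lat.component == comp)
            np.testing.assert_allclose(
                post.u[:, idx].sum(axis=1), 0.0, atol=1e-8
            )
        t = np.arange(panel.n_periods, dtype=float)
        np.testing.assert_allclose(post.gamma.sum(axis=1), 0.0, atol=1e-8)
        np.testing.assert_allclose(post.gamma @ t, 0.0, atol=1e-7)

    def test_prior_only_reproduces_hyperprior_mean(self):
        lat = pm.make_lattice(2, 2, 1, seed=10)
        cfg = pm.SimulationConfig(grid_rows=2, grid_cols=2, seed=10)
        panel, _ = pm.simulate_panel(lat, cfg, T=4)
        spec = STModelSpec(n_iter=50_000, n_burn=0, seed=11)
        post = pm.fit(panel, lat, spec, prior_only=True)
        for name, (a, b) in spec.hyperpriors.items():
            if name == "delta":
                continue
            assert post.tau[name].mean() == pytest.approx(a / b, rel=0.05)

    def test_alternative_hyperprior_sensitivity(self):
        # fit is stable under the Gamma(0.5, 5e-4) alternative
        lat = pm.make_lattice(3, 3, 1, seed=12)
        cfg = pm.SimulationConfig(grid_rows=3, grid_cols=3, b0=0.2, seed=12)
        panel, _ = pm.simulate_panel(lat, cfg, T=6)
        hp = {k: (0.5, 5e-4) for k in ("u", "v", "gamma", "phi", "delta")}
        post = pm.fit(
            panel, lat,
            STModelSpec(hyperpriors=hp, n_iter=800, n_burn=300, seed=13),
        )
        d, p_d, _ = pm.dic(post, panel)
        assert np.isfinite(d)
        assert abs(post.b0.mean() - 0.2) < 0.3

    def test_two_chains_report_rhat(self):
        lat = pm.make_lattice(2, 2, 1, seed=14)
        cfg = pm.SimulationConfig(grid_rows=2, grid_cols=2, seed=14)
        panel, _ = pm.simulate_panel(lat, cfg, T=6)
        post = pm.fit(
            panel, lat,
            STModelSpec(n_iter=400, n_burn=150, n_chains=2, seed=15),
        )
        assert post.rhat is not None and post.rhat["b0"] < 1.5


class TestCompareModels:
    def test_identical_specs_tie_flagged(self):
        lat = pm.make_lattice(3, 3, 1, seed=16)
        cfg = pm.SimulationConfig(grid_rows=3, grid_cols=3, seed=16)
        panel, _ = pm.simulate_panel(lat, cfg, T=6)
        spec = STModelSpec(interaction_type="I", n_iter=300, n_burn=100, seed=17)
        table, best = pm.compare_models(panel, lat, [spec, spec])
        assert table["tie"].all()
        assert best is not None

    def test_fewer_than_two_specs_rejected(self):
        lat = pm.make_lattice(2, 2, 1, seed=0)
        cfg = pm.SimulationConfig(grid_rows=2, grid_cols=2, seed=0)
        panel, _ = pm.simulate_panel(lat, cfg, T=4)
        with pytest.raises(ValueError):
            pm.compare_models(panel, lat, [STModelSpec()])

    def test_select_min_dic(self):
        best, value = pm.select_min_dic({"A": 3.0, "B": 1.5, "C": 2.0})
        assert (best, value) == ("B", 1.5)
        with pytest.raises(ValueError):
            pm.select_min_dic({})
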