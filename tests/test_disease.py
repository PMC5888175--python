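"""Stage-2 disease model: Leroux precision, CAR x AR(1) density, residualisation,
measurement-error machinery and sampler correctness against exact oracles."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from airhealth.disease import (
    DiseaseSampler,
    HealthPanel,
    car_ar1_log_density,
    compute_sir,
    fit_bm,
    fit_um,
    leroux_precision,
    relative_risk,
    residualize,
    sample_car_ar1,
)
from airhealth.io import AdjacencySpec, RunConfig
from airhealth.synthetic import (
    ScenarioConfig,
    draw_error_prone_exposures,
    make_lattice,
    scenario_truth,
    simulate_true_exposures_and_counts,
)


# ---------------------------------------------------------------------------
# Leroux precision and the joint random-effect density
# ---------------------------------------------------------------------------


class TestLerouxPrecision:
    def test_rho_zero_is_identity(self, path_adjacency):
        Q = leroux_precision(0.0, path_adjacency).toarray()
        assert np.array_equal(Q, np.eye(3))

    def test_rho_one_is_graph_laplacian(self):
        adj = AdjacencySpec(n_areas=2, edges=frozenset({(0, 1)}))
        Q = leroux_precision(1.0, adj).toarray()
        assert np.array_equal(Q, [[1, -1], [-1, 1]])

    def test_half_on_path(self, path_adjacency):
        Q = leroux_precision(0.5, path_adjacency).toarray()
        expected = [[1.0, -0.5, 0.0], [-0.5, 1.5, -0.5], [0.0, -0.5, 1.0]]
        assert np.allclose(Q, expected)

    def test_rho_out_of_range(self, path_adjacency):
        with pytest.raises(ValueError, match="rho"):
            leroux_precision(1.2, path_adjacency)

    def test_nonsymmetric_w_rejected(self):
        W = np.array([[0, 1], [0, 0]], float)
        with pytest.raises(ValueError, match="symmetric"):
            leroux_precision(0.5, W)

    def test_positive_definite_below_one(self, path_adjacency):
        Q = leroux_precision(0.99, path_adjacency).toarray()
        assert np.all(np.linalg.eigvalsh(Q) > 0)


def dense_car_ar1_logpdf(phi, rho, gamma, nu2, adj):
    """Dense oracle: assemble the full KT x KT joint precision explicitly."""
    K, T = phi.shape
    Q = leroux_precision(rho, adj).toarray()
    P = np.zeros((K * T, K * T))
    for t in range(T):
        blk = slice(t * K, (t + 1) * K)
        P[blk, blk] += Q
        if t < T - 1:
            nxt = slice((t + 1) * K, (t + 2) * K)
            P[blk, blk] += gamma**2 * Q
            P[blk, nxt] += -gamma * Q
            P[nxt, blk] += -gamma * Q
    P /= nu2
    return multivariate_normal(
        mean=np.zeros(K * T), cov=np.linalg.inv(P)
    ).logpdf(phi.T.ravel())


@pytest.mark.parametrize("rho", [0.0, 0.5, 0.99])
@pytest.mark.parametrize("gamma", [0.0, 0.5, 1.0])
@pytest.mark.parametrize("shape", [(2, 3, 3), (3, 2, 2)])
def test_car_ar1_density_matches_dense_oracle(rho, gamma, shape, rng):
    rows, cols, T = shape
    adj = make_lattice(rows, cols)
    phi = rng.standard_normal((adj.n_areas, T))
    nu2 = 0.7
    mine = car_ar1_log_density(phi, rho, gamma, nu2, adj)
    dense = dense_car_ar1_logpdf(phi, rho, gamma, nu2, adj)
    assert mine == pytest.approx(dense, abs=1e-8)


def test_gamma_zero_reduces_to_independent_car_fields(rng, small_lattice):
    phi = rng.standard_normal((9, 3))
    total = car_ar1_log_density(phi, 0.6, 0.0, 0.4, small_lattice)
    per_year = sum(
        car_ar1_log_density(phi[:, t : t + 1], 0.6, 0.0, 0.4, small_lattice)
        for t in range(3)
    )
    assert total == pytest.approx(per_year, abs=1e-10)


def test_rho_zero_gamma_zero_is_iid_normal(rng, small_lattice):
    phi = rng.standard_normal((9, 2))
    nu2 = 0.3
    total = car_ar1_log_density(phi, 0.0, 0.0, nu2, small_lattice)
    assert total == pytest.approx(
        norm.logpdf(phi.ravel(), scale=np.sqrt(nu2)).sum(), abs=1e-10
    )


def test_sample_car_ar1_constant_in_time_when_unit_persistence(small_lattice, rng):
    phi = sample_car_ar1(0.5, 1.0, 1e-14, small_lattice, 4, rng)
    # gamma=1 with vanishing innovation variance freezes the field in time
    assert np.allclose(phi, phi[:, :1], atol=1e-5)


# ---------------------------------------------------------------------------
# residualisation
# ---------------------------------------------------------------------------


class TestResidualize:
    def test_exact_linear_relation_gives_zero_residuals(self):
        x1 = np.linspace(1, 5, 6).reshape(3, 2)
        res = residualize(x1, 3.0 + 2.0 * x1)
        assert np.allclose(res.residuals, 0.0, atol=1e-12)
        assert np.allclose(res.beta1, 2.0)
        assert np.allclose(res.beta0, 3.0)

    def test_hand_computed_example(self):
        x1 = np.array([[0.0], [1.0], [2.0]])
        x2 = np.array([[1.0], [1.0], [3.0]])
        res = residualize(x1, x2)
        assert np.allclose(res.residuals[:, 0, 0], [1 / 3, -2 / 3, 1 / 3])

    def test_orthogonality_and_zero_mean_exact(self, rng):
        x1 = rng.uniform(5, 20, size=(11, 3, 7))
        x2 = 0.4 * x1 + rng.normal(size=x1.shape)
        res = residualize(x1, x2)
        for t in range(3):
            for i in range(7):
                assert abs(res.residuals[:, t, i].sum()) < 1e-10
                assert abs(res.residuals[:, t, i] @ x1[:, t, i]) < 1e-10

    def test_constant_regressor_rejected(self):
        x1 = np.full((5, 1), 2.0)
        x2 = np.arange(5.0).reshape(5, 1)
        with pytest.raises(ValueError, match="constant"):
            residualize(x1, x2)

    def test_mean_residual_shape(self, rng):
        res = residualize(rng.uniform(1, 2, (5, 2, 4)), rng.uniform(1, 2, (5, 2, 4)))
        assert res.mean_residual().shape == (5, 2)


# ---------------------------------------------------------------------------
# small numeric helpers
# ---------------------------------------------------------------------------


class TestSirAndRelativeRisk:
    def test_sir_examples(self):
        assert compute_sir(11, 10) == pytest.approx(1.1)
        assert compute_sir(0, 10) == 0.0
        assert compute_sir(7, 7) == 1.0
        with pytest.raises(ValueError):
            compute_sir(1, 0)

    def test_rr_null_effect(self):
        rr = relative_risk(np.zeros(10), 5.0)
        assert rr.mean == rr.lower == rr.upper == 1.0

    def test_rr_published_scale(self):
        effect = np.log(1.030114) / 6.84
        rr = relative_risk(np.full(10, effect), 6.84)
        assert rr.mean == pytest.approx(1.030114, abs=1e-9)

    def test_rr_constant_draws(self, rng):
        rr = relative_risk(np.full(50, 0.01), 2.0)
        assert rr.mean == pytest.approx(np.exp(0.02))
        assert rr.lower == pytest.approx(rr.upper)

    def test_rr_requires_positive_sd(self):
        with pytest.raises(ValueError):
            relative_risk(np.zeros(3), 0.0)


# ---------------------------------------------------------------------------
# sampler kernels against exact oracles
# ---------------------------------------------------------------------------


def _sampler(panel, config, **kw):
    return DiseaseSampler(panel, config, **kw)


def _flat_panel(K, T, Y, E, adj):
    return HealthPanel(
        Y=Y, E=E, covariates=np.empty((K, T, 0)), covariate_names=[],
        adjacency=adj, years=np.arange(T),
    )


def test_phi_kernel_matches_brute_force_posterior():
    """Two connected areas, one year: MH samples of phi | Y reproduce the
    grid-evaluated exact posterior."""
    adj = AdjacencySpec(n_areas=2, edges=frozenset({(0, 1)}))
    E = np.full((2, 1), 30.0)
    Y = np.array([[37.0], [22.0]])
    rho, gamma, nu2 = 0.6, 0.7, 0.2
    Q = rho * np.array([[1, -1], [-1, 1.0]]) + (1 - rho) * np.eye(2)
    g = np.linspace(-2.5, 2.5, 401)
    G1, G2 = np.meshgrid(g, g, indexing="ij")
    logp = (
        Y[0, 0] * G1 + Y[1, 0] * G2 - 30 * np.exp(G1) - 30 * np.exp(G2)
        - 0.5 / nu2 * (Q[0, 0] * G1**2 + 2 * Q[0, 1] * G1 * G2 + Q[1, 1] * G2**2)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    m1, m2 = (p * G1).sum(), (p * G2).sum()
    v1 = (p * (G1 - m1) ** 2).sum()

    cfg = RunConfig(n_iterations=10, n_burnin=1, thin_for_predictions=1, h=1, seed=0)
    s = _sampler(
        _flat_panel(2, 1, Y, E, adj), cfg,
        x1=np.zeros((2, 1)), resid=np.zeros((2, 1)), rng=np.random.default_rng(3),
    )
    s.alpha[0] = 0.0
    s.rho, s.gamma, s.nu2 = rho, gamma, nu2
    s._refresh_eta()
    samp = []
    for i in range(60000):
        s._update_phi()
        if i % 5 == 0:
            samp.append(s.phi[:, 0].copy())
    samp = np.array(samp)
    assert samp[:, 0].mean() == pytest.approx(m1, abs=0.01)
    assert samp[:, 1].mean() == pytest.approx(m2, abs=0.01)
    assert samp[:, 0].var() == pytest.approx(v1, rel=0.1)


def test_ridge_move_conditional_matches_numerical_derivatives(rng):
    """The closed-form Gaussian used by the likelihood-invariant ridge move
    agrees with numerical differentiation of the explicit log target."""
    adj = make_lattice(3, 3)
    K, T = 9, 3
    E = np.full((K, T), 40.0)
    x1 = rng.normal(10, 2, (K, T))
    eps = rng.normal(0, 1, (K, T))
    gpv = 7.0
    cfg = RunConfig(
        n_iterations=10, n_burnin=1, thin_for_predictions=1, h=1, seed=0,
        gaussian_prior_variance=gpv,
    )
    s = _sampler(
        _flat_panel(K, T, np.full((K, T), 40.0), E, adj), cfg,
        x1=x1, resid=eps, rng=np.random.default_rng(3),
    )
    s.alpha[0], s.lam, s.lam_r = 0.4, 0.05, -0.03
    s.rho, s.gamma, s.nu2 = 0.6, 0.7, 0.2
    s.phi = rng.normal(0, 0.3, (K, T))
    s._refresh_eta()

    def target(name, d):
        if name == "intercept":
            v, vbar = np.ones((K, T)), 0.0
            lp = -((s.alpha[0] + d) ** 2) / (2 * gpv)
        else:
            col = x1 if name == "lam" else eps
            vbar = col.mean()
            v = col - vbar
            eff = s.lam if name == "lam" else s.lam_r
            lp = -((eff + d) ** 2) / (2 * gpv) - (s.alpha[0] - d * vbar) ** 2 / (2 * gpv)
        return car_ar1_log_density(s.phi - d * v, s.rho, s.gamma, s.nu2, adj) + lp

    h = 1e-5
    for name in ("intercept", "lam", "lam_r"):
        f0, fp, fm = target(name, 0.0), target(name, h), target(name, -h)
        num_prec = -(fp - 2 * f0 + fm) / h**2
        num_grad = (fp - fm) / (2 * h)
        if name == "intercept":
            v, vbar, eff = np.ones((K, T)), 0.0, s.alpha[0]
        else:
            col = x1 if name == "lam" else eps
            vbar = col.mean()
            v = col - vbar
            eff = s.lam if name == "lam" else s.lam_r
        rv = v.copy()
        rv[:, 1:] -= s.gamma * v[:, :-1]
        Qrv = s._Q_mat(rv)
        quad_vv = float(np.sum(rv * Qrv))
        rphi = s.phi.copy()
        rphi[:, 1:] -= s.gamma * s.phi[:, :-1]
        cross = float(np.sum(rphi * Qrv))
        if name == "intercept":
            prec = quad_vv / s.nu2 + 1.0 / gpv
            lin = cross / s.nu2 - s.alpha[0] / gpv
        else:
            prec = quad_vv / s.nu2 + (1.0 + vbar**2) / gpv
            lin = cross / s.nu2 - eff / gpv + s.alpha[0] * vbar / gpv
        assert prec == pytest.approx(num_prec, rel=1e-4)
        assert lin == pytest.approx(num_grad, rel=1e-4, abs=1e-6)


def test_latent_exposure_conditional_matches_grid(rng):
    """One area, one year: the latent-exposure update reproduces the
    grid-evaluated unnormalised conditional posterior."""
    adj = AdjacencySpec(n_areas=1, edges=frozenset())
    K, T, h = 1, 1, 40
    truth_x = 20.0
    draws = truth_x * (1 + 0.15 * rng.standard_normal((K, T, h)))
    eps_draws = rng.normal(0, 0.5, (K, T, h))
    Y = np.array([[140.0]])
    E = np.array([[100.0]])
    cfg = RunConfig(n_iterations=10, n_burnin=1, thin_for_predictions=1, h=1, seed=0)
    s = _sampler(
        _flat_panel(K, T, Y, E, adj), cfg,
        x1_draws=draws, resid_draws=eps_draws, rng=np.random.default_rng(5),
    )
    lam, a0 = 0.02, -0.35
    sig_p2, sig_r2 = 0.02, 0.3
    s.lam, s.alpha[0], s.lam_r = lam, a0, 0.0
    s.sigma_p2, s.sigma_r2 = sig_p2, sig_r2
    s.phi[:] = 0.0
    s.nu2, s.rho, s.gamma = 0.1, 0.5, 0.5
    s._refresh_eta()

    xs = np.linspace(10, 30, 4000)
    S1, S2 = float(s.S1[0, 0]), float(s.S2[0, 0])
    mu_x, s2_x = float(s.mu_x[0, 0]), float(s.s2_x[0, 0])
    logp = (
        Y[0, 0] * lam * xs
        - E[0, 0] * np.exp(a0 + lam * xs)
        - h * np.log(xs)
        - (S2 - 2 * xs * S1 + h * xs**2) / (2 * sig_p2 * xs**2)
        - (xs - mu_x) ** 2 / (2 * s2_x)
    )
    w = np.exp(logp - logp.max())
    w /= w.sum()
    mean_bf = float((w * xs).sum())
    sd_bf = float(np.sqrt((w * (xs - mean_bf) ** 2).sum()))

    samples = []
    for i in range(40000):
        s._update_latent()
        # freeze the variance parameters and the residual block so only the
        # latent exposure moves
        s.sigma_p2, s.sigma_r2 = sig_p2, sig_r2
        s.eps[:] = 0.0
        s._refresh_eta()
        if i % 4 == 0:
            samples.append(s.x[0, 0])
    samples = np.array(samples[200:])
    assert samples.mean() == pytest.approx(mean_bf, abs=3 * sd_bf / np.sqrt(len(samples) / 20))
    assert samples.std() == pytest.approx(sd_bf, rel=0.12)


def test_joint_distribution_geweke_smoke():
    """Forward draws and successive-conditional sampling agree on the
    location-type summaries of the miniature model's joint distribution."""
    adj = make_lattice(2, 2)
    K, T = 4, 2
    E = np.full((K, T), 50.0)
    x1 = np.array([[0.3, -0.2], [1.0, 0.5], [-0.8, 0.1], [0.2, -1.1]])
    eps = np.array([[0.5, 0.2], [-0.3, 0.4], [0.1, -0.6], [-0.3, 0.0]])
    cfg = RunConfig(
        n_iterations=10, n_burnin=1, thin_for_predictions=1, h=1, seed=0,
        gaussian_prior_variance=0.25, ig_shape=3.0, ig_scale=0.3,
    )

    def forward(n, rng):
        out = []
        for _ in range(n):
            lam, lam_r, a0 = rng.normal(0, 0.5, 3)
            nu2 = 0.3 / rng.gamma(3.0)
            rho, gamma = rng.uniform(), rng.uniform()
            phi = sample_car_ar1(min(rho, 0.999), gamma, nu2, adj, T, rng)
            out.append((lam, lam_r, a0, gamma))
        return np.array(out)

    def successive(n, rng):
        panel = _flat_panel(K, T, np.full((K, T), 50.0), E, adj)
        s = _sampler(panel, cfg, x1=x1, resid=eps, rng=rng)
        s.lam, s.lam_r, s.alpha[0] = rng.normal(0, 0.5, 3)
        s.nu2 = 0.3 / rng.gamma(3.0)
        s.rho, s.gamma = rng.uniform(), rng.uniform()
        s.phi = sample_car_ar1(min(s.rho, 0.999), s.gamma, s.nu2, adj, T, rng)
        s._refresh_eta()
        s.set_counts(s.simulate_counts())
        out = []
        for _ in range(n):
            s.step()
            s.set_counts(s.simulate_counts())
            out.append((s.lam, s.lam_r, s.alpha[0], s.gamma))
        return np.array(out)

    f = forward(2500, np.random.default_rng(10))
    g = successive(20000, np.random.default_rng(11))
    names = ("lam", "lam_r", "alpha0", "gamma")
    for i, name in enumerate(names):
        # conservative autocorrelation inflation for the chain series
        se = np.sqrt(f[:, i].var() / len(f) + 200 * g[:, i].var() / len(g))
        z = abs(f[:, i].mean() - g[:, i].mean()) / se
        assert z < 4.5, f"joint-distribution mismatch for {name}: z={z:.2f}"


# ---------------------------------------------------------------------------
# model-level behaviour
# ---------------------------------------------------------------------------


def test_um_requires_multiple_draws(small_lattice, short_config, rng):
    K, T = 9, 2
    panel = _flat_panel(K, T, rng.poisson(50, (K, T)).astype(float),
                        np.full((K, T), 50.0), small_lattice)
    with pytest.raises(ValueError, match="fit_bm"):
        fit_um(panel, rng.uniform(1, 2, (K, T, 1)), rng.normal(size=(K, T, 1)), short_config)


def test_offset_property_doubling_expected_counts(rng):
    """Doubling E with Y fixed shifts the posterior overall log-risk level by
    about -ln 2 and leaves the exposure effect essentially unchanged."""
    adj = make_lattice(4, 4)
    K, T = 16, 2
    x1 = rng.uniform(5, 15, (K, T))
    E = np.full((K, T), 80.0)
    Y = rng.poisson(E * np.exp(0.02 * (x1 - x1.mean())))
    cfg = RunConfig(n_iterations=1500, n_burnin=500, thin_for_predictions=1, h=100, seed=2)
    p1 = fit_bm(_flat_panel(K, T, Y, E, adj), x1, None, cfg, rng=np.random.default_rng(4))
    p2 = fit_bm(_flat_panel(K, T, Y, 2 * E, adj), x1, None, cfg, rng=np.random.default_rng(4))
    level1 = p1.alpha[:, 0].mean() + (p1.lam.mean() * x1 + p1.phi_mean).mean()
    level2 = p2.alpha[:, 0].mean() + (p2.lam.mean() * x1 + p2.phi_mean).mean()
    assert level2 - level1 == pytest.approx(-np.log(2), abs=0.1)


def test_uninformative_exposure_leaves_effect_at_prior(rng):
    """An all-zero exposure column carries no information: the posterior for
    its effect stays diffuse like the N(0, 1000) prior."""
    adj = make_lattice(3, 3)
    K, T = 9, 2
    E = np.full((K, T), 60.0)
    Y = rng.poisson(E).astype(float)
    cfg = RunConfig(n_iterations=2000, n_burnin=500, thin_for_predictions=1, h=100, seed=3)
    post = fit_bm(_flat_panel(K, T, Y, E, adj), np.zeros((K, T)), None, cfg,
                  rng=np.random.default_rng(6))
    sd = post.lam.std()
    assert sd > 10.0  # prior sd is ~31.6; diffuse, nowhere near likelihood-scale
    assert abs(post.lam.mean()) < 3 * sd


def test_um_with_degenerate_draws_matches_bm(rng):
    """When every exposure draw is identical the measurement-error model
    collapses onto the baseline model."""
    sc = ScenarioConfig(rows=5, cols=5, n_periods=2, seed=8, expected_mean=120.0)
    adj = make_lattice(5, 5)
    truth = scenario_truth(sc, np.random.default_rng(8))
    panel, _ = simulate_true_exposures_and_counts(sc, adj, np.random.default_rng(9), truth=truth)
    x1 = truth["X1"]
    eps = truth["eps"]
    h = 5
    x1_draws = np.repeat(x1[:, :, None], h, axis=2)
    eps_draws = np.repeat(eps[:, :, None], h, axis=2)
    cfg = RunConfig(n_iterations=2500, n_burnin=800, thin_for_predictions=1, h=100, seed=4)
    bm = fit_bm(panel, x1, eps, cfg, rng=np.random.default_rng(10))
    um = fit_um(panel, x1_draws, eps_draws, cfg, rng=np.random.default_rng(11))
    rr_bm = relative_risk(bm.lam, truth["sd1"])
    rr_um = relative_risk(um.lam, truth["sd1"])
    assert rr_um.mean == pytest.approx(rr_bm.mean, abs=0.02)


def test_identical_seeds_reproduce_the_chain_exactly(rng):
    """Two runs with the same configuration and seed yield bit-identical draws."""
    adj = make_lattice(3, 3)
    K, T = 9, 2
    x1 = rng.uniform(5, 15, (K, T))
    E = np.full((K, T), 70.0)
    Y = rng.poisson(E).astype(float)
    panel = _flat_panel(K, T, Y, E, adj)
    cfg = RunConfig(n_iterations=300, n_burnin=100, thin_for_predictions=1, h=50, seed=11)
    p1 = fit_bm(panel, x1, None, cfg)
    p2 = fit_bm(panel, x1, None, cfg)
    assert np.array_equal(p1.lam, p2.lam)
    assert np.array_equal(p1.nu2, p2.nu2)
    assert np.array_equal(p1.phi_mean, p2.phi_mean)


def test_bm_recovers_relative_risk_without_measurement_error():
    """Counts generated at the published effect sizes with exact exposures:
    the 95% interval covers the generating relative risk."""
    sc = ScenarioConfig(rows=8, cols=8, n_periods=3, seed=5)
    adj = make_lattice(8, 8)
    truth = scenario_truth(sc, np.random.default_rng(5))
    panel, _ = simulate_true_exposures_and_counts(sc, adj, np.random.default_rng(6), truth=truth)
    cfg = RunConfig(n_iterations=4000, n_burnin=1000, thin_for_predictions=1, h=100, seed=6)
    post = fit_bm(panel, truth["X1"], truth["eps"], cfg, rng=np.random.default_rng(7))
    rr = relative_risk(post.lam, truth["sd1"])
    assert rr.lower - 0.005 <= sc.rr_lambda <= rr.upper + 0.005
    assert rr.mean == pytest.approx(sc.rr_lambda, abs=0.02)
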