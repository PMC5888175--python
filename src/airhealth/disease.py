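"""Stage 2: areal Poisson disease models with Leroux-CAR x AR(1) random effects.

Two variants of the same spatio-temporal Poisson log-linear model are
provided.  The baseline model (BM) plugs fixed point estimates of exposure
into the linear predictor:

    Y_kt ~ Poisson(E_kt R_kt)
    ln R_kt = b_kt' alpha + X_kt1 lambda + eps_kt lambda_r + phi_kt
    phi_t | phi_{t-1} ~ N(gamma phi_{t-1}, nu^2 Q(rho, W)^{-1})

with Q(rho, W) = rho (diag(W 1) - W) + (1 - rho) I the Leroux conditional
autoregressive precision.  The uncertainty model (UM) instead treats the true
exposure X_kt1 and the true residual-pollutant exposure eps_kt as latent,
linking them to the h stage-1 posterior draws through classical
measurement-error likelihoods: draws of the first pollutant scatter around
the truth with variance sigma_p^2 X_kt1^2 (error grows with concentration),
draws of the residual pollutant with constant variance sigma_r^2.

Collinearity between two pollutants is handled by residualisation: pollutant
2 is regressed on pollutant 1 year by year via least squares, and the
residuals (exactly orthogonal to pollutant 1 and zero-mean within each year)
enter the linear predictor as a second, uncorrelated exposure covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._mcmc import AdaptiveScale, greedy_coloring, sample_invgamma, sample_truncnorm01
from .io import AdjacencySpec, RunConfig, get_rng

logger = logging.getLogger("airhealth")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class HealthPanel:
    """Complete areal disease panel: counts, expected counts, confounders, adjacency."""

    Y: np.ndarray  # (K, T) nonnegative integer counts
    E: np.ndarray  # (K, T) positive expected counts
    covariates: np.ndarray  # (K, T, p) confounders, intercept NOT included
    covariate_names: list
    adjacency: AdjacencySpec
    years: np.ndarray

    def __post_init__(self):
        K, T = self.Y.shape
        if self.E.shape != (K, T):
            raise ValueError("Y and E must have the same (K, T) shape")
        if self.covariates.shape[:2] != (K, T):
            raise ValueError("covariates must be (K, T, p)")
        if K != self.adjacency.n_areas:
            raise ValueError("panel area count does not match the adjacency")
        if np.isnan(self.Y).any() or np.isnan(self.E).any():
            raise ValueError("Y and E must be complete (no missing values)")
        if (self.Y < 0).any():
            raise ValueError("counts must be nonnegative")
        if (self.E <= 0).any():
            raise ValueError("expected counts must be strictly positive")

    @property
    def shape(self):
        return self.Y.shape

    def design(self) -> np.ndarray:
        """(K, T, 1 + p) confounder design with a leading intercept column."""
        K, T = self.Y.shape
        return np.concatenate([np.ones((K, T, 1)), self.covariates], axis=2)


@dataclass
class ResidualExposure:
    """Year-wise least-squares residuals of pollutant 2 on pollutant 1, per draw.

    For every year t and draw i, ``residuals[:, t, i]`` is exactly orthogonal
    to the pollutant-1 vector of that (t, i) and sums to zero (the regression
    includes an intercept).
    """

    residuals: np.ndarray  # (K, T, h)
    beta0: np.ndarray  # (T, h)
    beta1: np.ndarray  # (T, h)
    sigma2: np.ndarray  # (T, h) residual error variance estimates

    @property
    def h(self) -> int:
        return self.residuals.shape[-1]

    def mean_residual(self) -> np.ndarray:
        """Mean over the h residual sets, the fixed exposure used by BM."""
        return self.residuals.mean(axis=-1)


@dataclass
class DiseasePosterior:
    """Posterior draws from :func:`fit_bm` / :func:`fit_um`."""

    model: str  # "bm" or "um"
    alpha: np.ndarray  # (n, 1 + p) intercept first
    lam: np.ndarray  # (n,) first-pollutant effect
    lam_r: np.ndarray  # (n,) residual-pollutant effect
    nu2: np.ndarray
    rho: np.ndarray
    gamma: np.ndarray
    sigma_p2: np.ndarray | None
    sigma_r2: np.ndarray | None
    phi_mean: np.ndarray  # (K, T) posterior mean random effects
    covariate_names: list
    acceptance: dict = field(default_factory=dict)
    phi: np.ndarray | None = None  # (n, K, T) only when requested

    @property
    def n_draws(self) -> int:
        return self.lam.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = {"alpha[intercept]": self.alpha[:, 0]}
        for c, name in enumerate(self.covariate_names):
            cols[f"alpha[{name}]"] = self.alpha[:, c + 1]
        cols["lambda"] = self.lam
        cols["lambda_r"] = self.lam_r
        cols["nu2"] = self.nu2
        cols["rho"] = self.rho
        cols["gamma"] = self.gamma
        if self.sigma_p2 is not None:
            cols["sigma_p2"] = self.sigma_p2
        if self.sigma_r2 is not None:
            cols["sigma_r2"] = self.sigma_r2
        return pd.DataFrame(cols)

    def summary(self, sds: dict | None = None) -> pd.DataFrame:
        """Posterior mean and 95% interval per parameter.

        ``sds`` maps covariate names (and "pollutant" / "residual") to the
        standard deviation used to report the effect as a relative risk for a
        one-standard-deviation increase; parameters without an entry are
        summarised on their natural scale.
        """
        sds = sds or {}
        rows = []

        def add(name, draws, sd=None):
            if sd is not None:
                rr = relative_risk(draws, sd)
                rows.append(
                    {"parameter": name, "mean": rr.mean, "lower_2.5": rr.lower,
                     "upper_97.5": rr.upper, "scale": f"RR per {sd:g} increase"}
                )
            else:
                lo, hi = np.percentile(draws, [2.5, 97.5])
                rows.append(
                    {"parameter": name, "mean": float(np.mean(draws)),
                     "lower_2.5": float(lo), "upper_97.5": float(hi), "scale": "natural"}
                )

        add("pollutant", self.lam, sds.get("pollutant"))
        add("residual", self.lam_r, sds.get("residual"))
        add("intercept", self.alpha[:, 0])
        for c, name in enumerate(self.covariate_names):
            add(name, self.alpha[:, c + 1], sds.get(name))
        for name in ("nu2", "rho", "gamma"):
            add(name, getattr(self, name))
        if self.sigma_p2 is not None:
            add("sigma_p2", self.sigma_p2)
        if self.sigma_r2 is not None:
            add("sigma_r2", self.sigma_r2)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class RelativeRisk:
    mean: float
    lower: float
    upper: float


# ---------------------------------------------------------------------------
# model primitives
# ---------------------------------------------------------------------------


def leroux_precision(rho: float, W) -> sp.csr_array:
    """Leroux CAR precision Q(rho, W) = rho (diag(W 1) - W) + (1 - rho) I.

    rho = 0 gives independence (identity precision); rho = 1 the intrinsic
    autoregression (graph Laplacian, singular).  Returned sparse.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    W = _as_W(W)
    if (abs(W - W.T) > 1e-12).nnz:
        raise ValueError("W must be symmetric")
    if np.any(W.diagonal() != 0):
        raise ValueError("W must have a zero diagonal")
    data = W.data
    if data.size and not np.all((data == 0) | (data == 1)):
        raise ValueError("W must be binary")
    n = W.shape[0]
    deg = np.asarray(W.sum(axis=1)).ravel()
    lap = sp.diags_array(deg) - W
    return sp.csr_array(rho * lap + (1.0 - rho) * sp.eye_array(n))


def _as_W(W) -> sp.csr_array:
    if isinstance(W, AdjacencySpec):
        return W.W()
    return sp.csr_array(W, dtype=float)


def car_ar1_log_density(phi: np.ndarray, rho: float, gamma: float, nu2: float, W) -> float:
    """Normalised joint log density of the CAR x AR(1) random-effect field.

    ``phi`` is (K, T): phi_1 ~ N(0, nu2 Q^{-1}) and
    phi_t | phi_{t-1} ~ N(gamma phi_{t-1}, nu2 Q^{-1}).  Computed with sparse
    quadratic forms and the eigenvalues of the graph Laplacian, so it scales
    to large K; requires rho < 1 for a proper density.
    """
    W = _as_W(W)
    K, T = phi.shape
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1) for a proper density")
    deg = np.asarray(W.sum(axis=1)).ravel()
    lap_eigs = np.linalg.eigvalsh((sp.diags_array(deg) - W).toarray())
    logdet_Q = float(np.sum(np.log(rho * lap_eigs + (1.0 - rho))))
    resid = phi.copy()
    resid[:, 1:] -= gamma * phi[:, :-1]
    Qr = rho * (deg[:, None] * resid - W @ resid) + (1.0 - rho) * resid
    S = float(np.sum(resid * Qr))
    return (
        -0.5 * K * T * np.log(2.0 * np.pi * nu2)
        + 0.5 * T * logdet_Q
        - S / (2.0 * nu2)
    )


def sample_car_ar1(
    rho: float, gamma: float, nu2: float, adjacency, T: int, rng
) -> np.ndarray:
    """Draw a (K, T) field from the CAR x AR(1) prior (dense Cholesky of Q)."""
    rng = get_rng(rng)
    Q = leroux_precision(rho, adjacency).toarray()
    K = Q.shape[0]
    jitter = 0.0
    for _ in range(6):
        try:
            L = np.linalg.cholesky(Q + jitter * np.eye(K))
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-10)
            logger.warning("singular Leroux precision; applying jitter %.1e", jitter)
    else:  # pragma: no cover
        raise np.linalg.LinAlgError("could not factor the Leroux precision")
    phi = np.empty((K, T))
    innov = np.sqrt(nu2) * rng.standard_normal((K, T))
    # solve L' x = z  =>  x ~ N(0, Q^{-1})
    phi[:, 0] = np.linalg.solve(L.T, innov[:, 0])
    for t in range(1, T):
        phi[:, t] = gamma * phi[:, t - 1] + np.linalg.solve(L.T, innov[:, t])
    return phi


def residualize(x1_draws: np.ndarray, x2_draws: np.ndarray) -> ResidualExposure:
    """Regress pollutant 2 on pollutant 1, per year and per draw, via OLS.

    Inputs are (K, T) or (K, T, h) aligned arrays on the natural scale.  The
    returned residuals satisfy, exactly (to numerical precision), both
    sum_k eps_kt^i = 0 and eps^(t,i) . x1^(t,i) = 0 for every (t, i).
    """
    x1 = np.asarray(x1_draws, dtype=float)
    x2 = np.asarray(x2_draws, dtype=float)
    if x1.ndim == 2:
        x1 = x1[..., None]
    if x2.ndim == 2:
        x2 = x2[..., None]
    if x1.shape != x2.shape:
        raise ValueError("pollutant draw arrays must be aligned (K, T, h)")
    K = x1.shape[0]
    if K < 3:
        raise ValueError("at least 3 areas are needed for the year-wise regression")
    x1c = x1 - x1.mean(axis=0)
    x2c = x2 - x2.mean(axis=0)
    var1 = (x1c**2).mean(axis=0)  # (T, h)
    if np.any(var1 <= 1e-12 * np.maximum(1.0, x1.mean(axis=0) ** 2)):
        raise ValueError(
            "pollutant 1 is (numerically) constant within a year: "
            "the year-wise regression is degenerate"
        )
    beta1 = (x1c * x2c).mean(axis=0) / var1
    beta0 = x2.mean(axis=0) - beta1 * x1.mean(axis=0)
    resid = x2c - beta1[None, :, :] * x1c
    dof = max(K - 2, 1)
    sigma2 = (resid**2).sum(axis=0) / dof
    return ResidualExposure(residuals=resid, beta0=beta0, beta1=beta1, sigma2=sigma2)


def compute_sir(Y, E):
    """Standardised incidence ratio Y / E (risk relative to expectation)."""
    Y = np.asarray(Y, dtype=float)
    E = np.asarray(E, dtype=float)
    if np.any(E <= 0):
        raise ValueError("expected counts must be positive")
    return Y / E


def relative_risk(effect_draws: np.ndarray, sd: float) -> RelativeRisk:
    """Relative risk for a one-standard-deviation covariate increase.

    Each posterior draw maps to exp(effect * sd); the summary reports the
    posterior mean and the equal-tailed 95% credible interval.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    rr = np.exp(np.asarray(effect_draws, dtype=float) * sd)
    lo, hi = np.percentile(rr, [2.5, 97.5])
    return RelativeRisk(mean=float(rr.mean()), lower=float(lo), upper=float(hi))


# ---------------------------------------------------------------------------
# the MCMC engine
# ---------------------------------------------------------------------------


class DiseaseSampler:
    """Metropolis-within-Gibbs sampler shared by the BM and UM variants.

    Regression effects use adaptive scalar random walks on the Poisson
    log-posterior; random effects use single-site random walks vectorised
    over graph-colouring classes (same-colour areas are conditionally
    independent at a given year); nu2, gamma and the measurement-error
    variances are conjugate; rho uses a logit random walk with the Leroux
    log-determinant evaluated through the Laplacian eigenvalues.
    """

    def __init__(
        self,
        health: HealthPanel,
        config: RunConfig,
        x1=None,
        resid=None,
        x1_draws=None,
        resid_draws=None,
        rng=None,
    ):
        self.health = health
        self.config = config
        self.rng = get_rng(config.seed if rng is None else rng)
        self.K, self.T = health.Y.shape
        self.Y = health.Y.astype(float)
        self.E = health.E.astype(float)
        self.B = health.design()  # (K, T, pb)
        self.pb = self.B.shape[-1]
        self.latent = x1_draws is not None
        self.gpv = config.gaussian_prior_variance
        self.a0, self.b0 = config.ig_shape, config.ig_scale

        W = health.adjacency.W()
        # dense neighbourhood arithmetic beats sparse dispatch overhead for
        # the areal sizes this model is run at; fall back to sparse when big
        self.W = W.toarray() if health.adjacency.n_areas <= 2000 else W
        self.dense = isinstance(self.W, np.ndarray)
        self.deg = np.asarray(W.sum(axis=1)).ravel()
        lap = sp.diags_array(self.deg) - W
        self.lap_eigs = np.linalg.eigvalsh(lap.toarray())
        self.colors = greedy_coloring(W)
        if self.dense:
            self.W_rows = [self.W[g, :] for g in self.colors]
        else:
            self.W_rows = [sp.csr_array(W[g, :]) for g in self.colors]
        self._phi_ix = {}
        for parity in (0, 1):
            ts = np.arange(parity, self.T, 2)
            for ci, group in enumerate(self.colors):
                self._phi_ix[(parity, ci)] = np.ix_(group, ts)
        if health.adjacency.isolated_areas().size:
            logger.warning("disease model fitted on a graph with isolated areas")

        if self.latent:
            x1_draws = np.asarray(x1_draws, dtype=float)
            resid_draws = np.asarray(resid_draws, dtype=float)
            self.h = x1_draws.shape[-1]
            if self.h < 2:
                raise ValueError(
                    "the uncertainty model needs h >= 2 exposure draws per cell; "
                    "with a single draw use fit_bm"
                )
            if np.any(x1_draws <= 0):
                raise ValueError("exposure draws must be positive")
            # sufficient statistics of the h draws per cell
            self.S1 = x1_draws.sum(axis=-1)
            self.S2 = (x1_draws**2).sum(axis=-1)
            self.mu_x = self.S1 / self.h
            var_x = np.maximum(self.S2 / self.h - self.mu_x**2, 0.0)
            # hyperparameters of the latent-exposure prior, fixed large so the
            # prior is weakly informative on the scale of the data
            self.s2_x = np.maximum(1000.0 * var_x, 1.0)
            self.T1 = resid_draws.sum(axis=-1)
            self.T2 = (resid_draws**2).sum(axis=-1)
            self.mu_e = self.T1 / self.h
            var_e = np.maximum(self.T2 / self.h - self.mu_e**2, 0.0)
            self.s2_e = np.maximum(1000.0 * var_e, 1.0)
            self.x = self.mu_x.copy()
            self.eps = self.mu_e.copy()
            self.sigma_p2 = float(np.mean(var_x / np.maximum(self.mu_x**2, 1e-12)) + 1e-6)
            self.sigma_r2 = float(np.mean(var_e) + 1e-6)
        else:
            self.x = np.asarray(x1, dtype=float)
            self.eps = (
                np.zeros((self.K, self.T))
                if resid is None
                else np.asarray(resid, dtype=float)
            )
            self.sigma_p2 = None
            self.sigma_r2 = None
        if self.x.shape != (self.K, self.T) or self.eps.shape != (self.K, self.T):
            raise ValueError("exposures must align with the (K, T) health panel")

        # initial state
        self.alpha = np.zeros(self.pb)
        self.alpha[0] = float(np.log(max(self.Y.sum() / self.E.sum(), 1e-12)))
        self.lam = 0.0
        self.lam_r = 0.0
        self.phi = np.zeros((self.K, self.T))
        self.nu2 = 0.1
        self.rho = 0.5
        self.gamma = 0.5
        self._refresh_eta()

        self.steps = {
            "alpha": [AdaptiveScale(init=0.05) for _ in range(self.pb)],
            "lam": AdaptiveScale(init=0.01),
            "lam_r": AdaptiveScale(init=0.01),
            "phi": [AdaptiveScale(init=0.3, target=0.44) for _ in range(2)],
            "rho": AdaptiveScale(init=0.5),
        }
        if self.latent:
            self.steps["x"] = AdaptiveScale(init=0.02, target=0.3)
            self.steps["eps"] = AdaptiveScale(init=0.1, target=0.3)
        self._acc = {k: 0.0 for k in ("alpha", "lam", "lam_r", "rho")}
        self._n_steps = 0

    # -- bookkeeping -----------------------------------------------------

    def _refresh_eta(self):
        self.offset = (
            np.einsum("ktp,p->kt", self.B, self.alpha)
            + self.x * self.lam
            + self.eps * self.lam_r
        )
        self.eta = self.offset + self.phi

    def set_counts(self, Y: np.ndarray) -> None:
        """Replace the observed counts (used by joint-distribution validation)."""
        self.Y = np.asarray(Y, dtype=float)

    def simulate_counts(self, rng=None) -> np.ndarray:
        """Draw counts from the Poisson likelihood at the current state."""
        rng = self.rng if rng is None else get_rng(rng)
        return rng.poisson(self.E * np.exp(self.eta)).astype(float)

    def freeze_adaptation(self):
        for s in self.steps.values():
            if isinstance(s, list):
                for si in s:
                    si.freeze()
            else:
                s.freeze()

    def _Q_mat(self, v: np.ndarray) -> np.ndarray:
        """Q(rho, W) @ v for v of shape (K,) or (K, T)."""
        if v.ndim == 1:
            return self.rho * (self.deg * v - self.W @ v) + (1.0 - self.rho) * v
        return self.rho * (self.deg[:, None] * v - self.W @ v) + (1.0 - self.rho) * v

    # -- update blocks ---------------------------------------------------

    def _mh_effect(self, name: str, value: float, column: np.ndarray) -> float:
        """Scalar adaptive random-walk update of a regression effect."""
        step = self.steps[name]
        delta = step.scale * self.rng.standard_normal()
        new = value + delta
        with np.errstate(over="ignore"):
            d_ll = float(
                np.sum(self.Y * delta * column)
                - np.sum(self.E * np.exp(self.eta) * (np.exp(delta * column) - 1.0))
            )
        d_prior = (value**2 - new**2) / (2.0 * self.gpv)
        logr = d_ll + d_prior
        accept = np.isfinite(logr) and np.log(self.rng.uniform()) < logr
        if accept:
            value = new
            self.offset += delta * column
            self.eta += delta * column
            self._acc[name] += 1
        step.update(1.0 if accept else 0.0)
        return value

    def _mh_alpha(self, c: int):
        step = self.steps["alpha"][c]
        column = self.B[:, :, c]
        delta = step.scale * self.rng.standard_normal()
        with np.errstate(over="ignore"):
            d_ll = float(
                np.sum(self.Y * delta * column)
                - np.sum(self.E * np.exp(self.eta) * (np.exp(delta * column) - 1.0))
            )
        new = self.alpha[c] + delta
        d_prior = (self.alpha[c] ** 2 - new**2) / (2.0 * self.gpv)
        logr = d_ll + d_prior
        accept = np.isfinite(logr) and np.log(self.rng.uniform()) < logr
        if accept:
            self.alpha[c] = new
            self.offset += delta * column
            self.eta += delta * column
            self._acc["alpha"] += 1.0 / self.pb
        step.update(1.0 if accept else 0.0)

    def _update_phi(self):
        """Single-site MH on phi, vectorised over (colour, time-parity) blocks.

        Under the CAR x AR(1) prior, phi_kt interacts only with same-year
        graph neighbours and with year t±1 at k and its neighbours, so cells
        sharing a graph colour and a year parity are conditionally
        independent and can be proposed/accepted simultaneously.
        """
        g2 = self.gamma**2
        Qkk = self.rho * self.deg + (1.0 - self.rho)
        mult = np.ones(self.T)
        mult[: self.T - 1] += g2  # forward AR term exists except in the last year
        off = self.eta - self.phi
        for parity in (0, 1):
            ts = np.arange(parity, self.T, 2)
            other = np.arange(1 - parity, self.T, 2)
            if ts.size == 0:
                continue
            # Q phi for the neighbouring (other-parity) years: those columns
            # are not touched during this pass, so compute them once
            gterm = np.zeros((self.K, ts.size))
            if other.size:
                phi_o = self.phi[:, other]
                QP = np.zeros((self.K, self.T))
                QP[:, other] = (
                    self.rho * (self.deg[:, None] * phi_o - self.W @ phi_o)
                    + (1.0 - self.rho) * phi_o
                )
                for i, t in enumerate(ts):
                    if t > 0:
                        gterm[:, i] += QP[:, t - 1]
                    if t < self.T - 1:
                        gterm[:, i] += QP[:, t + 1]
                gterm *= self.gamma
            mult_ts = mult[ts][None, :]
            A_ts = Qkk[:, None] * mult_ts
            with np.errstate(over="ignore"):
                Eexp = self.E[:, ts] * np.exp(off[:, ts])
            Y_ts = self.Y[:, ts]
            step = self.steps["phi"][parity]
            acc_sum, n_sum = 0.0, 0
            for ci, (group, Wrows) in enumerate(zip(self.colors, self.W_rows)):
                ix = self._phi_ix[(parity, ci)]
                Wphi = Wrows @ self.phi[:, ts]  # only the rows being updated
                Bq = -self.rho * Wphi * mult_ts - gterm[group]
                v = self.phi[ix]
                vn = v + step.scale * self.rng.standard_normal(v.shape)
                with np.errstate(over="ignore"):
                    ev = np.exp(v)
                    d_ll = Y_ts[group] * (vn - v) - Eexp[group] * (np.exp(vn) - ev)
                d_prior = -(A_ts[group] * (vn**2 - v**2) + 2.0 * (vn - v) * Bq) / (
                    2.0 * self.nu2
                )
                logr = d_ll + d_prior
                accept = np.log(self.rng.uniform(size=v.shape)) < np.where(
                    np.isfinite(logr), logr, -np.inf
                )
                self.phi[ix] = np.where(accept, vn, v)
                acc_sum += accept.sum()
                n_sum += accept.size
            step.update(acc_sum / max(n_sum, 1))
        self.eta = off + self.phi

    def _translation_moves(self):
        """Exact Gibbs moves along the effect/random-field ridge.

        The linear predictor is invariant under (effect + d, intercept
        - d * col_mean, phi - d * (col - col_mean)), so the conditional
        distribution of d given everything else involves only the Gaussian
        effect priors and the CAR x AR(1) prior — a closed-form Gaussian.
        Sampling it exactly decorrelates the regression effects from the
        random field; without these moves the single-site phi updates leave
        the effects trapped near their starting values, because the field can
        impersonate any covariate at a prior cost the likelihood never sees.
        """
        for name in ("intercept", "lam", "lam_r"):
            if name == "intercept":
                v = np.ones((self.K, self.T))
                vbar = 0.0
                eff = self.alpha[0]
            else:
                column = self.x if name == "lam" else self.eps
                vbar = float(column.mean())
                v = column - vbar
                eff = self.lam if name == "lam" else self.lam_r
            rv = v.copy()
            rv[:, 1:] -= self.gamma * v[:, :-1]
            Qrv = self._Q_mat(rv)
            quad_vv = float(np.sum(rv * Qrv))
            rphi = self.phi.copy()
            rphi[:, 1:] -= self.gamma * self.phi[:, :-1]
            cross = float(np.sum(rphi * Qrv))
            prec = quad_vv / self.nu2 + (1.0 + vbar**2) / self.gpv
            lin = cross / self.nu2 - eff / self.gpv + self.alpha[0] * vbar / self.gpv
            if name == "intercept":
                # effect IS the intercept: prior term -(a0 + d)^2 / (2 gpv)
                prec = quad_vv / self.nu2 + 1.0 / self.gpv
                lin = cross / self.nu2 - self.alpha[0] / self.gpv
            d = lin / prec + self.rng.standard_normal() / np.sqrt(prec)
            if name == "intercept":
                self.alpha[0] += d
            elif name == "lam":
                self.lam += d
                self.alpha[0] -= d * vbar
            else:
                self.lam_r += d
                self.alpha[0] -= d * vbar
            self.phi -= d * v
            self.offset += d * v

    def _car_quadratics(self):
        """(S_L, S_I): Laplacian and identity parts of the CAR x AR(1) quadratic."""
        resid = self.phi.copy()
        resid[:, 1:] -= self.gamma * self.phi[:, :-1]
        Wr = self.W @ resid
        S_L = float(np.sum(resid * (self.deg[:, None] * resid - Wr)))
        S_I = float(np.sum(resid * resid))
        return S_L, S_I

    def _update_variance_and_dependence(self):
        # nu2: conjugate inverse-gamma
        S_L, S_I = self._car_quadratics()
        S = self.rho * S_L + (1.0 - self.rho) * S_I
        self.nu2 = sample_invgamma(
            self.rng, self.a0 + self.K * self.T / 2.0, self.b0 + 0.5 * S
        )

        # gamma: conjugate Gaussian truncated to [0, 1]
        if self.T > 1:
            Qphi = self._Q_mat(self.phi)
            a = float(np.sum(self.phi[:, :-1] * Qphi[:, :-1]))
            b = float(np.sum(self.phi[:, 1:] * Qphi[:, :-1]))
            if a > 1e-12:
                self.gamma = sample_truncnorm01(
                    self.rng, b / a, float(np.sqrt(self.nu2 / a))
                )
            else:
                self.gamma = self.rng.uniform()
        else:
            self.gamma = self.rng.uniform()

        # rho: logit random walk; determinant via Laplacian eigenvalues
        step = self.steps["rho"]
        S_L, S_I = self._car_quadratics()

        def rho_logpost(r):
            if not (0.0 < r < 1.0):
                return -np.inf
            logdet = np.sum(np.log(r * self.lap_eigs + (1.0 - r)))
            quad = (r * S_L + (1.0 - r) * S_I) / (2.0 * self.nu2)
            return 0.5 * self.T * logdet - quad + np.log(r) + np.log(1.0 - r)

        logit = np.log(self.rho / (1.0 - self.rho))
        r_new = 1.0 / (1.0 + np.exp(-(logit + step.scale * self.rng.standard_normal())))
        logr = rho_logpost(r_new) - rho_logpost(self.rho)
        accept = np.isfinite(logr) and np.log(self.rng.uniform()) < logr
        if accept:
            self.rho = float(r_new)
            self._acc["rho"] += 1
        step.update(1.0 if accept else 0.0)

    def _update_latent(self):
        # latent true exposure of pollutant 1: log-scale random walk, all cells
        # at once (conditionally independent given the parameters)
        step = self.steps["x"]
        z = self.rng.standard_normal((self.K, self.T))
        xn = self.x * np.exp(step.scale * z)
        off_x = self.eta - self.x * self.lam

        def x_logpost(xv):
            with np.errstate(over="ignore", divide="ignore"):
                ll = self.Y * self.lam * xv - self.E * np.exp(off_x + self.lam * xv)
                me = -self.h * np.log(xv) - (
                    self.S2 - 2.0 * xv * self.S1 + self.h * xv**2
                ) / (2.0 * self.sigma_p2 * xv**2)
                pr = -((xv - self.mu_x) ** 2) / (2.0 * self.s2_x)
            return ll + me + pr

        logr = x_logpost(xn) - x_logpost(self.x) + np.log(xn) - np.log(self.x)
        accept = np.log(self.rng.uniform(size=(self.K, self.T))) < np.where(
            np.isfinite(logr), logr, -np.inf
        )
        self.x = np.where(accept, xn, self.x)
        self.eta = off_x + self.x * self.lam
        self.offset = self.eta - self.phi
        step.update(float(accept.mean()))

        # sigma_p2: conjugate inverse-gamma given the latent exposures
        ss = float(
            np.sum((self.S2 - 2.0 * self.x * self.S1 + self.h * self.x**2) / self.x**2)
        )
        self.sigma_p2 = sample_invgamma(
            self.rng, self.a0 + self.h * self.K * self.T / 2.0, self.b0 + 0.5 * max(ss, 0.0)
        )

        # latent residual exposure: symmetric random walk, all cells at once
        step = self.steps["eps"]
        en = self.eps + step.scale * self.rng.standard_normal((self.K, self.T))
        off_e = self.eta - self.eps * self.lam_r

        def e_logpost(ev):
            with np.errstate(over="ignore"):
                ll = self.Y * self.lam_r * ev - self.E * np.exp(off_e + self.lam_r * ev)
                me = -(self.h * ev**2 - 2.0 * ev * self.T1) / (2.0 * self.sigma_r2)
                pr = -((ev - self.mu_e) ** 2) / (2.0 * self.s2_e)
            return ll + me + pr

        logr = e_logpost(en) - e_logpost(self.eps)
        accept = np.log(self.rng.uniform(size=(self.K, self.T))) < np.where(
            np.isfinite(logr), logr, -np.inf
        )
        self.eps = np.where(accept, en, self.eps)
        self.eta = off_e + self.eps * self.lam_r
        self.offset = self.eta - self.phi
        step.update(float(accept.mean()))

        # sigma_r2: conjugate inverse-gamma
        ss = float(np.sum(self.T2 - 2.0 * self.eps * self.T1 + self.h * self.eps**2))
        self.sigma_r2 = sample_invgamma(
            self.rng, self.a0 + self.h * self.K * self.T / 2.0, self.b0 + 0.5 * max(ss, 0.0)
        )

    def step(self):
        """One full MCMC sweep over every parameter block."""
        self._n_steps += 1
        for c in range(self.pb):
            self._mh_alpha(c)
        self.lam = self._mh_effect("lam", self.lam, self.x)
        self.lam_r = self._mh_effect("lam_r", self.lam_r, self.eps)
        self._update_phi()
        self._translation_moves()
        self._update_variance_and_dependence()
        if self.latent:
            self._update_latent()

    def run(self, progress: bool = False, store_phi: bool = False) -> DiseasePosterior:
        cfg = self.config
        n_keep = cfg.n_retained
        draws = {
            "alpha": np.empty((n_keep, self.pb)),
            "lam": np.empty(n_keep),
            "lam_r": np.empty(n_keep),
            "nu2": np.empty(n_keep),
            "rho": np.empty(n_keep),
            "gamma": np.empty(n_keep),
        }
        if self.latent:
            draws["sigma_p2"] = np.empty(n_keep)
            draws["sigma_r2"] = np.empty(n_keep)
        phi_store = np.empty((n_keep, self.K, self.T)) if store_phi else None
        phi_mean = np.zeros((self.K, self.T))
        for it in range(cfg.n_iterations):
            if it == cfg.n_burnin:
                self.freeze_adaptation()
            self.step()
            if it >= cfg.n_burnin:
                k = it - cfg.n_burnin
                draws["alpha"][k] = self.alpha
                draws["lam"][k] = self.lam
                draws["lam_r"][k] = self.lam_r
                draws["nu2"][k] = self.nu2
                draws["rho"][k] = self.rho
                draws["gamma"][k] = self.gamma
                if self.latent:
                    draws["sigma_p2"][k] = self.sigma_p2
                    draws["sigma_r2"][k] = self.sigma_r2
                phi_mean += self.phi
                if store_phi:
                    phi_store[k] = self.phi
            if progress and (it + 1) % 1000 == 0:
                logger.info("disease MCMC iteration %d / %d", it + 1, cfg.n_iterations)
        phi_mean /= n_keep
        n_it = max(self._n_steps, 1)
        acceptance = {k: v / n_it for k, v in self._acc.items()}
        return DiseasePosterior(
            model="um" if self.latent else "bm",
            alpha=draws["alpha"],
            lam=draws["lam"],
            lam_r=draws["lam_r"],
            nu2=draws["nu2"],
            rho=draws["rho"],
            gamma=draws["gamma"],
            sigma_p2=draws.get("sigma_p2"),
            sigma_r2=draws.get("sigma_r2"),
            phi_mean=phi_mean,
            covariate_names=list(self.health.covariate_names),
            acceptance=acceptance,
            phi=phi_store,
        )


# ---------------------------------------------------------------------------
# public fitting interfaces
# ---------------------------------------------------------------------------


def _coerce_x1(exposure, pollutant: int = 0) -> np.ndarray:
    from .fusion import ExposureEnsemble

    if isinstance(exposure, ExposureEnsemble):
        return exposure.pollutant_draws(pollutant)
    return np.asarray(exposure, dtype=float)


def _coerce_resid(resid) -> np.ndarray:
    if isinstance(resid, ResidualExposure):
        return resid.residuals
    return np.asarray(resid, dtype=float)


def fit_bm(
    health: HealthPanel,
    x1,
    resid,
    config: RunConfig,
    rng=None,
    store_phi: bool = False,
) -> DiseasePosterior:
    """Fit the baseline model: exposures enter as fixed point estimates.

    ``x1`` is the (K, T) posterior-mean first-pollutant exposure (the mean of
    the h stage-1 draws) and ``resid`` the (K, T) mean residual-pollutant
    exposure (or None to fit a single-pollutant model).
    """
    x1 = _coerce_x1(x1)
    if x1.ndim == 3:
        x1 = x1.mean(axis=-1)
    if resid is not None:
        resid = _coerce_resid(resid)
        if resid.ndim == 3:
            resid = resid.mean(axis=-1)
    sampler = DiseaseSampler(health, config, x1=x1, resid=resid, rng=rng)
    return sampler.run(store_phi=store_phi)


def fit_um(
    health: HealthPanel,
    x1_draws,
    resid_draws,
    config: RunConfig,
    rng=None,
    pollutant: int = 0,
    store_phi: bool = False,
) -> DiseasePosterior:
    """Fit the uncertainty model: exposures are latent behind measurement error.

    ``x1_draws`` is the (K, T, h) ensemble of first-pollutant draws (or an
    :class:`~airhealth.fusion.ExposureEnsemble`), ``resid_draws`` the (K, T, h)
    residual sets (or a :class:`ResidualExposure`); h must be at least 2.
    """
    x1_draws = _coerce_x1(x1_draws, pollutant)
    resid_draws = _coerce_resid(resid_draws)
    sampler = DiseaseSampler(
        health, config, x1_draws=x1_draws, resid_draws=resid_draws, rng=rng
    )
    return sampler.run(store_phi=store_phi)
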