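"""Stage 1: multivariate spatio-temporal pollution fusion model.

The model regresses monitored log concentrations of q pollutants at m sites
over T years on site type, dispersion-model (modelled) log concentrations and
temperature, with time-varying coefficients following a centred AR(1) process,
a between-pollutant covariance C shared across sites, and a year-specific
residual scale sigma_t^2 following a log-scale random walk:

    X^(t) ~ N( blockdiag(Z_1^(t), ..., Z_q^(t)) beta^(t),  sigma_t^2 C (x) I_m )
    beta_j^(t) ~ N( beta_j + kappa (beta_j^(t-1) - beta_j), tau^2 I )
    ln sigma_t^2 ~ N( ln sigma_{t-1}^2, delta^2 )

Sites are assumed independent across space after covariate adjustment; the
semivariogram diagnostic in this module checks that assumption on residuals.
Missing observations (sites that do not measure a pollutant in a year) are
treated as unknowns and drawn from their conditional Gaussians each sweep.

Inference is by a block Gibbs sampler with conjugate updates for the
regression coefficients, their long-run means, tau^2, delta^2 and C
(inverse-Wishart), and adaptive random-walk Metropolis steps for kappa (logit
scale) and ln sigma_t^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import invwishart

from ._mcmc import AdaptiveScale, sample_invgamma
from .io import GridCovariates, RunConfig, get_rng

logger = logging.getLogger("airhealth")

DESIGN_SITE_COLUMNS = ("kerbside", "roadside", "rural")  # urban background = reference


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class MonitoringPanel:
    """Monitoring observations on the log scale plus per-pollutant design matrices.

    ``X`` is (q, m, T) with entries defined only where ``observed`` is True.
    ``design`` (q, T, m, p), when built, holds the regression design for each
    pollutant and year: an intercept, site-type indicators, the log modelled
    concentration of that pollutant at the nearest grid point and temperature.
    """

    X: np.ndarray
    observed: np.ndarray
    sites: pd.DataFrame  # site_id, x, y, site_type
    years: np.ndarray
    pollutants: list
    design: np.ndarray | None = None
    design_columns: list = field(default_factory=list)

    def __post_init__(self):
        q, m, T = self.X.shape
        if self.observed.shape != (q, m, T):
            raise ValueError("observed mask must match X")
        if len(self.sites) != m or len(self.years) != T or len(self.pollutants) != q:
            raise ValueError("panel metadata inconsistent with X")
        if self.design is not None:
            p = self.design.shape[-1]
            if self.design.shape != (q, T, m, p):
                raise ValueError("design must be (q, T, m, p)")
            if not np.allclose(self.design[..., 0], 1.0):
                raise ValueError("design must carry a leading intercept column")

    @property
    def shape(self):
        return self.X.shape

    def coords(self) -> np.ndarray:
        return self.sites[["x", "y"]].to_numpy(dtype=float)

    def with_design(self, grid: GridCovariates) -> "MonitoringPanel":
        """Attach design matrices, assigning each site its nearest grid point."""
        if list(grid.pollutants) != list(self.pollutants):
            raise ValueError("grid and panel pollutants differ")
        if not np.array_equal(grid.years, self.years):
            raise ValueError("grid and panel years differ")
        q, m, T = self.X.shape
        nearest = grid.nearest_point(self.coords())
        dummies = np.zeros((m, len(DESIGN_SITE_COLUMNS)))
        for c, level in enumerate(DESIGN_SITE_COLUMNS):
            dummies[:, c] = (self.sites["site_type"] == level).to_numpy()
        p = 1 + len(DESIGN_SITE_COLUMNS) + 2
        Z = np.empty((q, T, m, p))
        for j in range(q):
            for t in range(T):
                Z[j, t, :, 0] = 1.0
                Z[j, t, :, 1:4] = dummies
                Z[j, t, :, 4] = np.log(grid.modelled[j, nearest, t])
                Z[j, t, :, 5] = grid.temperature[nearest, t]
        names = ["intercept", *DESIGN_SITE_COLUMNS, "log_modelled", "temperature"]
        return replace(self, design=Z, design_columns=names)

    def subset_pollutant(self, j: int) -> "MonitoringPanel":
        """Single-pollutant (q=1) view, e.g. for single- vs multi-pollutant comparisons."""
        return replace(
            self,
            X=self.X[j : j + 1].copy(),
            observed=self.observed[j : j + 1].copy(),
            pollutants=[self.pollutants[j]],
            design=None if self.design is None else self.design[j : j + 1].copy(),
        )

    def mask_entry(self, j: int, i: int, t: int) -> "MonitoringPanel":
        """Copy of the panel with one observation held out (marked missing)."""
        if not self.observed[j, i, t]:
            raise ValueError("cannot hold out an entry that is already missing")
        obs = self.observed.copy()
        obs[j, i, t] = False
        return replace(self, X=self.X.copy(), observed=obs)


@dataclass
class FusionPosterior:
    """Posterior draws from :func:`fit_fusion` (one row per retained iteration)."""

    beta: np.ndarray  # (n, T, q, p)
    beta_bar: np.ndarray  # (n, q, p)
    kappa: np.ndarray  # (n,)
    C: np.ndarray  # (n, q, q)
    sigma2: np.ndarray  # (n, T)
    tau2: np.ndarray  # (n,)
    delta2: np.ndarray  # (n,)
    imputed: np.ndarray  # (n, n_missing) log-scale draws of missing entries
    missing_entries: list  # [(j, i, t), ...] aligned with imputed columns
    years: np.ndarray
    pollutants: list
    design_columns: list
    acceptance: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def imputed_draws(self, j: int, i: int, t: int) -> np.ndarray:
        """Posterior (predictive) draws of one held-out/missing log concentration."""
        try:
            col = self.missing_entries.index((j, i, t))
        except ValueError:
            raise KeyError(f"entry {(j, i, t)} was not missing in the fitted panel")
        return self.imputed[:, col]

    def to_frame(self) -> pd.DataFrame:
        n, T, q, p = self.beta.shape
        cols = {}
        for t in range(T):
            for j in range(q):
                for c in range(p):
                    cols[f"beta[t{t},{self.pollutants[j]},{self.design_columns[c]}]"] = (
                        self.beta[:, t, j, c]
                    )
        for j in range(q):
            for c in range(p):
                cols[f"beta_bar[{self.pollutants[j]},{self.design_columns[c]}]"] = (
                    self.beta_bar[:, j, c]
                )
        cols["kappa"] = self.kappa
        for j in range(q):
            for j2 in range(j, q):
                cols[f"C[{j},{j2}]"] = self.C[:, j, j2]
        for t in range(T):
            cols[f"sigma2[t{t}]"] = self.sigma2[:, t]
        cols["tau2"] = self.tau2
        cols["delta2"] = self.delta2
        for col, (j, i, t) in enumerate(self.missing_entries):
            cols[f"imputed[{self.pollutants[j]},s{i},t{t}]"] = self.imputed[:, col]
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, years, pollutants: list, design_columns: list
    ) -> "FusionPosterior":
        """Rebuild a posterior from :meth:`to_frame` output plus its metadata."""
        years = np.asarray(years)
        T, q, p = len(years), len(pollutants), len(design_columns)
        n = len(df)
        beta = np.empty((n, T, q, p))
        beta_bar = np.empty((n, q, p))
        for t in range(T):
            for j, pol in enumerate(pollutants):
                for c, name in enumerate(design_columns):
                    beta[:, t, j, c] = df[f"beta[t{t},{pol},{name}]"]
        for j, pol in enumerate(pollutants):
            for c, name in enumerate(design_columns):
                beta_bar[:, j, c] = df[f"beta_bar[{pol},{name}]"]
        C = np.empty((n, q, q))
        for j in range(q):
            for j2 in range(j, q):
                C[:, j, j2] = C[:, j2, j] = df[f"C[{j},{j2}]"]
        sigma2 = np.column_stack([df[f"sigma2[t{t}]"] for t in range(T)])
        missing_entries = []
        imp_cols = []
        pol_index = {pol: j for j, pol in enumerate(pollutants)}
        for col in df.columns:
            if col.startswith("imputed["):
                pol, si, ti = col[len("imputed[") : -1].split(",")
                missing_entries.append((pol_index[pol], int(si[1:]), int(ti[1:])))
                imp_cols.append(col)
        imputed = (
            df[imp_cols].to_numpy(dtype=float) if imp_cols else np.empty((n, 0))
        )
        return cls(
            beta=beta,
            beta_bar=beta_bar,
            kappa=df["kappa"].to_numpy(dtype=float),
            C=C,
            sigma2=sigma2,
            tau2=df["tau2"].to_numpy(dtype=float),
            delta2=df["delta2"].to_numpy(dtype=float),
            imputed=imputed,
            missing_entries=missing_entries,
            years=years,
            pollutants=list(pollutants),
            design_columns=list(design_columns),
        )


@dataclass
class ExposureEnsemble:
    """Posterior exposure draws on the natural scale.

    ``values`` is (n_locations, T, q, h): grid points before aggregation,
    areas after.  ``metric`` records the spatial aggregation used ("point"
    before aggregation, else "mean" or "max").
    """

    values: np.ndarray
    years: np.ndarray
    pollutants: list
    metric: str = "point"

    def __post_init__(self):
        if self.values.ndim != 4:
            raise ValueError("values must be (n_locations, T, q, h)")
        if np.any(self.values <= 0):
            raise ValueError("exposure values must be positive (natural scale)")

    @property
    def h(self) -> int:
        return self.values.shape[-1]

    def pollutant_draws(self, j: int) -> np.ndarray:
        """(n_locations, T, h) draws for one pollutant."""
        return self.values[:, :, j, :]

    def posterior_mean(self) -> np.ndarray:
        return self.values.mean(axis=-1)

    def summary(self) -> pd.DataFrame:
        n_loc, T, q, _ = self.values.shape
        lo, hi = np.percentile(self.values, [2.5, 97.5], axis=-1)
        mean = self.posterior_mean()
        rows = []
        for k in range(n_loc):
            for t in range(T):
                for j in range(q):
                    rows.append(
                        {
                            "area": k,
                            "year": self.years[t],
                            "pollutant": self.pollutants[j],
                            "mean": mean[k, t, j],
                            "lower_2.5": lo[k, t, j],
                            "upper_97.5": hi[k, t, j],
                        }
                    )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# conditional-distribution building blocks (exposed for verification)
# ---------------------------------------------------------------------------


def beta_time_conditional(
    t: int,
    ZtX_t: np.ndarray,
    G_t: np.ndarray,
    Cinv: np.ndarray,
    sigma2_t: float,
    beta: np.ndarray,
    beta_bar: np.ndarray,
    kappa: float,
    tau2: float,
    T: int,
):
    """Full conditional N(mean, cov) of the stacked coefficient vector beta^(t).

    ``ZtX_t[j, j']`` is Z_j' X_j' (p-vector) and ``G_t[j, j']`` is Z_j' Z_j'
    (p x p) for year t; ``beta`` is the full (T, q, p) current state.
    """
    q, p = beta_bar.shape
    P = np.zeros((q * p, q * p))
    ell = np.zeros(q * p)
    for j in range(q):
        for j2 in range(q):
            w = Cinv[j, j2] / sigma2_t
            P[j * p : (j + 1) * p, j2 * p : (j2 + 1) * p] = w * G_t[j, j2]
            ell[j * p : (j + 1) * p] += w * ZtX_t[j, j2]
    b = beta_bar.ravel()
    if T == 1:
        prior_prec = 1.0 / tau2
        prior_lin = b / tau2
    elif t == 0:
        nxt = beta[1].ravel()
        prior_prec = (1.0 + kappa**2) / tau2
        prior_lin = (b + kappa * (nxt - (1.0 - kappa) * b)) / tau2
    elif t == T - 1:
        mu = b + kappa * (beta[t - 1].ravel() - b)
        prior_prec = 1.0 / tau2
        prior_lin = mu / tau2
    else:
        mu = b + kappa * (beta[t - 1].ravel() - b)
        nxt = beta[t + 1].ravel()
        prior_prec = (1.0 + kappa**2) / tau2
        prior_lin = (mu + kappa * (nxt - (1.0 - kappa) * b)) / tau2
    P[np.diag_indices_from(P)] += prior_prec
    ell += prior_lin
    cov = np.linalg.inv(P)
    return cov @ ell, cov


def conditional_gaussian(mu, cov, observed_idx, observed_values):
    """Mean and covariance of the missing block of N(mu, cov) given observations.

    Standard multivariate-normal conditioning; with no observed components the
    marginal (mu, cov) of the missing block is returned.
    """
    mu = np.asarray(mu, dtype=float)
    cov = np.asarray(cov, dtype=float)
    all_idx = np.arange(mu.size)
    miss_idx = np.setdiff1d(all_idx, observed_idx)
    if len(observed_idx) == 0:
        return miss_idx, mu[miss_idx], cov[np.ix_(miss_idx, miss_idx)]
    o = np.asarray(observed_idx, dtype=int)
    Soo = cov[np.ix_(o, o)]
    Smo = cov[np.ix_(miss_idx, o)]
    Smm = cov[np.ix_(miss_idx, miss_idx)]
    sol = np.linalg.solve(Soo, np.asarray(observed_values, dtype=float) - mu[o])
    w = np.linalg.solve(Soo, Smo.T).T
    return miss_idx, mu[miss_idx] + Smo @ sol, Smm - w @ Smo.T


def impute_missing_step(X, observed, mean, C, sigma2, rng):
    """One sweep of conditional-Gaussian draws for all missing entries.

    For each (site, year) the q-vector of log concentrations is
    N(mean[:, i, t], sigma2[t] * C); missing components are drawn given the
    observed ones (or from the marginal when nothing is observed there).
    Returns an updated copy of ``X``.
    """
    X = np.asarray(X, dtype=float).copy()
    observed = np.asarray(observed, dtype=bool)
    q, m, T = X.shape
    sigma2 = np.broadcast_to(np.asarray(sigma2, dtype=float), (T,))
    for t in range(T):
        cov = sigma2[t] * C
        for i in range(m):
            miss = np.flatnonzero(~observed[:, i, t])
            if miss.size == 0:
                continue
            obs = np.flatnonzero(observed[:, i, t])
            _, mu_c, cov_c = conditional_gaussian(
                mean[:, i, t], cov, obs, X[obs, i, t]
            )
            if miss.size == 1:
                X[miss[0], i, t] = rng.normal(mu_c[0], np.sqrt(cov_c[0, 0]))
            else:
                X[miss, i, t] = rng.multivariate_normal(mu_c, cov_c)
    return X


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_FIXABLE = ("kappa", "C", "sigma2", "tau2", "delta2", "beta_bar")


def fit_fusion(
    panel: MonitoringPanel,
    config: RunConfig,
    rng=None,
    fix: dict | None = None,
    progress: bool = False,
) -> FusionPosterior:
    """Fit the multivariate fusion model by MCMC and return all retained draws.

    ``fix`` maps parameter names (any of kappa, C, sigma2, tau2, delta2,
    beta_bar) to values held constant, which is useful for conjugate-update
    verification and degenerate-limit checks.
    """
    fix = dict(fix or {})
    unknown = set(fix) - set(_FIXABLE)
    if unknown:
        raise ValueError(f"cannot fix parameter(s) {sorted(unknown)}")
    if panel.design is None:
        raise ValueError("panel has no design matrices; call with_design() first")
    q, m, T = panel.X.shape
    p = panel.design.shape[-1]
    if T > 1 and not np.all(np.diff(panel.years) == 1):
        raise ValueError("panel years must be contiguous")
    for j in range(q):
        if not panel.observed[j].any():
            raise ValueError(f"pollutant {panel.pollutants[j]!r} has no observed values")
    if config.wishart_scale_multiplier <= 0:
        raise ValueError("Wishart scale must be positive definite")
    rng = get_rng(config.seed if rng is None else rng)

    Z = panel.design  # (q, T, m, p)
    X = panel.X.copy()
    obs_mask = panel.observed
    # fill missing entries with the pollutant-wise observed mean to start
    for j in range(q):
        X[j][~obs_mask[j]] = X[j][obs_mask[j]].mean()
    missing_entries = [tuple(e) for e in np.argwhere(~obs_mask)]
    miss_cells = sorted({(i, t) for _, i, t in missing_entries})

    # --- initial state --------------------------------------------------
    beta = np.zeros((T, q, p))
    for t in range(T):
        for j in range(q):
            Zt = Z[j, t]
            beta[t, j] = np.linalg.solve(
                Zt.T @ Zt + 1e-6 * np.eye(p), Zt.T @ X[j, :, t]
            )
    beta_bar = np.asarray(fix.get("beta_bar", beta.mean(axis=0)), dtype=float)
    kappa = float(fix.get("kappa", 0.5))
    C = np.atleast_2d(np.asarray(fix.get("C", np.eye(q)), dtype=float)).astype(float)
    sigma2 = np.broadcast_to(
        np.asarray(fix.get("sigma2", np.ones(T)), dtype=float), (T,)
    ).copy()
    tau2 = float(fix.get("tau2", 1.0))
    delta2 = float(fix.get("delta2", 1.0))

    G = np.empty((T, q, q, p, p))
    for t in range(T):
        for j in range(q):
            for j2 in range(q):
                G[t, j, j2] = Z[j, t].T @ Z[j2, t]

    a0, b0 = config.ig_shape, config.ig_scale
    gpv = config.gaussian_prior_variance
    iw_df = config.wishart_df if config.wishart_df is not None else q
    iw_scale = config.wishart_scale_multiplier * np.eye(q)

    n_keep = config.n_retained
    out = {
        "beta": np.empty((n_keep, T, q, p)),
        "beta_bar": np.empty((n_keep, q, p)),
        "kappa": np.empty(n_keep),
        "C": np.empty((n_keep, q, q)),
        "sigma2": np.empty((n_keep, T)),
        "tau2": np.empty(n_keep),
        "delta2": np.empty(n_keep),
        "imputed": np.empty((n_keep, len(missing_entries))),
    }
    kappa_step = AdaptiveScale(init=0.5)
    sig_steps = [AdaptiveScale(init=0.3) for _ in range(T)]
    acc = {"kappa": 0, "sigma2": np.zeros(T)}

    def current_means():
        Mn = np.empty((q, m, T))
        for t in range(T):
            for j in range(q):
                Mn[j, :, t] = Z[j, t] @ beta[t, j]
        return Mn

    for it in range(config.n_iterations):
        if it == config.n_burnin:
            kappa_step.freeze()
            for s in sig_steps:
                s.freeze()
        M = current_means()

        # -- missing-value imputation (conditional Gaussians per site-year)
        if miss_cells:
            for (i, t) in miss_cells:
                miss = np.flatnonzero(~obs_mask[:, i, t])
                obs = np.flatnonzero(obs_mask[:, i, t])
                cov = sigma2[t] * C
                _, mu_c, cov_c = conditional_gaussian(
                    M[:, i, t], cov, obs, X[obs, i, t]
                )
                if miss.size == 1:
                    X[miss[0], i, t] = rng.normal(mu_c[0], np.sqrt(max(cov_c[0, 0], 0.0)))
                else:
                    L = np.linalg.cholesky(cov_c + 1e-12 * np.eye(miss.size))
                    X[miss, i, t] = mu_c + L @ rng.standard_normal(miss.size)

        # -- beta^(t) block Gibbs
        Cinv = np.linalg.inv(C)
        for t in range(T):
            ZtX = np.empty((q, q, p))
            for j in range(q):
                for j2 in range(q):
                    ZtX[j, j2] = Z[j, t].T @ X[j2, :, t]
            mean_t, cov_t = beta_time_conditional(
                t, ZtX, G[t], Cinv, sigma2[t], beta, beta_bar, kappa, tau2, T
            )
            L = np.linalg.cholesky(cov_t)
            beta[t] = (mean_t + L @ rng.standard_normal(q * p)).reshape(q, p)

        # -- long-run means
        if "beta_bar" not in fix:
            prec = (1.0 + (T - 1) * (1.0 - kappa) ** 2) / tau2 + 1.0 / gpv
            lin = beta[0].copy()
            if T > 1:
                lin += (1.0 - kappa) * (beta[1:] - kappa * beta[:-1]).sum(axis=0)
            lin /= tau2
            beta_bar = lin / prec + rng.standard_normal((q, p)) / np.sqrt(prec)

        # -- AR residual sum of squares, used by tau2 and kappa
        def ar_ss(k):
            ss = float(((beta[0] - beta_bar) ** 2).sum())
            if T > 1:
                resid = beta[1:] - beta_bar - k * (beta[:-1] - beta_bar)
                ss += float((resid**2).sum())
            return ss

        if "tau2" not in fix:
            tau2 = sample_invgamma(rng, a0 + q * p * T / 2.0, b0 + 0.5 * ar_ss(kappa))

        # -- kappa: random walk on the logit scale, U[0,1] prior
        if "kappa" not in fix:
            if T == 1:
                kappa = rng.uniform()
            else:
                def kappa_logpost(k):
                    if not (0.0 < k < 1.0):
                        return -np.inf
                    resid = beta[1:] - beta_bar - k * (beta[:-1] - beta_bar)
                    return -float((resid**2).sum()) / (2.0 * tau2) + np.log(k) + np.log(1.0 - k)

                logit = np.log(kappa / (1.0 - kappa))
                prop = logit + kappa_step.scale * rng.standard_normal()
                k_new = 1.0 / (1.0 + np.exp(-prop))
                lr = kappa_logpost(k_new) - kappa_logpost(kappa)
                accept = np.log(rng.uniform()) < lr
                if accept:
                    kappa = k_new
                    acc["kappa"] += 1
                kappa_step.update(1.0 if accept else 0.0)

        # -- between-pollutant covariance: inverse-Wishart conjugate update
        M = current_means()
        R = X - M  # (q, m, T)
        if "C" not in fix:
            S = iw_scale.copy()
            for t in range(T):
                Rt = R[:, :, t]
                S += (Rt @ Rt.T) / sigma2[t]
            C = np.atleast_2d(
                invwishart.rvs(df=iw_df + m * T, scale=S, random_state=rng)
            )
            Cinv = np.linalg.inv(C)

        # -- sigma_t^2: MH on theta_t = ln sigma_t^2 with the RW(1) prior
        if "sigma2" not in fix:
            theta = np.log(sigma2)
            s_stat = np.array(
                [float(np.sum(R[:, :, t] * (Cinv @ R[:, :, t]))) for t in range(T)]
            )
            for t in range(T):
                def theta_logpost(th):
                    lp = -0.5 * m * q * th - 0.5 * s_stat[t] * np.exp(-th)
                    if t > 0:
                        lp -= (th - theta[t - 1]) ** 2 / (2.0 * delta2)
                    if t < T - 1:
                        lp -= (theta[t + 1] - th) ** 2 / (2.0 * delta2)
                    return lp

                prop = theta[t] + sig_steps[t].scale * rng.standard_normal()
                lr = theta_logpost(prop) - theta_logpost(theta[t])
                accept = np.log(rng.uniform()) < lr
                if accept:
                    theta[t] = prop
                    acc["sigma2"][t] += 1
                sig_steps[t].update(1.0 if accept else 0.0)
            sigma2 = np.exp(theta)

        # -- delta^2
        if "delta2" not in fix:
            if T > 1:
                dth = np.diff(np.log(sigma2))
                delta2 = sample_invgamma(
                    rng, a0 + (T - 1) / 2.0, b0 + 0.5 * float((dth**2).sum())
                )
            else:
                delta2 = sample_invgamma(rng, a0, b0)

        if it >= config.n_burnin:
            k = it - config.n_burnin
            out["beta"][k] = beta
            out["beta_bar"][k] = beta_bar
            out["kappa"][k] = kappa
            out["C"][k] = C
            out["sigma2"][k] = sigma2
            out["tau2"][k] = tau2
            out["delta2"][k] = delta2
            for col, (j, i, t) in enumerate(missing_entries):
                out["imputed"][k, col] = X[j, i, t]
        if progress and (it + 1) % 1000 == 0:
            logger.info("fusion MCMC iteration %d / %d", it + 1, config.n_iterations)

    acceptance = {
        "kappa": acc["kappa"] / max(config.n_iterations, 1),
        "sigma2": (acc["sigma2"] / max(config.n_iterations, 1)).tolist(),
    }
    return FusionPosterior(
        beta=out["beta"],
        beta_bar=out["beta_bar"],
        kappa=out["kappa"],
        C=out["C"],
        sigma2=out["sigma2"],
        tau2=out["tau2"],
        delta2=out["delta2"],
        imputed=out["imputed"],
        missing_entries=missing_entries,
        years=panel.years,
        pollutants=list(panel.pollutants),
        design_columns=list(panel.design_columns),
        acceptance=acceptance,
    )


# ---------------------------------------------------------------------------
# prediction and aggregation
# ---------------------------------------------------------------------------


def predict_points(
    posterior: FusionPosterior,
    grid: GridCovariates,
    config: RunConfig,
    rng=None,
    include_noise: bool = True,
) -> ExposureEnsemble:
    """Draw ``h`` posterior predictive concentrations at every grid point.

    Every ceil(n_draws / h)-th retained posterior draw is used; at each point
    the q-vector is drawn from N(Z beta^(t), sigma_t^2 C) (the residual noise
    can be suppressed with ``include_noise=False`` to obtain exp(Z beta^(t)))
    and exponentiated back to the natural scale.
    """
    if list(grid.pollutants) != list(posterior.pollutants):
        raise ValueError("grid pollutants do not match the fitted model")
    if not np.array_equal(grid.years, posterior.years):
        raise ValueError("grid years do not match the fitted model")
    rng = get_rng(config.seed + 1 if rng is None else rng)
    n_draws = posterior.n_draws
    h = min(config.h, n_draws)
    stride = max(1, n_draws // h)
    sel = np.arange(h) * stride

    n = len(grid.points)
    q = len(grid.pollutants)
    T = len(grid.years)
    p = posterior.beta.shape[-1]
    rural = (grid.points["site_type"] == "rural").to_numpy(dtype=float)
    Zg = np.empty((q, T, n, p))
    for j in range(q):
        for t in range(T):
            Zg[j, t, :, 0] = 1.0
            Zg[j, t, :, 1] = 0.0  # kerbside: never a prediction location
            Zg[j, t, :, 2] = 0.0  # roadside: never a prediction location
            Zg[j, t, :, 3] = rural
            Zg[j, t, :, 4] = np.log(grid.modelled[j, :, t])
            Zg[j, t, :, 5] = grid.temperature[:, t]

    values = np.empty((n, T, q, h))
    for i, d in enumerate(sel):
        for t in range(T):
            mean = np.stack([Zg[j, t] @ posterior.beta[d, t, j] for j in range(q)], axis=1)
            if include_noise:
                L = np.linalg.cholesky(
                    posterior.sigma2[d, t] * posterior.C[d]
                    + 1e-12 * np.eye(q)
                )
                mean = mean + rng.standard_normal((n, q)) @ L.T
            values[:, t, :, i] = np.exp(mean)
    return ExposureEnsemble(
        values=values, years=grid.years, pollutants=list(grid.pollutants), metric="point"
    )


def aggregate_exposure(
    ensemble: ExposureEnsemble,
    assignments: np.ndarray,
    n_areas: int,
    metric: str = "mean",
    grid_coords: np.ndarray | None = None,
    area_centroids: np.ndarray | None = None,
) -> ExposureEnsemble:
    """Aggregate grid-level draws to areas, draw by draw.

    ``assignments`` gives the area index of each grid point (-1 for points in
    no area).  The spatial mean averages member points within each area per
    draw; the spatial max takes their maximum.  An area containing no grid
    point falls back to the closest prediction location to its centroid, for
    both metrics.
    """
    if metric not in ("mean", "max"):
        raise ValueError("metric must be 'mean' or 'max'")
    assignments = np.asarray(assignments, dtype=int)
    n_pts = ensemble.values.shape[0]
    if assignments.shape != (n_pts,):
        raise ValueError("assignments must give one area per grid point")
    out = np.empty((n_areas,) + ensemble.values.shape[1:])
    for k in range(n_areas):
        members = np.flatnonzero(assignments == k)
        if members.size == 0:
            if grid_coords is None or area_centroids is None:
                raise ValueError(
                    f"area {k} contains no prediction location and no coordinates "
                    "were supplied to find the closest one"
                )
            d2 = ((grid_coords - area_centroids[k]) ** 2).sum(axis=1)
            out[k] = ensemble.values[int(np.argmin(d2))]
        elif metric == "mean":
            out[k] = ensemble.values[members].mean(axis=0)
        else:
            out[k] = ensemble.values[members].max(axis=0)
    return ExposureEnsemble(
        values=out,
        years=ensemble.years,
        pollutants=list(ensemble.pollutants),
        metric=metric,
    )


# ---------------------------------------------------------------------------
# spatial-independence diagnostic
# ---------------------------------------------------------------------------


@dataclass
class SemivariogramResult:
    """Binned empirical semivariogram with a Monte-Carlo independence envelope."""

    bin_centers: np.ndarray
    gamma: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_pairs: np.ndarray
    inside_envelope: bool


def residual_semivariogram(
    residuals: np.ndarray,
    coords: np.ndarray,
    n_bins: int = 10,
    n_sims: int = 199,
    rng=None,
    alpha: float = 0.05,
) -> SemivariogramResult:
    """Empirical semivariogram of residuals with a permutation envelope.

    gamma(b) averages 0.5 (z_i - z_j)^2 over site pairs whose separation falls
    in distance bin b.  The envelope is built by randomly permuting residuals
    over locations ``n_sims`` times, which simulates the spatial-independence
    null; the empirical curve lying inside the envelope at every populated bin
    is consistent with no residual spatial autocorrelation.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be at least 1")
    z = np.asarray(residuals, dtype=float).ravel()
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] != z.size:
        raise ValueError("residuals and coordinates must align")
    if np.unique(coords, axis=0).shape[0] < 2:
        raise ValueError("at least 2 distinct locations are required")
    rng = get_rng(rng)
    d = pdist(coords)
    iu, ju = np.triu_indices(z.size, k=1)
    edges = np.linspace(0.0, d.max() * (1 + 1e-12), n_bins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    n_pairs = np.bincount(which, minlength=n_bins)

    def binned_gamma(values):
        sq = 0.5 * (values[iu] - values[ju]) ** 2
        tot = np.bincount(which, weights=sq, minlength=n_bins)
        with np.errstate(invalid="ignore"):
            return np.where(n_pairs > 0, tot / np.maximum(n_pairs, 1), np.nan)

    gamma = binned_gamma(z)
    sims = np.empty((n_sims, n_bins))
    for s in range(n_sims):
        sims[s] = binned_gamma(rng.permutation(z))
    lower = np.nanpercentile(sims, 100 * alpha / 2, axis=0)
    upper = np.nanpercentile(sims, 100 * (1 - alpha / 2), axis=0)
    ok = n_pairs > 0
    inside = bool(np.all((gamma[ok] >= lower[ok]) & (gamma[ok] <= upper[ok])))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return SemivariogramResult(
        bin_centers=centers,
        gamma=gamma,
        lower=lower,
        upper=upper,
        n_pairs=n_pairs,
        inside_envelope=inside,
    )
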