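"""Readers/writers, run configuration, logging and seed management.

All tabular formats are comma-separated UTF-8 with a header row.  Areal
adjacency is a plain-text edge list (one ``i j`` pair per line, 0-based)
preceded by a ``n_areas K`` header line.  Concentrations are stored on the
natural scale on disk and log-transformed on ingest, because the fusion model
operates on log concentrations throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

logger = logging.getLogger("airhealth")

#: Monitoring-site classification levels accepted on input.
SITE_TYPES = ("urban background", "kerbside", "roadside", "rural")
#: Levels permitted at prediction locations (grid squares are never kerb/road).
PREDICTION_SITE_TYPES = ("urban background", "rural")


def get_rng(seed) -> np.random.Generator:
    """Return a :class:`numpy.random.Generator` from a seed or pass one through."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_rngs(seed, n: int) -> list[np.random.Generator]:
    """Deterministically derive ``n`` independent generators from one seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# adjacency
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdjacencySpec:
    """Undirected areal adjacency: ``n_areas`` nodes and a set of border pairs.

    The neighbourhood matrix ``W`` is binary and symmetric with zero diagonal;
    ``W[i, j] = 1`` exactly when areas i and j share a border.
    """

    n_areas: int
    edges: frozenset

    def __post_init__(self):
        if self.n_areas <= 0:
            raise ValueError("n_areas must be positive")
        norm = set()
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-edge ({i},{i}) is not a valid border")
            if not (0 <= i < self.n_areas and 0 <= j < self.n_areas):
                raise ValueError(f"edge ({i},{j}) outside [0, {self.n_areas})")
            norm.add((min(i, j), max(i, j)))
        object.__setattr__(self, "edges", frozenset(norm))
        iso = self.isolated_areas()
        if iso.size:
            logger.warning("adjacency has %d isolated area(s): %s", iso.size, iso[:10])

    def W(self, sparse: bool = True):
        """Binary neighbourhood matrix (CSR if ``sparse`` else dense)."""
        n = self.n_areas
        if self.edges:
            ij = np.array(sorted(self.edges))
            rows = np.concatenate([ij[:, 0], ij[:, 1]])
            cols = np.concatenate([ij[:, 1], ij[:, 0]])
            W = sp.csr_array(
                (np.ones(rows.size), (rows, cols)), shape=(n, n), dtype=float
            )
        else:
            W = sp.csr_array((n, n), dtype=float)
        return W if sparse else W.toarray()

    def degrees(self) -> np.ndarray:
        return np.asarray(self.W().sum(axis=1)).ravel()

    def isolated_areas(self) -> np.ndarray:
        return np.flatnonzero(self.degrees() == 0)


def read_adjacency(path) -> AdjacencySpec:
    """Read an edge-list adjacency file.

    First non-comment line must be ``n_areas K``; every further line is an
    unordered 0-based pair ``i j``.
    """
    n_areas = None
    edges = set()
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if n_areas is None:
                if parts[0] != "n_areas" or len(parts) != 2:
                    raise ValueError("first line must be 'n_areas K'")
                n_areas = int(parts[1])
                continue
            if len(parts) != 2:
                raise ValueError(f"malformed edge line: {line!r}")
            edges.add((int(parts[0]), int(parts[1])))
    if n_areas is None:
        raise ValueError("empty adjacency file: missing 'n_areas K' header")
    return AdjacencySpec(n_areas=n_areas, edges=frozenset(edges))


def write_adjacency(adj: AdjacencySpec, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"n_areas {adj.n_areas}\n")
        for i, j in sorted(adj.edges):
            fh.write(f"{i} {j}\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """MCMC run settings and prior constants.

    Defaults follow standard practice for this model class: 50 000 iterations
    with a 20 000-iteration burn-in, and ``h=100`` exposure predictions taken
    at every 300th retained iteration.  Regression effects get N(0, 1000)
    priors, variances inverse-gamma(0.001, 0.001), the between-pollutant
    covariance an inverse-Wishart(df=q, scale=100 I), and the temporal and
    spatial dependence parameters uniform priors on [0, 1].
    """

    n_iterations: int = 50_000
    n_burnin: int = 20_000
    thin_for_predictions: int = 300
    h: int = 100
    seed: int = 0
    gaussian_prior_variance: float = 1000.0
    ig_shape: float = 0.001
    ig_scale: float = 0.001
    wishart_df: int | None = None  # defaults to q at fit time
    wishart_scale_multiplier: float = 100.0
    aggregation_metric: str = "mean"

    def __post_init__(self):
        for name in ("n_iterations", "n_burnin", "thin_for_predictions", "h"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise ValueError(f"{name} must be an integer, got {v!r}")
        if self.n_iterations <= 0 or self.thin_for_predictions <= 0 or self.h <= 0:
            raise ValueError("n_iterations, thin_for_predictions and h must be positive")
        if self.n_burnin < 0 or self.n_burnin >= self.n_iterations:
            raise ValueError(
                f"n_burnin ({self.n_burnin}) must satisfy 0 <= n_burnin < "
                f"n_iterations ({self.n_iterations})"
            )
        if self.h > (self.n_iterations - self.n_burnin) / self.thin_for_predictions:
            raise ValueError(
                "h must not exceed (n_iterations - n_burnin) / thin_for_predictions"
            )
        if self.gaussian_prior_variance <= 0 or self.ig_shape <= 0 or self.ig_scale <= 0:
            raise ValueError("prior constants must be positive")
        if self.aggregation_metric not in ("mean", "max"):
            raise ValueError("aggregation_metric must be 'mean' or 'max'")

    @property
    def n_retained(self) -> int:
        return self.n_iterations - self.n_burnin

    def replace(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def load_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from YAML (or JSON, a YAML subset).

    An empty file yields all defaults; unknown keys raise a ``ValueError``
    naming the offending key, as do keys set to null.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping of settings")
    known = {f.name for f in fields(RunConfig)}
    for key, value in raw.items():
        if key not in known:
            raise ValueError(f"unknown config key: {key!r} (allowed: {sorted(known)})")
        if value is None and key != "wishart_df":
            raise ValueError(f"config key {key!r} is required to have a value")
    return RunConfig(**raw)


def write_config(config: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# monitoring data
# ---------------------------------------------------------------------------

MONITORING_COLUMNS = ("site_id", "x", "y", "site_type", "year", "pollutant", "value")


def read_monitoring_panel(path):
    """Read a long-format monitoring CSV into a :class:`~airhealth.fusion.MonitoringPanel`.

    Columns: ``site_id, x, y, site_type, year, pollutant, value``; an empty
    ``value`` cell marks a missing observation.  Values are stored on the
    natural-log scale with an explicit observation mask.
    """
    from .fusion import MonitoringPanel  # container lives with the model

    df = pd.read_csv(path, float_precision="round_trip")
    missing_cols = [c for c in MONITORING_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"monitoring file missing column(s): {missing_cols}")
    bad_types = sorted(set(df["site_type"]) - set(SITE_TYPES))
    if bad_types:
        raise ValueError(
            f"unknown site_type value(s) {bad_types}; allowed: {list(SITE_TYPES)}"
        )
    dup = df.duplicated(subset=["site_id", "year", "pollutant"])
    if dup.any():
        rows = df.loc[dup, ["site_id", "year", "pollutant"]].head()
        raise ValueError(f"duplicate (site, year, pollutant) rows, e.g.\n{rows}")
    observed = df["value"].notna()
    if (df.loc[observed, "value"] <= 0).any():
        bad = df.loc[observed & (df["value"] <= 0)].head()
        raise ValueError(f"nonpositive concentration(s): log is undefined\n{bad}")

    sites = (
        df[["site_id", "x", "y", "site_type"]]
        .drop_duplicates()
        .sort_values("site_id")
        .reset_index(drop=True)
    )
    if sites["site_id"].duplicated().any():
        raise ValueError("a site_id maps to more than one (x, y, site_type)")
    years = np.array(sorted(df["year"].unique()))
    pollutants = sorted(df["pollutant"].unique())
    m, T, q = len(sites), len(years), len(pollutants)
    site_idx = {s: i for i, s in enumerate(sites["site_id"])}
    year_idx = {y: t for t, y in enumerate(years)}
    poll_idx = {p: j for j, p in enumerate(pollutants)}

    X = np.full((q, m, T), np.nan)
    mask = np.zeros((q, m, T), dtype=bool)
    obs = df[observed]
    j = obs["pollutant"].map(poll_idx).to_numpy()
    i = obs["site_id"].map(site_idx).to_numpy()
    t = obs["year"].map(year_idx).to_numpy()
    X[j, i, t] = np.log(obs["value"].to_numpy(dtype=float))
    mask[j, i, t] = True
    return MonitoringPanel(
        X=X, observed=mask, sites=sites, years=years, pollutants=pollutants
    )


def write_monitoring_panel(panel, path) -> None:
    """Inverse of :func:`read_monitoring_panel` (values back on natural scale)."""
    rows = []
    for j, pol in enumerate(panel.pollutants):
        for i in range(len(panel.sites)):
            for t, year in enumerate(panel.years):
                rows.append(
                    {
                        "site_id": panel.sites["site_id"].iloc[i],
                        "x": panel.sites["x"].iloc[i],
                        "y": panel.sites["y"].iloc[i],
                        "site_type": panel.sites["site_type"].iloc[i],
                        "year": year,
                        "pollutant": pol,
                        "value": np.exp(panel.X[j, i, t])
                        if panel.observed[j, i, t]
                        else np.nan,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# grid covariates
# ---------------------------------------------------------------------------

GRID_COLUMNS = ("point_id", "x", "y", "site_type", "year", "pollutant", "modelled", "temperature")


@dataclass
class GridCovariates:
    """Covariates at the gridded prediction points.

    ``modelled`` holds dispersion-model concentrations on the natural scale,
    indexed (pollutant, point, year); ``temperature`` is (point, year).
    """

    points: pd.DataFrame  # point_id, x, y, site_type
    years: np.ndarray
    pollutants: list
    modelled: np.ndarray  # (q, n_points, T), natural scale
    temperature: np.ndarray  # (n_points, T)

    def __post_init__(self):
        q, n, T = self.modelled.shape
        if self.temperature.shape != (n, T):
            raise ValueError("temperature shape must match (n_points, T)")
        if np.any(self.modelled <= 0):
            raise ValueError("modelled concentrations must be positive")
        bad = sorted(set(self.points["site_type"]) - set(PREDICTION_SITE_TYPES))
        if bad:
            raise ValueError(
                f"prediction locations must be one of {list(PREDICTION_SITE_TYPES)}, got {bad}"
            )

    @property
    def coords(self) -> np.ndarray:
        return self.points[["x", "y"]].to_numpy(dtype=float)

    def nearest_point(self, xy: np.ndarray) -> np.ndarray:
        """Index of the closest grid point to each row of ``xy`` (ties -> lowest index)."""
        d2 = ((xy[:, None, :] - self.coords[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)


def read_grid_covariates(path) -> GridCovariates:
    df = pd.read_csv(path, float_precision="round_trip")
    missing_cols = [c for c in GRID_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"grid file missing column(s): {missing_cols}")
    points = (
        df[["point_id", "x", "y", "site_type"]]
        .drop_duplicates()
        .sort_values("point_id")
        .reset_index(drop=True)
    )
    years = np.array(sorted(df["year"].unique()))
    pollutants = sorted(df["pollutant"].unique())
    q, n, T = len(pollutants), len(points), len(years)
    pidx = {p: i for i, p in enumerate(points["point_id"])}
    yidx = {y: t for t, y in enumerate(years)}
    jidx = {p: j for j, p in enumerate(pollutants)}
    modelled = np.full((q, n, T), np.nan)
    temperature = np.full((n, T), np.nan)
    jj = df["pollutant"].map(jidx).to_numpy()
    ii = df["point_id"].map(pidx).to_numpy()
    tt = df["year"].map(yidx).to_numpy()
    modelled[jj, ii, tt] = df["modelled"].to_numpy(dtype=float)
    temperature[ii, tt] = df["temperature"].to_numpy(dtype=float)
    if np.isnan(modelled).any() or np.isnan(temperature).any():
        raise ValueError("grid covariates must be complete for every point/year/pollutant")
    return GridCovariates(
        points=points, years=years, pollutants=pollutants,
        modelled=modelled, temperature=temperature,
    )


def write_grid_covariates(grid: GridCovariates, path) -> None:
    rows = []
    for j, pol in enumerate(grid.pollutants):
        for i in range(len(grid.points)):
            for t, year in enumerate(grid.years):
                rows.append(
                    {
                        "point_id": grid.points["point_id"].iloc[i],
                        "x": grid.points["x"].iloc[i],
                        "y": grid.points["y"].iloc[i],
                        "site_type": grid.points["site_type"].iloc[i],
                        "year": year,
                        "pollutant": pol,
                        "modelled": grid.modelled[j, i, t],
                        "temperature": grid.temperature[i, t],
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# health panel
# ---------------------------------------------------------------------------


def read_health_panel(path, adjacency: AdjacencySpec):
    """Read an areal health CSV (area, year, observed, expected, covariates...)."""
    from .disease import HealthPanel

    df = pd.read_csv(path, float_precision="round_trip")
    for c in ("area", "year", "observed", "expected"):
        if c not in df.columns:
            raise ValueError(f"health file missing column: {c}")
    covs = [c for c in df.columns if c not in ("area", "year", "observed", "expected")]
    years = np.array(sorted(df["year"].unique()))
    K, T = adjacency.n_areas, len(years)
    if len(df) != K * T or set(df["area"]) != set(range(K)):
        raise ValueError("health panel must contain every (area, year) exactly once")
    df = df.sort_values(["area", "year"])
    Y = df["observed"].to_numpy().reshape(K, T)
    E = df["expected"].to_numpy(dtype=float).reshape(K, T)
    B = np.stack(
        [df[c].to_numpy(dtype=float).reshape(K, T) for c in covs], axis=-1
    ) if covs else np.empty((K, T, 0))
    return HealthPanel(
        Y=Y, E=E, covariates=B, covariate_names=covs, adjacency=adjacency, years=years
    )


def write_health_panel(panel, path) -> None:
    K, T = panel.Y.shape
    rows = []
    for k in range(K):
        for t in range(T):
            row = {
                "area": k,
                "year": panel.years[t],
                "observed": panel.Y[k, t],
                "expected": panel.E[k, t],
            }
            for c, name in enumerate(panel.covariate_names):
                row[name] = panel.covariates[k, t, c]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# posterior samples and ensembles
# ---------------------------------------------------------------------------


def write_samples(posterior, path) -> None:
    """Write posterior draws to CSV, one column per scalar parameter.

    Floats are formatted with 17 significant digits, so a write/read round
    trip is bit-identical for IEEE double draws.
    """
    posterior.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_samples(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_ensemble(ensemble, path) -> None:
    """Write an :class:`~airhealth.fusion.ExposureEnsemble` as long-format CSV."""
    n_loc, T, q, h = ensemble.values.shape
    loc, t, j, i = np.meshgrid(
        np.arange(n_loc), np.arange(T), np.arange(q), np.arange(h), indexing="ij"
    )
    pd.DataFrame(
        {
            "area": loc.ravel(),
            "year": np.asarray(ensemble.years)[t.ravel()],
            "pollutant": np.asarray(ensemble.pollutants, dtype=object)[j.ravel()],
            "draw": i.ravel(),
            "value": ensemble.values.ravel(),
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_ensemble(path):
    from .fusion import ExposureEnsemble

    df = pd.read_csv(path, float_precision="round_trip")
    for c in ("area", "year", "pollutant", "draw", "value"):
        if c not in df.columns:
            raise ValueError(f"ensemble file missing column: {c}")
    areas = np.array(sorted(df["area"].unique()))
    years = np.array(sorted(df["year"].unique()))
    pollutants = sorted(df["pollutant"].unique())
    draws = np.array(sorted(df["draw"].unique()))
    shape = (len(areas), len(years), len(pollutants), len(draws))
    values = np.full(shape, np.nan)
    a = np.searchsorted(areas, df["area"].to_numpy())
    t = np.searchsorted(years, df["year"].to_numpy())
    j = pd.Categorical(df["pollutant"], categories=pollutants).codes
    i = np.searchsorted(draws, df["draw"].to_numpy())
    values[a, t, j, i] = df["value"].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("ensemble file is not a complete (area, year, pollutant, draw) grid")
    return ExposureEnsemble(values=values, years=years, pollutants=pollutants)
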