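"""Evaluation harnesses: fusion leave-one-out cross-validation and the
baseline-vs-uncertainty disease-model simulation study.

Both harnesses return tidy metric tables (bias, RMSE/RMSPE, mean 95%-interval
width, empirical coverage) plus the per-replicate / per-holdout records they
were aggregated from, so results can be audited and re-aggregated.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .disease import fit_bm, fit_um, relative_risk, residualize
from .fusion import MonitoringPanel, fit_fusion
from .io import RunConfig
from .synthetic import (
    ScenarioConfig,
    draw_error_prone_exposures,
    make_lattice,
    scenario_truth,
    simulate_true_exposures_and_counts,
)

logger = logging.getLogger("airhealth")

RECORD_COLUMNS = ("scenario", "model", "parameter", "truth", "estimate", "lower", "upper")


def summarize_metrics(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate replicate records into a metrics table.

    Per (scenario, model, parameter): bias = mean(estimate - truth), RMSE on
    the same scale, the mean width of the 95% intervals and the percentage of
    replicates whose interval covers the truth.
    """
    for c in RECORD_COLUMNS:
        if c not in records.columns:
            raise ValueError(f"records are missing column {c!r}")
    rows = []
    for (scen, model, param), g in records.groupby(
        ["scenario", "model", "parameter"], sort=True
    ):
        err = g["estimate"].to_numpy() - g["truth"].to_numpy()
        covered = (g["lower"] <= g["truth"]) & (g["truth"] <= g["upper"])
        rows.append(
            {
                "scenario": scen,
                "model": model,
                "parameter": param,
                "bias": float(err.mean()),
                "rmse": float(np.sqrt((err**2).mean())),
                "ci_width": float((g["upper"] - g["lower"]).mean()),
                "coverage": float(covered.mean() * 100.0),
                "n_replicates": len(g),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# disease-model simulation study (BM vs UM)
# ---------------------------------------------------------------------------


def run_bm_um_study(
    scenario: ScenarioConfig,
    progress: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the measurement-error simulation comparing models BM and UM.

    For each error level sigma1^2 and replicate: disease counts are generated
    from the baseline model at the scenario truths; error-prone exposure
    realisations are drawn around the (fixed, shared) true surfaces with the
    configured correlation; BM is fitted to a single realisation (and its
    residuals) while UM receives all h realisations through its
    measurement-error likelihoods.  Estimates are relative risks per one
    standard deviation of the true exposure scales.

    Returns ``(metrics, records)``; replicates whose MCMC fails are dropped
    with a logged count and reflected in ``n_replicates``.
    """
    adjacency = make_lattice(scenario.rows, scenario.cols)
    root = np.random.SeedSequence(scenario.seed)
    n_cells = len(scenario.sigma1_sq) * scenario.n_replicates
    children = root.spawn(1 + n_cells)
    truth_rng = np.random.default_rng(children[0])
    truth = scenario_truth(scenario, truth_rng)
    rr_truth = {"lambda": scenario.rr_lambda, "lambda_r": scenario.rr_lambda_r}
    sds = {"lambda": truth["sd1"], "lambda_r": truth["sd_r"]}

    config = RunConfig(
        n_iterations=scenario.n_iterations,
        n_burnin=scenario.n_burnin,
        thin_for_predictions=1,
        h=min(scenario.h, scenario.n_iterations - scenario.n_burnin),
        seed=scenario.seed,
    )
    records = []
    n_failed = 0
    for s_idx, sig2 in enumerate(scenario.sigma1_sq):
        for rep in range(scenario.n_replicates):
            ss = children[1 + s_idx * scenario.n_replicates + rep]
            rngs = [np.random.default_rng(c) for c in ss.spawn(4)]
            panel, _ = simulate_true_exposures_and_counts(
                scenario, adjacency, rngs[0], truth=truth
            )
            try:
                d1, d2 = draw_error_prone_exposures(
                    truth["X1"], truth["X2"], sig2, scenario.h, rngs[1],
                    correlation=scenario.error_correlation,
                )
                # BM: a single error-prone realisation stands in for the truth
                resid_bm = residualize(d1[:, :, :1], d2[:, :, :1])
                post_bm = fit_bm(
                    panel, d1[:, :, 0], resid_bm.residuals[:, :, 0], config, rng=rngs[2]
                )
                # UM: all h realisations through the measurement-error model
                resid_um = residualize(d1, d2)
                post_um = fit_um(panel, d1, resid_um, config, rng=rngs[3])
            except Exception:  # noqa: BLE001 - a failed replicate is excluded
                n_failed += 1
                logger.exception(
                    "replicate %d at sigma1^2=%g failed; excluded", rep, sig2
                )
                continue
            for model, post in (("BM", post_bm), ("UM", post_um)):
                for param, draws in (("lambda", post.lam), ("lambda_r", post.lam_r)):
                    rr = relative_risk(draws, sds[param])
                    records.append(
                        {
                            "scenario": sig2,
                            "replicate": rep,
                            "model": model,
                            "parameter": param,
                            "truth": rr_truth[param],
                            "estimate": rr.mean,
                            "lower": rr.lower,
                            "upper": rr.upper,
                        }
                    )
            if progress:
                logger.info(
                    "sigma1^2=%g replicate %d/%d done",
                    sig2,
                    rep + 1,
                    scenario.n_replicates,
                )
    if n_failed:
        logger.warning("%d replicate(s) failed and were excluded", n_failed)
    records = pd.DataFrame(records)
    metrics = summarize_metrics(records)
    metrics.attrs["n_failed"] = n_failed
    metrics.attrs["scale"] = {
        "areas": scenario.n_areas,
        "periods": scenario.n_periods,
        "replicates": scenario.n_replicates,
        "iterations": scenario.n_iterations,
    }
    return metrics, records


# ---------------------------------------------------------------------------
# fusion leave-one-out cross-validation
# ---------------------------------------------------------------------------


def prediction_metrics(records: pd.DataFrame) -> pd.DataFrame:
    """Bias, RMSPE and 95% coverage per pollutant from holdout records."""
    rows = []
    for pol, g in records.groupby("pollutant", sort=True):
        err = g["predicted"].to_numpy() - g["observed"].to_numpy()
        covered = (g["lower"] <= g["observed"]) & (g["observed"] <= g["upper"])
        rows.append(
            {
                "pollutant": pol,
                "bias": float(err.mean()),
                "rmspe": float(np.sqrt((err**2).mean())),
                "coverage": float(covered.mean() * 100.0),
                "n_heldout": len(g),
            }
        )
    return pd.DataFrame(rows)


def loocv_fusion(
    panel: MonitoringPanel,
    config: RunConfig,
    heldout: list | None = None,
    model: str = "multi",
    rng=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leave-one-out cross-validation of the fusion model on the log scale.

    Each held-out observation (default: every observed entry in the final
    year) is marked missing and the model refitted on the remaining data; the
    posterior draws of the held-out entry — its imputation draws — form the
    predictive distribution.  ``model="single"`` repeats the exercise with
    independent single-pollutant (q=1) fits, quantifying what borrowing
    strength across correlated pollutants buys.

    Returns ``(metrics, records)``: per-pollutant bias, RMSPE and coverage of
    the 95% predictive intervals, all on the natural-log scale.
    """
    if model not in ("multi", "single"):
        raise ValueError("model must be 'multi' or 'single'")
    if panel.design is None:
        raise ValueError("panel needs design matrices (call with_design first)")
    q, m, T = panel.X.shape
    for j in range(q):
        if panel.observed[j].sum() < 2:
            raise ValueError(
                f"pollutant {panel.pollutants[j]!r} has fewer than 2 observations"
            )
    if heldout is None:
        heldout = [
            (j, i, T - 1) for j in range(q) for i in range(m) if panel.observed[j, i, T - 1]
        ]
    seed_seq = np.random.SeedSequence(config.seed if rng is None else rng)
    child_seeds = seed_seq.spawn(len(heldout))
    records = []
    for (j, i, t), child in zip(heldout, child_seeds):
        fit_rng = np.random.default_rng(child)
        if model == "multi":
            masked = panel.mask_entry(j, i, t)
            post = fit_fusion(masked, config, rng=fit_rng)
            draws = post.imputed_draws(j, i, t)
        else:
            sub = panel.subset_pollutant(j)
            masked = sub.mask_entry(0, i, t)
            post = fit_fusion(masked, config, rng=fit_rng)
            draws = post.imputed_draws(0, i, t)
        lo, hi = np.percentile(draws, [2.5, 97.5])
        records.append(
            {
                "pollutant": panel.pollutants[j],
                "site": panel.sites["site_id"].iloc[i],
                "year": panel.years[t],
                "observed": float(panel.X[j, i, t]),
                "predicted": float(draws.mean()),
                "lower": float(lo),
                "upper": float(hi),
                "model": model,
            }
        )
    records = pd.DataFrame(records)
    return prediction_metrics(records), records
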