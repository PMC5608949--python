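"""Preprocessing chain for multifluid metabolomics matrices.

The stages, in their fixed order:

1. run-day filter        — drop features with too few measurements on too
                           many run days for valid medians
2. run-day normalization — divide by the per-(feature, run day) median
3. PQN                   — probabilistic quotient normalization of the
                           dilution-affected fluids (default urine, saliva)
4. log2 transform
5. multivariate outlier exclusion (robust PCA / Mahalanobis score, per fluid)
6. missingness filter    — drop features with > 20% missing values
7. censored-normal imputation per (feature, run day), fitted on the
   log2 *raw* (pre-normalization) values
8. predictive mean matching for the residual missing values

The output matrix is fully observed.  :func:`preprocess_pipeline` enforces
the ordering and collects per-stage bookkeeping into a
:class:`PreprocessReport`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._rng import substream
from .datatypes import IntensityMatrix

__all__ = [
    "PreprocessReport",
    "runday_filter",
    "runday_normalize",
    "pqn_normalize",
    "log2_transform",
    "detect_outliers",
    "missingness_filter",
    "fit_censored_normal",
    "impute_censored",
    "impute_pmm",
    "preprocess_pipeline",
]

log = logging.getLogger(__name__)


@dataclass
class PreprocessReport:
    """Bookkeeping of what each preprocessing stage dropped or filled in."""

    features_dropped_runday: list[str] = field(default_factory=list)
    features_dropped_missingness: list[str] = field(default_factory=list)
    samples_dropped_outlier: list[str] = field(default_factory=list)
    dilution_factors: dict[str, pd.Series] = field(default_factory=dict)
    imputation_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    censored_fits: dict[tuple[str, str], tuple[float, float, float]] = field(
        default_factory=dict
    )  # (feature, runday) -> (mu, sigma, censor point)

    def record_imputation(self, feature: str, kind: str, n: int) -> None:
        if n:
            d = self.imputation_counts.setdefault(
                feature, {"censored": 0, "pmm": 0, "marginal": 0}
            )
            d[kind] += n


# ---------------------------------------------------------------------------
# run-day handling
# ---------------------------------------------------------------------------

def runday_filter(x: IntensityMatrix, min_values: int = 3) -> tuple[IntensityMatrix, list[str]]:
    """Drop features with fewer than ``min_values`` measurements on more than
    half of the run days (strict inequality on both counts)."""
    days = x.runday.unique()
    n_days = len(days)
    if n_days == 0:
        raise ValueError("no run days")
    counts = x.values.notna().groupby(x.runday, observed=True).sum()  # days x features
    n_failing_days = (counts < min_values).sum(axis=0)
    dropped = sorted(n_failing_days.index[n_failing_days > n_days / 2])
    kept = [f for f in x.feature_ids if f not in set(dropped)]
    return x.select_features(kept), dropped


def runday_normalize(x: IntensityMatrix) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Rescale every value by the median of its feature on its run day.

    Returns the normalized matrix and the (run day x feature) median table,
    which the censored-imputation stage needs to map raw-scale fits back into
    normalized space.
    """
    medians = x.values.groupby(x.runday, observed=True).median()  # days x features
    per_cell = medians.loc[x.runday].set_axis(x.values.index)
    out = x.copy()
    out.values = x.values / per_cell
    return out, medians


# ---------------------------------------------------------------------------
# PQN
# ---------------------------------------------------------------------------

def pqn_normalize(
    x: IntensityMatrix, fluid: str
) -> tuple[IntensityMatrix, pd.Series]:
    """Probabilistic quotient normalization of one fluid's feature block.

    The reference pseudo-sample is the per-feature mean over samples, using
    only features of the block with no missing entries; each sample's
    dilution factor is the median of its quotients against the reference on
    those features, and every value of the sample in the block is divided by
    it.
    """
    block_cols = [f for f in x.feature_ids if x.fluid.loc[f] == fluid]
    if not block_cols:
        raise ValueError(f"no features in fluid {fluid!r}")
    block = x.values[block_cols]
    complete = block.columns[block.notna().all(axis=0)]
    if len(complete) == 0:
        raise ValueError(
            f"no feature with zero missingness in fluid {fluid!r}; "
            "cannot form a PQN reference (impute first or drop the fluid "
            "from the PQN list)"
        )
    reference = block[complete].mean(axis=0)  # per-feature mean
    quotients = block[complete] / reference
    dilution = quotients.median(axis=1)
    out = x.copy()
    out.values[block_cols] = block.div(dilution, axis=0)
    return out, dilution.rename(f"dilution_{fluid}")


# ---------------------------------------------------------------------------
# transforms and filters
# ---------------------------------------------------------------------------

def log2_transform(x: IntensityMatrix) -> IntensityMatrix:
    if x.log_scale:
        raise ValueError("matrix already log-transformed")
    arr = x.values.to_numpy(dtype=float)
    if np.any((arr <= 0) & ~np.isnan(arr)):
        raise ValueError("non-positive value; cannot log-transform")
    out = x.copy()
    out.values = np.log2(x.values)
    out.log_scale = True
    return out


def detect_outliers(
    x_complete: pd.DataFrame,
    threshold_sd: float = 4.0,
    var_explained: float = 0.99,
) -> list[str]:
    """Multivariate outlier score on a fully observed (log-scale) block.

    Robustly centers/scales each feature (median, scaled MAD), projects onto
    the principal components retaining ``var_explained`` of the variance, and
    scores each sample by its Mahalanobis-type distance in that space with
    per-component robust location/scale.  Samples whose score exceeds
    ``threshold_sd`` robust standard deviations above the median score are
    flagged.
    """
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")
    if x_complete.isna().any().any():
        raise ValueError("outlier detection requires a fully observed block")
    n, p = x_complete.shape
    if p < 3:
        raise ValueError("need at least 3 complete features")
    arr = x_complete.to_numpy(dtype=float)
    med = np.median(arr, axis=0)
    mad = stats.median_abs_deviation(arr, axis=0, scale="normal")
    mad[mad == 0] = 1.0
    z = (arr - med) / mad
    # classical PCA on the robustly scaled matrix
    u, s, vt = np.linalg.svd(z - z.mean(axis=0), full_matrices=False)
    var = s**2
    frac = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(frac, var_explained) + 1)
    k = min(k, min(n, p))
    scores = z @ vt[:k].T
    c_med = np.median(scores, axis=0)
    c_mad = stats.median_abs_deviation(scores, axis=0, scale="normal")
    c_mad[c_mad == 0] = 1.0
    d = np.sqrt(((scores - c_med) / c_mad) ** 2 @ np.ones(k))
    d_med = np.median(d)
    d_mad = stats.median_abs_deviation(d, scale="normal")
    if d_mad == 0:
        return []
    flagged = d > d_med + threshold_sd * d_mad
    return [str(s_) for s_ in x_complete.index[flagged]]


def missingness_filter(
    x: IntensityMatrix, max_frac: float = 0.20
) -> tuple[IntensityMatrix, list[str]]:
    """Drop features whose missing fraction strictly exceeds ``max_frac``."""
    frac = x.values.isna().mean(axis=0)
    dropped = sorted(frac.index[frac > max_frac])
    kept = [f for f in x.feature_ids if f not in set(dropped)]
    return x.select_features(kept), dropped


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def fit_censored_normal(
    observed: np.ndarray, n_censored: int, censor_point: float
) -> tuple[float, float]:
    """Maximum-likelihood fit of a left-censored normal.

    ``observed`` are the measured values; ``n_censored`` values are known
    only to lie at or below ``censor_point``.  Maximizes

        sum log phi((x - mu)/sigma)/sigma + n_censored * log Phi((c - mu)/sigma)

    over (mu, sigma > 0) and returns (mu_hat, sigma_hat).
    """
    obs = np.asarray(observed, dtype=float)
    mu0, sd0 = float(obs.mean()), float(obs.std(ddof=1)) if obs.size > 1 else 1.0
    if not np.isfinite(sd0) or sd0 <= 0:
        sd0 = 1.0

    def nll(params):
        mu, log_sd = params
        sd = np.exp(log_sd)
        ll = stats.norm.logpdf(obs, mu, sd).sum()
        if n_censored:
            ll += n_censored * stats.norm.logcdf(censor_point, mu, sd)
        return -ll

    res = optimize.minimize(
        nll, x0=[mu0, np.log(sd0)], method="Nelder-Mead",
        options={"maxiter": 2000, "maxfev": 4000, "xatol": 1e-6, "fatol": 1e-9},
    )
    if not res.success:
        raise RuntimeError("censored-normal MLE did not converge")
    mu, sd = float(res.x[0]), float(np.exp(res.x[1]))
    if sd < 1e-8:
        raise RuntimeError("degenerate censored-normal fit (sigma ~ 0)")
    return mu, sd


def impute_censored(
    x_log_raw: IntensityMatrix,
    seed: int = 0,
    min_observed: int = 10,
    report: PreprocessReport | None = None,
) -> tuple[IntensityMatrix, PreprocessReport]:
    """Left-censored-normal imputation per (feature, run day).

    Operates on log-transformed pre-normalization values.  For every
    (feature, run day) cell group with strictly more than ``min_observed``
    measured values, fits a left-censored normal (censor point = minimum
    observed value on that run day) and draws each missing value from the
    fitted normal truncated to (-inf, censor point].  Groups at or below the
    cutoff are left missing for predictive mean matching.
    """
    if not x_log_raw.log_scale:
        raise ValueError("censored imputation expects log-scale values")
    report = report or PreprocessReport()
    out = x_log_raw.copy()
    vals = out.values
    for feature in out.feature_ids:
        col = vals[feature]
        if not col.isna().any():
            continue
        for day, group in col.groupby(out.runday, observed=True):
            missing_idx = group.index[group.isna()]
            if len(missing_idx) == 0:
                continue
            observed = group.dropna().to_numpy()
            if observed.size <= min_observed:
                continue
            c = float(observed.min())
            try:
                mu, sd = fit_censored_normal(observed, len(missing_idx), c)
            except RuntimeError as err:  # pragma: no cover - rare numerics
                log.warning(
                    "censored fit failed for %s on %s (%s); left for PMM",
                    feature, day, err,
                )
                continue
            rng = substream(seed, "censored", str(feature), str(day))
            a = (-np.inf, (c - mu) / sd)
            draws = stats.truncnorm.rvs(
                a[0], a[1], loc=mu, scale=sd, size=len(missing_idx),
                random_state=rng,
            )
            vals.loc[missing_idx, feature] = draws
            report.censored_fits[(str(feature), str(day))] = (mu, sd, c)
            report.record_imputation(str(feature), "censored", len(missing_idx))
    return out, report


def impute_pmm(
    x: IntensityMatrix,
    donors: int = 5,
    n_predictors: int = 10,
    seed: int = 0,
    min_observed: int = 10,
    report: PreprocessReport | None = None,
) -> tuple[IntensityMatrix, PreprocessReport]:
    """Predictive mean matching for residual missing values.

    Each incomplete feature is regressed on its ``n_predictors``
    most-correlated complete features; every missing entry receives a draw
    from the ``donors`` observed values of the feature whose predicted means
    are closest to the missing entry's predicted mean.  Features with fewer
    than ``min_observed`` observed values fall back to a draw from their
    marginal empirical distribution.
    """
    report = report or PreprocessReport()
    out = x.copy()
    vals = out.values
    complete_cols = [f for f in out.feature_ids if not vals[f].isna().any()]
    complete_arr = vals[complete_cols].to_numpy(dtype=float) if complete_cols else None
    for feature in out.feature_ids:
        col = vals[feature]
        miss = col.isna()
        if not miss.any():
            continue
        rng = substream(seed, "pmm", str(feature))
        observed_vals = col[~miss]
        if len(observed_vals) < min_observed or complete_arr is None:
            log.warning(
                "feature %s: %d observed values; imputing from marginal",
                feature, len(observed_vals),
            )
            draws = rng.choice(observed_vals.to_numpy(), size=int(miss.sum()))
            vals.loc[miss, feature] = draws
            report.record_imputation(str(feature), "marginal", int(miss.sum()))
            continue
        y = col.to_numpy(dtype=float)
        obs_mask = ~miss.to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            cors = np.array([
                abs(np.corrcoef(y[obs_mask], complete_arr[obs_mask, j])[0, 1])
                for j in range(complete_arr.shape[1])
            ])
        cors = np.nan_to_num(cors)
        top = np.argsort(-cors)[: min(n_predictors, complete_arr.shape[1])]
        design = np.column_stack(
            [np.ones(len(y)), complete_arr[:, top]]
        )
        beta, *_ = np.linalg.lstsq(design[obs_mask], y[obs_mask], rcond=None)
        pred = design @ beta
        obs_pred = pred[obs_mask]
        obs_y = y[obs_mask]
        for i in np.flatnonzero(miss.to_numpy()):
            dist = np.abs(obs_pred - pred[i])
            donor_idx = np.argsort(dist, kind="stable")[: min(donors, len(obs_y))]
            vals.iloc[i, vals.columns.get_loc(feature)] = obs_y[
                donor_idx[rng.integers(len(donor_idx))]
            ]
        report.record_imputation(str(feature), "pmm", int(miss.sum()))
    return out, report


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def preprocess_pipeline(
    x_raw: IntensityMatrix,
    pqn_fluids: tuple[str, ...] = ("U", "S"),
    outlier_sd: float = 4.0,
    max_missing: float = 0.20,
    seed: int = 0,
    donors: int = 5,
    n_predictors: int = 10,
) -> tuple[IntensityMatrix, PreprocessReport]:
    """Run the full preprocessing chain in its fixed order.

    The censored-imputation stage fits on log2 raw (pre-normalization)
    values per run day; its draws are mapped into the normalized log2 space
    by subtracting the log2 run-day median and the log2 PQN dilution factor
    of the target cell, so observed and imputed values live on the same
    scale.  Returns a fully observed matrix plus the stage report.
    """
    report = PreprocessReport()

    x, dropped = runday_filter(x_raw)
    report.features_dropped_runday = dropped

    x, runday_medians = runday_normalize(x)

    for fluid in pqn_fluids:
        x, d = pqn_normalize(x, fluid)
        report.dilution_factors[fluid] = d

    x = log2_transform(x)

    # outlier exclusion per fluid on complete features
    excluded: set[str] = set()
    for fluid in sorted(set(x.fluid)):
        block_cols = [f for f in x.feature_ids if x.fluid.loc[f] == fluid]
        block = x.values[block_cols]
        complete = block.columns[block.notna().all(axis=0)]
        if len(complete) < 3:
            log.warning(
                "fluid %s: only %d complete features; skipping outlier scan",
                fluid, len(complete),
            )
            continue
        excluded.update(detect_outliers(block[complete], threshold_sd=outlier_sd))
    report.samples_dropped_outlier = sorted(excluded)
    kept_samples = [s for s in x.sample_ids if s not in excluded]
    x = x.select_samples(kept_samples)

    x, dropped_miss = missingness_filter(x, max_frac=max_missing)
    report.features_dropped_missingness = dropped_miss

    # censored imputation on log2 raw values of the surviving cells
    raw = x_raw.select_features(x.feature_ids).select_samples(x.sample_ids)
    raw_log = log2_transform(raw)
    raw_imp, report = impute_censored(raw_log, seed=seed, report=report)
    # map draws into normalized space: subtract log2 run-day median and
    # log2 dilution for the cell's fluid
    filled = x.values.isna() & raw_imp.values.notna()
    if filled.any().any():
        med = runday_medians.loc[x.runday, x.feature_ids].set_axis(x.values.index)
        offset = np.log2(med)
        for fluid, d in report.dilution_factors.items():
            cols = [f for f in x.feature_ids if x.fluid.loc[f] == fluid]
            if cols:
                offset[cols] = offset[cols].add(np.log2(d.loc[x.sample_ids]), axis=0)
        normalized_draws = raw_imp.values - offset
        x.values = x.values.where(~filled, normalized_draws)

    x, report = impute_pmm(
        x, donors=donors, n_predictors=n_predictors, seed=seed, report=report
    )
    assert not x.values.isna().any().any(), "pipeline output must be complete"
    return x, report
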