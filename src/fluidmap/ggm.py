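"""Gaussian graphical model inference with shrinkage partial correlations.

The estimator shrinks the sample correlation matrix toward the identity with
the analytic (Ledoit-Wolf / Schaefer-Strimmer) intensity, inverts it, and
reads partial correlations off the precision matrix.  Covariates (age,
gender, BMI by default) are appended as extra variables so every partial
correlation is conditioned on them; their rows/columns are removed from the
result.

Edges require *both* the Pearson correlation (computed on
covariate-residualized data, exact t-test) and the partial correlation to be
significant at alpha after Bonferroni correction for the p(p-1)/2 variable
pairs (covariates never count).

Partial-correlation p-values come from a null density fitted to the observed
off-diagonal partial correlations,

    f0(r) ∝ (1 - r^2)^((kappa - 3)/2),

where kappa plays the role of an effective degree of freedom that absorbs
the shrinkage.  Because observed partial correlations are a mixture of null
and genuinely connected pairs, the default fit is a two-component mixture
eta0 * f0(r; kappa) + (1 - eta0) * Uniform(-1, 1), maximized over
(eta0, kappa); p-values are two-sided tails under the fitted f0.  A pure
single-component kappa fit and a Fisher-z test are selectable alternatives.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import optimize, special, stats

from .datatypes import CorrelationNetwork, EdgeStats

__all__ = [
    "shrinkage_intensity",
    "partial_correlation_from_corr",
    "shrinkage_partial_correlation",
    "fit_pcor_null",
    "pcor_pvalues",
    "edge_pvalues",
    "build_ggm",
]

log = logging.getLogger(__name__)

_KAPPA_MIN = 3.0 + 1e-6
_KAPPA_MAX = 1e9


def _standardize(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    sd = data.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"constant column(s) at index {bad.tolist()}")
    return (data - data.mean(axis=0)) / sd


def shrinkage_intensity(data: np.ndarray) -> float:
    """Analytic shrinkage intensity for correlation -> identity shrinkage.

    Schaefer-Strimmer estimator: lambda* = sum Var(r_ij) / sum r_ij^2 over
    the off-diagonal entries, clipped to [0, 1].
    """
    x = _standardize(data)
    n = x.shape[0]
    r = (x.T @ x) / (n - 1)
    w_bar = r * (n - 1) / n
    # Var(r_ij) = n / (n-1)^3 * sum_k (w_kij - w_bar_ij)^2
    sq = (x**2).T @ (x**2)  # sum_k x_ki^2 x_kj^2
    var_w = sq / n - w_bar**2
    var_r = var_w * n**2 / (n - 1) ** 3
    mask = ~np.eye(r.shape[1], dtype=bool)
    denom = float((r[mask] ** 2).sum())
    if denom == 0:
        return 1.0
    lam = float(var_r[mask].sum()) / denom
    return float(np.clip(lam, 0.0, 1.0))


def partial_correlation_from_corr(corr: np.ndarray, lam: float = 0.0) -> np.ndarray:
    """Partial correlations from a correlation matrix, after shrinking it
    toward the identity with intensity ``lam``."""
    corr = np.asarray(corr, dtype=float)
    p = corr.shape[0]
    shrunk = (1.0 - lam) * corr + lam * np.eye(p)
    omega = np.linalg.inv(shrunk)
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    return pcor


def shrinkage_partial_correlation(
    data: np.ndarray,
    n_covariates: int = 0,
    shrinkage: float | None = None,
) -> tuple[np.ndarray, float]:
    """Shrinkage partial correlation matrix of the leading p columns.

    ``data`` has the p network variables first and ``n_covariates`` covariate
    columns appended last; partial correlations condition on everything, and
    covariate rows/columns are dropped from the returned matrix.
    ``shrinkage=None`` uses the analytic intensity; a float forces it.
    """
    x = _standardize(data)
    n = x.shape[0]
    corr = (x.T @ x) / (n - 1)
    lam = shrinkage_intensity(data) if shrinkage is None else float(shrinkage)
    if lam >= 1.0:
        warnings.warn("shrinkage intensity is 1: partial correlations all zero")
    pcor = partial_correlation_from_corr(corr, lam)
    p = x.shape[1] - n_covariates
    return pcor[:p, :p], lam


# ---------------------------------------------------------------------------
# null density of partial correlations
# ---------------------------------------------------------------------------

def _log_f0(r2: np.ndarray, kappa: float) -> np.ndarray:
    # f0(r) = (1-r^2)^((kappa-3)/2) / Beta(1/2, (kappa-1)/2)
    return (kappa - 3.0) / 2.0 * np.log1p(-r2) - special.betaln(
        0.5, (kappa - 1.0) / 2.0
    )


def fit_pcor_null(
    pcor_offdiag: np.ndarray,
    method: str = "mixture",
    kappa_min: float = 4.0,
) -> tuple[float, float]:
    """Fit the null density of partial correlations.

    Returns ``(kappa, eta0)``.  ``method="mixture"`` (default) maximizes the
    likelihood of eta0*f0(r; kappa) + (1-eta0)/2 so that genuinely connected
    pairs are absorbed by the uniform component; ``method="pure"`` fits kappa
    alone on all values.

    ``kappa_min`` is a model-derived lower bound on the effective degree of
    freedom: with no shrinkage the null partial correlation of n samples
    conditioned on q other variables has kappa = n - 1 - q exactly, and
    shrinkage can only narrow the null, so smaller fitted values are
    spurious (they arise when very few off-diagonals are available and the
    non-null ones dominate the fit).
    """
    r = np.asarray(pcor_offdiag, dtype=float)
    r2 = np.clip(r**2, 0.0, 1.0 - 1e-12)
    log_km3_lo = np.log(max(kappa_min, 4.0) - 3.0)
    log_km3_hi = np.log(_KAPPA_MAX)

    if method == "pure":
        def nll(log_km3):
            kappa = 3.0 + np.exp(log_km3)
            return -_log_f0(r2, kappa).sum()

        res = optimize.minimize_scalar(
            nll, bounds=(log_km3_lo, log_km3_hi), method="bounded"
        )
        return float(3.0 + np.exp(res.x)), 1.0

    if method != "mixture":
        raise ValueError(f"unknown null-fit method {method!r}")

    def nll(params):
        logit_eta, log_km3 = params
        logit_eta = np.clip(logit_eta, -30.0, 30.0)
        log_km3 = np.clip(log_km3, log_km3_lo, log_km3_hi)
        eta = 1.0 / (1.0 + np.exp(-logit_eta))
        kappa = 3.0 + np.exp(log_km3)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            comp = np.logaddexp(
                np.log(eta) + _log_f0(r2, kappa),
                np.log1p(-eta) - np.log(2.0),
            )
        return -comp.sum()

    # coarse deterministic grid, then local refinement
    best, best_val = None, np.inf
    for eta in (0.5, 0.9, 0.99, 0.3, 0.7):
        logit = np.log(eta / (1 - eta))
        for log_km3 in np.linspace(log_km3_lo, log_km3_hi, 40):
            v = nll((logit, log_km3))
            if v < best_val:
                best, best_val = (logit, log_km3), v
    res = optimize.minimize(nll, x0=best, method="Nelder-Mead")
    logit_eta = float(np.clip(res.x[0], -30.0, 30.0))
    log_km3 = float(np.clip(res.x[1], log_km3_lo, log_km3_hi))
    eta = float(1.0 / (1.0 + np.exp(-logit_eta)))
    kappa = float(3.0 + np.exp(log_km3))
    return kappa, eta


def pcor_pvalues(
    partial_r: np.ndarray, kappa: float
) -> np.ndarray:
    """Two-sided tail probability of each partial correlation under f0.

    Under f0, r^2 ~ Beta(1/2, (kappa-1)/2), so the two-sided p-value is the
    Beta survival function at r^2.
    """
    r2 = np.clip(np.asarray(partial_r, dtype=float) ** 2, 0.0, 1.0)
    return stats.beta.sf(r2, 0.5, (kappa - 1.0) / 2.0)


def _fisher_z_pvalues(partial_r: np.ndarray, kappa: float) -> np.ndarray:
    df = max(kappa - 3.0, 1.0)
    z = np.arctanh(np.clip(partial_r, -1 + 1e-15, 1 - 1e-15)) * np.sqrt(df)
    return 2.0 * stats.norm.sf(np.abs(z))


def _residualize(data: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(data.shape[0]), covariates])
    beta, *_ = np.linalg.lstsq(design, data, rcond=None)
    return data - design @ beta


def edge_pvalues(
    data: np.ndarray,
    partial_r: np.ndarray,
    covariates: np.ndarray | None = None,
    null_fit: str = "mixture",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pearson and partial-correlation p-value matrices.

    ``data`` holds the p network variables only (covariates passed
    separately).  Pearson correlations are computed on covariate-residualized
    data and tested with the exact t-test on n - 2 - c degrees of freedom.
    Partial p-values come from the fitted null density (see module
    docstring).  Returns (pearson_r, pearson_p, partial_p).
    """
    data = np.asarray(data, dtype=float)
    n, p = data.shape
    if n < 10:
        raise ValueError("need at least 10 samples")
    c = 0 if covariates is None else np.atleast_2d(covariates).shape[1]
    resid = data if c == 0 else _residualize(data, covariates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pearson_r = np.corrcoef(resid, rowvar=False)
    np.fill_diagonal(pearson_r, 1.0)
    df = n - 2 - c
    r_clip = np.clip(pearson_r, -1 + 1e-15, 1 - 1e-15)
    tstat = r_clip * np.sqrt(df / (1.0 - r_clip**2))
    pearson_p = 2.0 * stats.t.sf(np.abs(tstat), df)
    np.fill_diagonal(pearson_p, 0.0)

    iu = np.triu_indices(p, k=1)
    # with q = p + c - 2 conditioned variables the unshrunk null df is
    # n - 1 - q; shrinkage only narrows the null, so this bounds kappa below
    kappa_min = max(4.0, n - 1.0 - (p + c - 2.0))
    kappa, eta0 = fit_pcor_null(
        partial_r[iu], method=null_fit, kappa_min=kappa_min
    )
    if kappa <= 3.0 + 1e-5:
        warnings.warn(
            f"fitted kappa {kappa:.3g} <= 3; falling back to Fisher-z"
        )
        partial_p = _fisher_z_pvalues(partial_r, max(kappa, 4.0))
    else:
        partial_p = pcor_pvalues(partial_r, kappa)
    np.fill_diagonal(partial_p, 0.0)
    return pearson_r, pearson_p, partial_p


def build_ggm(
    data,
    variables: list[str] | None = None,
    covariates: np.ndarray | None = None,
    alpha: float = 0.05,
    shrinkage: float | None = None,
    null_fit: str = "mixture",
    level: str = "metabolite",
) -> CorrelationNetwork:
    """Infer a GGM network with dual-significance Bonferroni edges.

    An edge (i, j) is drawn iff the Pearson p-value *and* the partial
    p-value are both below alpha / C(p, 2), with p the number of network
    variables (covariates excluded from the count and from the nodes).
    """
    try:
        cols = list(data.columns)
        arr = data.to_numpy(dtype=float)
    except AttributeError:
        arr = np.asarray(data, dtype=float)
        cols = None
    names = variables if variables is not None else (
        cols if cols is not None else [f"V{i}" for i in range(arr.shape[1])]
    )
    n, p = arr.shape
    if p < 2:
        raise ValueError("need at least 2 variables")
    cov = None if covariates is None else np.atleast_2d(np.asarray(covariates, float))
    if cov is not None and cov.shape[0] != n:
        cov = cov.T
    full = arr if cov is None else np.column_stack([arr, cov])
    n_cov = 0 if cov is None else cov.shape[1]
    partial_r, lam = shrinkage_partial_correlation(
        full, n_covariates=n_cov, shrinkage=shrinkage
    )
    pearson_r, pearson_p, partial_p = edge_pvalues(
        arr, partial_r, covariates=cov, null_fit=null_fit
    )
    n_tests = p * (p - 1) // 2
    thresh = alpha / n_tests
    edges: dict[tuple[str, str], EdgeStats] = {}
    for i in range(p):
        for j in range(i + 1, p):
            if pearson_p[i, j] < thresh and partial_p[i, j] < thresh:
                u, v = names[i], names[j]
                key = (u, v) if u < v else (v, u)
                edges[key] = EdgeStats(
                    pearson_r=float(pearson_r[i, j]),
                    partial_r=float(partial_r[i, j]),
                    pearson_p=float(pearson_p[i, j]),
                    partial_p=float(partial_p[i, j]),
                )
    net = CorrelationNetwork(level=level, nodes=list(names), edges=edges)
    net.shrinkage_lambda = lam  # attached for reporting
    net.n_samples = n
    net.n_tests = n_tests
    return net
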