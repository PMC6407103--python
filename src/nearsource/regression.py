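"""Source-proximity regression on aggregated log concentrations.

The segment x wind-category medians are modelled on the natural-log scale as

    Y(s, w) = b0 + b1*calm(w) + b2*railyard(s) + b3*downwind(s, w)
              + b4*distance(s) + eps(s, w)

with distance in kilometers from the yard edge (0 inside the yard).  Two
error models are fitted per pollutant:

* independent -- eps iid Gaussian (ordinary least squares);
* spatial -- eps a zero-mean Gaussian process, independent across wind
  categories but correlated across space within a category with
  exponential covariance Cov(eps_i, eps_j) = sigma^2 exp(-phi * d_ij)
  (d in meters) and Var(eps_i) = sigma^2 + tau^2 (sill + nugget).

The spatial likelihood is maximised by profiling: for any (phi, nugget
share) the regression coefficients are the GLS solution and the total
variance has a closed form, leaving a 2-D bounded quasi-Newton search with
multiple deterministic starts (GP likelihoods can be multimodal).
Exponentiated coefficients give multiplicative effects: exp(b4) is the
factor by which concentrations change per kilometer of distance.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.spatial.distance import squareform, pdist
from scipy.stats import norm

from .spatial import WindCategory

__all__ = [
    "COEF_NAMES",
    "CovarianceParams",
    "FitResult",
    "build_design",
    "fit_independent",
    "exp_cov_matrix",
    "fit_spatial",
    "interpret_effects",
    "correlation_matrix",
]

COEF_NAMES = ("intercept", "calm", "railyard", "downwind", "distance_km")

_PHI_BOUNDS = (np.log(1e-5), np.log(1.0))  # phi in 1/m: ranges 1 m .. 100 km


@dataclass(frozen=True)
class CovarianceParams:
    """Exponential-covariance parameters: sill sigma^2, nugget tau^2 (both in
    squared log units) and decay rate phi (1/m)."""

    sill_sigma2: float
    nugget_tau2: float
    range_phi: float

    def __post_init__(self) -> None:
        if self.sill_sigma2 < 0 or self.nugget_tau2 < 0:
            raise ValueError("sill and nugget must be nonnegative")
        if self.range_phi <= 0:
            raise ValueError("range_phi must be positive")


@dataclass
class FitResult:
    """Coefficients and uncertainty for one error model on one channel."""

    model: str  # "independent" | "spatial"
    beta: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    cov_params: CovarianceParams | None
    loglik: float
    converged: bool
    n_rows: int
    diagnostics: str = ""

    @property
    def significant(self) -> np.ndarray:
        """Wald significance at the 5% level (the convention used for
        flagging effects in tabular reports)."""
        return self.pvalues < 0.05


def build_design(records: pd.DataFrame, channel: str) -> pd.DataFrame:
    """Design rows for one channel: log median plus the Eq.-style covariates.

    Non-positive medians cannot be log-transformed; they are dropped and the
    count reported in ``df.attrs['n_dropped_nonpositive']``.
    """
    df = records[records["channel"] == channel].copy()
    if df.empty:
        raise ValueError(f"no aggregated records for channel {channel!r}")
    bad = ~(df["median"] > 0)
    n_bad = int(bad.sum())
    df = df[~bad]
    out = pd.DataFrame(
        {
            "log_y": np.log(df["median"].to_numpy(dtype=float)),
            "calm": df["calm"].to_numpy(dtype=int),
            "railyard": df["railyard"].to_numpy(dtype=int),
            "downwind": df["downwind"].to_numpy(dtype=int),
            "distance_km": df["distance_km"].to_numpy(dtype=float),
            "seg_x": df["seg_x"].to_numpy(dtype=float),
            "seg_y": df["seg_y"].to_numpy(dtype=float),
            "wind_category": df["wind_category"].to_numpy(),
            "segment_id": df["segment_id"].to_numpy(),
        }
    )
    out.attrs["n_dropped_nonpositive"] = n_bad
    return out


def _design_matrix(design: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    X = np.column_stack(
        [
            np.ones(len(design)),
            design["calm"].to_numpy(dtype=float),
            design["railyard"].to_numpy(dtype=float),
            design["downwind"].to_numpy(dtype=float),
            design["distance_km"].to_numpy(dtype=float),
        ]
    )
    y = design["log_y"].to_numpy(dtype=float)
    return X, y


def _check_rank(X: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR: columns pivoted beyond the numerical rank are the
        # ones expressible in terms of the others
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        bad = sorted(COEF_NAMES[j] for j in piv[rank:])
        raise ValueError(f"design matrix rank deficient; collinear columns: {bad}")


def fit_independent(design: pd.DataFrame) -> FitResult:
    """OLS fit assuming errors independent across space and wind category."""
    X, y = _design_matrix(design)
    if len(y) < 6:
        raise ValueError(f"need at least 6 rows, got {len(y)}")
    _check_rank(X)
    res = sm.OLS(y, X).fit()
    return FitResult(
        model="independent",
        beta=np.asarray(res.params),
        se=np.asarray(res.bse),
        pvalues=np.asarray(res.pvalues),
        cov_params=None,
        loglik=float(res.llf),
        converged=True,
        n_rows=len(y),
    )


def exp_cov_matrix(
    coords: np.ndarray, wind_categories: np.ndarray, params: CovarianceParams
) -> np.ndarray:
    """Error covariance matrix for the spatial model.

    Entry (i, j) is sigma^2 exp(-phi d_ij) when rows i != j share a wind
    category, sigma^2 + tau^2 on the diagonal, and 0 across categories
    (errors are independent between wind categories).
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    cats = np.asarray(wind_categories)
    D = squareform(pdist(coords)) if n > 1 else np.zeros((1, 1))
    same = cats[:, None] == cats[None, :]
    C = params.sill_sigma2 * np.exp(-params.range_phi * D) * same
    np.fill_diagonal(C, params.sill_sigma2 + params.nugget_tau2)
    return C


class _BlockCache:
    """Per-wind-category distance matrices, grouping identical blocks.

    When every category covers the same segments (the common balanced
    layout) the correlation matrix only needs to be factorised once per
    candidate phi instead of once per category.
    """

    def __init__(self, coords: np.ndarray, cats: np.ndarray):
        self.groups: list[tuple[np.ndarray, list[np.ndarray]]] = []
        by_key: dict[bytes, int] = {}
        for c in pd.unique(cats):
            idx = np.flatnonzero(cats == c)
            D = squareform(pdist(coords[idx])) if idx.size > 1 else np.zeros((idx.size, idx.size))
            key = D.tobytes()
            if key in by_key:
                self.groups[by_key[key]][1].append(idx)
            else:
                by_key[key] = len(self.groups)
                self.groups.append((D, [idx]))


def _profile_negloglik(
    theta: np.ndarray,
    cache: _BlockCache,
    X: np.ndarray,
    y: np.ndarray,
    jitter: float = 0.0,
) -> tuple[float, np.ndarray, float, np.ndarray]:
    """Negative log-likelihood with beta and total variance profiled out.

    theta = (log phi, w) with w = tau^2 / (sigma^2 + tau^2) in [0, 1].
    The correlation matrix is V = (1-w) exp(-phi D) + w I per category
    block; given V, beta_hat is GLS and s2_hat = r' V^-1 r / n, yielding
    -2 loglik = n log(2 pi s2_hat) + log|V| + n.

    Returns (negloglik, beta_hat, s2_hat, XtVinvX).
    """
    logphi, w = theta
    phi = np.exp(logphi)
    n, p = X.shape
    logdet = 0.0
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    solves: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for D, idx_list in cache.groups:
        m = D.shape[0]
        V = (1.0 - w) * np.exp(-phi * D) + (w + jitter) * np.eye(m)
        try:
            cf = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            raise
        logdet_block = 2.0 * np.sum(np.log(np.diag(cf[0])))
        for idx in idx_list:
            Xb, yb = X[idx], y[idx]
            ViX = cho_solve(cf, Xb)
            Viy = cho_solve(cf, yb)
            XtViX += Xb.T @ ViX
            XtViy += Xb.T @ Viy
            logdet += logdet_block
            solves.append((idx, Viy, ViX))
    beta = np.linalg.solve(XtViX, XtViy)
    rss = 0.0
    for idx, Viy, ViX in solves:
        r_weighted = Viy - ViX @ beta
        rss += (y[idx] - X[idx] @ beta) @ r_weighted
    s2 = max(rss / n, 1e-300)
    nll = 0.5 * (n * np.log(2.0 * np.pi * s2) + logdet + n)
    return nll, beta, s2, XtViX


def _eval_with_jitter(theta, cache, X, y):
    """Evaluate the profiled likelihood, escalating a diagonal jitter if the
    candidate correlation matrix is numerically singular."""
    for jitter in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            return _profile_negloglik(theta, cache, X, y, jitter=jitter)
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(
        "correlation matrix not positive definite even after jitter"
    )


#: Deterministic multi-start grid over (phi in 1/m, nugget share w).
_STARTS = [
    (1.0 / 50.0, 0.3),
    (1.0 / 200.0, 0.1),
    (1.0 / 200.0, 0.6),
    (1.0 / 1000.0, 0.3),
    (1.0 / 100.0, 0.9),
]


def fit_spatial(design: pd.DataFrame, starts: list[tuple[float, float]] | None = None) -> FitResult:
    """Maximum-likelihood fit with exponential spatial error covariance.

    Row locations are the segment centroids.  Coefficient standard errors
    come from (X' Sigma_hat^-1 X)^-1 at the optimum, the GLS information.
    Non-convergence of every start is reported via ``converged=False``
    together with the best point found, never a silent partial fit.
    """
    X, y = _design_matrix(design)
    n = len(y)
    if n < 10:
        raise ValueError(f"need at least 10 rows for the spatial model, got {n}")
    coords = design[["seg_x", "seg_y"]].to_numpy(dtype=float)
    if np.unique(coords, axis=0).shape[0] < 2:
        raise ValueError("need at least 2 distinct segment locations")
    _check_rank(X)
    cats = design["wind_category"].to_numpy()
    cache = _BlockCache(coords, cats)

    def objective(theta: np.ndarray) -> float:
        return _eval_with_jitter(theta, cache, X, y)[0]

    best = None
    any_converged = False
    for phi0, w0 in starts if starts is not None else _STARTS:
        res = minimize(
            objective,
            x0=np.array([np.log(phi0), w0]),
            method="L-BFGS-B",
            bounds=[_PHI_BOUNDS, (0.0, 1.0)],
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    nll, beta, s2, XtViX = _eval_with_jitter(best.x, cache, X, y)
    logphi, w = best.x
    phi = float(np.exp(logphi))
    sigma2 = float(s2 * (1.0 - w))
    tau2 = float(s2 * w)
    # (X' Sigma^-1 X)^-1 with Sigma = s2 * V  =>  s2 * (X' V^-1 X)^-1
    cov_beta = s2 * np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(cov_beta))
    z = beta / se
    pvals = 2.0 * norm.sf(np.abs(z))
    return FitResult(
        model="spatial",
        beta=beta,
        se=se,
        pvalues=pvals,
        cov_params=CovarianceParams(sill_sigma2=sigma2, nugget_tau2=tau2, range_phi=phi),
        loglik=float(-nll),
        converged=any_converged,
        n_rows=n,
        diagnostics="" if any_converged else f"no start converged: {best.message}",
    )


def interpret_effects(fit: FitResult) -> pd.DataFrame:
    """Multiplicative interpretation of the fitted coefficients.

    exp(b0) is the predicted concentration (original units) on a non-calm,
    upwind, out-of-yard segment at distance 0; the other exp(b) are the
    factors by which concentrations change when the indicator switches on,
    or per kilometer of distance for b4.  Intervals use +/- 1.96 SE.
    """
    if not fit.converged:
        raise ValueError("cannot interpret a non-converged fit")
    lo = fit.beta - 1.96 * fit.se
    hi = fit.beta + 1.96 * fit.se
    return pd.DataFrame(
        {
            "term": COEF_NAMES,
            "beta": fit.beta,
            "se": fit.se,
            "factor": np.exp(fit.beta),
            "factor_lo": np.exp(lo),
            "factor_hi": np.exp(hi),
            "significant": fit.significant,
        }
    )


def correlation_matrix(
    records: pd.DataFrame, channels: list[str] | None = None, min_pairs: int = 3
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations of log segment medians.

    Each (segment, wind category) cell is one observation per channel; an
    entry uses the rows where both channels are present and is NaN when
    fewer than ``min_pairs`` complete pairs exist.
    """
    wide = records.pivot_table(
        index=["segment_id", "wind_category"],
        columns="channel",
        values="median",
        aggfunc="first",
    )
    if channels is not None:
        wide = wide[channels]
    logw = np.log(wide.where(wide > 0))
    corr = logw.corr(method="pearson", min_periods=min_pairs)
    corr.index.name = None
    corr.columns.name = None
    return corr
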