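"""Two-stage regression of per-location variation on urbanization metrics.

Stage one (elsewhere) fits the by-location heterogeneous-variance model and
turns its posterior into a per-draw, per-location CV. Stage two, here, runs
one linear regression of the per-location CVs on centered/scaled mean ISA
and variance ISA *per posterior iteration*, then pools all coefficient draws
into a single posterior — so the stage-one uncertainty is propagated rather
than collapsed to a point estimate.

The per-iteration engine is exact conjugate Bayesian linear regression with
a flat prior: sigma² is drawn from its scaled-inverse-chi² marginal and the
coefficients from their conditional normal, which is auditable against
ordinary least squares. A Bayesian R² (variance of the fitted values over
itself plus the drawn error variance) is averaged per iteration and across
iterations; the "scale of effect" is the buffer radius maximizing it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AlignmentError,
    CollinearityError,
    ConfigError,
    ConstantPredictorError,
    DomainError,
    InsufficientSitesError,
    UndefinedRankError,
)

COEF_NAMES = ("intercept", "beta_mean_isa", "beta_var_isa")


@dataclass
class GradientFit:
    """Pooled second-stage posterior for one (response, scale) combination."""

    scale_m: float
    response: str
    coef_draws: np.ndarray  # (n_iterations * draws_per_iteration, 3)
    r2_per_iteration: np.ndarray
    included_locations: list[str]
    with_forest: bool
    n_iterations_used: int
    draws_per_iteration: int
    level: float = 0.95

    @property
    def r2_mean(self) -> float:
        return float(self.r2_per_iteration.mean())

    def summary(self) -> pd.DataFrame:
        lo, hi = (1 - self.level) / 2, 1 - (1 - self.level) / 2
        rows = []
        for j, name in enumerate(COEF_NAMES):
            d = self.coef_draws[:, j]
            rows.append(
                {"coefficient": name, "median": float(np.median(d)),
                 "ci_low": float(np.quantile(d, lo)),
                 "ci_high": float(np.quantile(d, hi))}
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "scale_m": self.scale_m,
            "response": self.response,
            "with_forest": self.with_forest,
            "included_locations": self.included_locations,
            "n_iterations_used": self.n_iterations_used,
            "draws_per_iteration": self.draws_per_iteration,
            "r2_mean": self.r2_mean,
            "coefficients": self.summary().to_dict(orient="records"),
        }


def filter_locations(
    observation_counts: Mapping[str, int], min_obs: int = 30
) -> list[str]:
    """Locations with at least ``min_obs`` observations, sorted; logs excluded."""
    included = sorted(loc for loc, n in observation_counts.items() if n >= min_obs)
    if len(included) < 3:
        raise InsufficientSitesError(
            f"only {len(included)} locations with >= {min_obs} observations; "
            "the two-predictor regression needs at least 3"
        )
    return included


def standardize(x: Sequence[float]) -> np.ndarray:
    """Center and scale to sample SD 1 (denominator n-1)."""
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise ConstantPredictorError("need >= 2 values to standardize")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ConstantPredictorError("zero standard deviation: constant predictor")
    return (arr - arr.mean()) / sd


def bayesian_r2(fitted_values: np.ndarray, error_variance: float | np.ndarray) -> np.ndarray | float:
    """var(fitted) / (var(fitted) + error variance).

    ``fitted_values`` may be 1-D (one fit) or 2-D ``(n_points, n_draws)``;
    ``error_variance`` broadcasts against the draw axis.
    """
    fitted = np.asarray(fitted_values, dtype=float)
    var_fit = fitted.var(axis=0, ddof=1)
    total = var_fit + np.asarray(error_variance, dtype=float)
    if np.any(total <= 0):
        raise DomainError("zero total variance: Bayesian R2 undefined")
    return var_fit / total


def per_iteration_regression(
    cv_draws: np.ndarray | pd.DataFrame,
    mean_isa: Sequence[float],
    var_isa: Sequence[float],
    n_iterations_used: int = 1000,
    draws_per_iteration: int = 100,
    seed: int = 0,
    scale_m: float = np.nan,
    response: str = "CV_I",
    locations: Sequence[str] | None = None,
    with_forest: bool = True,
    level: float = 0.95,
    collinearity_limit: float = 0.8,
) -> GradientFit:
    """One flat-prior Bayesian regression per posterior iteration, pooled.

    ``cv_draws`` is ``(n_locations, n_iterations)``; the first
    ``n_iterations_used`` iterations are used. Predictors are standardized
    internally. Raises :class:`CollinearityError` when |Spearman rho|
    between the predictors reaches ``collinearity_limit``.
    """
    if isinstance(cv_draws, pd.DataFrame):
        locations = list(cv_draws.index.astype(str)) if locations is None else list(locations)
        cv = cv_draws.to_numpy(dtype=float)
    else:
        cv = np.asarray(cv_draws, dtype=float)
        locations = [f"loc{i}" for i in range(cv.shape[0])] if locations is None else list(locations)
    L, T = cv.shape
    if L < 3:
        raise InsufficientSitesError(f"need >= 3 locations, got {L}")
    mean_isa = np.asarray(mean_isa, dtype=float)
    var_isa = np.asarray(var_isa, dtype=float)
    if mean_isa.shape != (L,) or var_isa.shape != (L,):
        raise AlignmentError("ISA predictors not aligned with CV rows")
    if T < n_iterations_used:
        raise AlignmentError(
            f"requested {n_iterations_used} iterations but only {T} supplied"
        )
    rho = stats.spearmanr(mean_isa, var_isa).statistic
    if np.isfinite(rho) and abs(rho) >= collinearity_limit:
        raise CollinearityError(
            f"|Spearman rho(mean ISA, var ISA)| = {abs(rho):.2f} >= {collinearity_limit}"
        )
    x1 = standardize(mean_isa)
    x2 = standardize(var_isa)
    X = np.column_stack([np.ones(L), x1, x2])
    pcoef = X.shape[1]
    if np.linalg.matrix_rank(X) < pcoef:
        raise CollinearityError("rank-deficient second-stage design")
    df = L - pcoef
    if df < 1:
        raise InsufficientSitesError(
            f"{L} locations leave no residual degrees of freedom for {pcoef} coefficients"
        )

    Y = cv[:, :n_iterations_used]  # (L, T_used)
    XtX_inv = np.linalg.inv(X.T @ X)
    P = XtX_inv @ X.T
    bhat = P @ Y  # (3, T_used)
    resid = Y - X @ bhat
    ss = (resid**2).sum(axis=0)  # (T_used,)

    rng = np.random.default_rng(seed)
    D = draws_per_iteration
    # sigma^2 | y ~ ss / chi2_df ; beta | sigma^2 ~ N(bhat, sigma^2 (X'X)^-1)
    chi2 = rng.chisquare(df, size=(n_iterations_used, D))
    sigma2 = ss[:, None] / chi2  # (T_used, D)
    Lchol = np.linalg.cholesky(XtX_inv)
    z = rng.standard_normal((n_iterations_used, D, pcoef))
    beta = bhat.T[:, None, :] + np.sqrt(sigma2)[:, :, None] * (z @ Lchol.T)

    fitted = np.einsum("lk,tdk->ltd", X, beta)  # (L, T_used, D)
    var_fit = fitted.var(axis=0, ddof=1)  # (T_used, D)
    r2 = var_fit / (var_fit + sigma2)
    r2_per_iter = r2.mean(axis=1)

    return GradientFit(
        scale_m=float(scale_m),
        response=response,
        coef_draws=beta.reshape(-1, pcoef),
        r2_per_iteration=r2_per_iter,
        included_locations=list(locations),
        with_forest=with_forest,
        n_iterations_used=n_iterations_used,
        draws_per_iteration=D,
        level=level,
    )


def scale_of_effect(r2_by_scale: Mapping[float, float]) -> float:
    """Scale with the maximal average R²; ties resolved to the smallest scale."""
    if not r2_by_scale:
        raise ConfigError("empty scale → R² map")
    best = max(r2_by_scale.values())
    return min(s for s, r in r2_by_scale.items() if r == best)


def mean_variance_correlation(
    means: Sequence[float], variances: Sequence[float]
) -> tuple[float, float]:
    """Spearman rho between paired means and variances, with p-value.

    For n <= 8 the p-value is an exact two-sided permutation test (all n!
    orderings); beyond that the asymptotic approximation is used.
    """
    m = np.asarray(means, dtype=float)
    v = np.asarray(variances, dtype=float)
    if m.shape != v.shape:
        raise AlignmentError("means and variances must be aligned")
    n = m.size
    if n < 4:
        raise DomainError(f"need >= 4 pairs, got {n}")
    if np.ptp(m) == 0 or np.ptp(v) == 0:
        raise UndefinedRankError("all-tied input: rank correlation undefined")
    res = stats.spearmanr(m, v)
    rho = float(res.statistic)
    if n <= 8:
        rv = stats.rankdata(v)
        rm = stats.rankdata(m)
        count = 0
        total = 0
        for perm in itertools.permutations(rv):
            r = np.corrcoef(rm, perm)[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        p = float(res.pvalue)
    return rho, p


def cv_matrix_from_summary(
    summary_frame: pd.DataFrame, response: str, locations: Sequence[str]
) -> np.ndarray:
    """``(n_locations, n_draws)`` matrix pulled from a tidy CV summary."""
    cols = []
    for loc in locations:
        sub = summary_frame[summary_frame["group"] == loc].sort_values("draw")
        if sub.empty:
            from .errors import MissingGroupError

            raise MissingGroupError(f"no CV draws for location {loc!r}")
        cols.append(sub[response].to_numpy())
    lengths = {c.size for c in cols}
    if len(lengths) != 1:
        raise AlignmentError("unequal draw counts across locations")
    return np.vstack(cols)
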