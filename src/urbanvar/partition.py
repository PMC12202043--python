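"""Posterior variance decomposition, marginal means, CVs and repeatability.

Everything here is computed *per posterior draw* so that downstream effect
sizes and gradient regressions inherit the full posterior uncertainty. The
total phenotypic variance is the exact per-draw sum

    V_p = V_i + V_y + V_f + V_r

where ``V_f`` is the variance (over a group's observed rows) of the linear
predictor restricted to biologically relevant terms (default: sex and the
linear + quadratic hour of day). Observer variance is tracked but excluded
from the total. For Poisson and ordinal families every quantity lives on the
latent scale; a log-normal data-scale mean is available for Poisson but off
by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MissingGroupError, TermNotFoundError, UndefinedCVError
from .hetvar import ORDINAL, POISSON, PosteriorDraws

DEFAULT_VF_TERMS = ("sex", "hour", "hour2")
DEFAULT_MARGINALIZE = ("sex", "age_class")

_CATEGORY_LEVELS = {"sex": ("F", "M"), "age_class": ("adult", "juvenile")}


@dataclass
class VarianceComponents:
    """Tidy per-draw × per-group variance components (long format)."""

    frame: pd.DataFrame  # columns: draw, group, V_i, V_y, V_f, V_r, V_o, V_p

    def for_group(self, group: str) -> pd.DataFrame:
        sub = self.frame[self.frame["group"] == group]
        if sub.empty:
            raise MissingGroupError(f"no components for group {group!r}")
        return sub.reset_index(drop=True)


@dataclass
class CVSummary:
    """Per-draw marginal means, CVs and repeatability per group."""

    frame: pd.DataFrame  # columns: draw, group, mean, CV_P, CV_I, [CV_R], rpt
    family: str

    def for_group(self, group: str) -> pd.DataFrame:
        sub = self.frame[self.frame["group"] == group]
        if sub.empty:
            raise MissingGroupError(f"no CV summary for group {group!r}")
        return sub.reset_index(drop=True)

    def draw_matrix(self, response: str, groups: Sequence[str]) -> np.ndarray:
        """``[len(groups), n_draws]`` matrix of one response column."""
        cols = []
        for g in groups:
            cols.append(self.for_group(g)[response].to_numpy())
        return np.vstack(cols)


def fixed_effect_variance(
    draws: PosteriorDraws,
    table: pd.DataFrame,
    selected_terms: Sequence[str] = DEFAULT_VF_TERMS,
) -> dict[str, np.ndarray]:
    """Per-draw variance of the selected fixed terms' contribution, per group.

    The variance is the population variance (denominator *n*) across the
    group's observed rows of ``X_sel @ beta`` where ``X_sel`` keeps only the
    columns whose term base is in ``selected_terms``.
    """
    design = draws.design
    fitted_bases = {c.base for c in design.columns}
    missing = set(selected_terms) - fitted_bases
    if missing:
        raise TermNotFoundError(
            f"terms not in the fitted model: {sorted(missing)} "
            f"(fitted: {sorted(fitted_bases)})"
        )
    beta = draws.beta()  # (n_kept, p)
    out: dict[str, np.ndarray] = {}
    group_vals = table[design.group_col].astype(str).to_numpy()
    for g in draws.groups:
        sub = table[group_vals == g]
        if sub.empty:
            raise MissingGroupError(f"group {g!r} has no observations")
        X_sel = design.encode(sub, only_bases=list(selected_terms))
        contrib = X_sel @ beta.T  # (n_rows_g, n_kept)
        out[g] = contrib.var(axis=0, ddof=0)
    return out


def _reference_grid(
    table: pd.DataFrame, group: str, group_col: str, marginalize_over: Sequence[str]
) -> pd.DataFrame:
    """Balanced grid over the marginalized categories at reference covariates.

    Continuous covariates sit at the group's observed means; ``assay_rank``
    at 0 (first assay) and ``protocol`` at post2017.
    """
    sub = table[table[group_col].astype(str) == group]
    if sub.empty:
        raise MissingGroupError(f"group {group!r} has no observations")
    for cov in marginalize_over:
        if cov not in _CATEGORY_LEVELS:
            raise TermNotFoundError(f"cannot marginalize over non-categorical {cov!r}")
    base = {
        group_col: group,
        "day_of_year": float(sub["day_of_year"].mean()),
        "decimal_hour": float(sub["decimal_hour"].mean()),
        "assay_rank": 0.0,
        "protocol": "post2017",
        "sex": sub["sex"].mode().iat[0],
        "age_class": sub["age_class"].mode().iat[0],
    }
    rows = [dict(base)]
    for cov in marginalize_over:
        rows = [dict(r, **{cov: lev}) for r in rows for lev in _CATEGORY_LEVELS[cov]]
    return pd.DataFrame(rows)


def marginal_mean(
    draws: PosteriorDraws,
    table: pd.DataFrame,
    marginalize_over: Sequence[str] = DEFAULT_MARGINALIZE,
) -> dict[str, np.ndarray]:
    """Per-draw predicted mean per group, averaged over a balanced grid.

    The grid crosses the marginalized categories with equal weights;
    remaining covariates are held at reference values (see
    :func:`_reference_grid`). Gaussian means are on the data scale; Poisson
    and ordinal means are latent-scale predictions.
    """
    design = draws.design
    beta = draws.beta()
    out: dict[str, np.ndarray] = {}
    for g in draws.groups:
        grid = _reference_grid(table, g, design.group_col, marginalize_over)
        Xg = design.encode(grid)
        out[g] = (Xg @ beta.T).mean(axis=0)
    return out


def assemble(
    draws: PosteriorDraws,
    v_f: Mapping[str, np.ndarray],
    means: Mapping[str, np.ndarray],
) -> tuple[VarianceComponents, CVSummary]:
    """Combine posterior draws into components + CV/repeatability tables.

    Per draw and group: ``V_p`` is the exact sum ``V_i + V_y + V_f + V_r``;
    ``CV_x = sqrt(V_x)/mean``; ``rpt = V_i/V_p``. ``CV_R`` is omitted for
    the ordinal family (latent residual fixed at 1 carries no information).
    Raises :class:`UndefinedCVError` if any draw's mean is non-positive.
    """
    n_kept = draws.n_kept
    comp_rows = []
    cv_rows = []
    idx = np.arange(n_kept)
    for g in draws.groups:
        vf = np.asarray(v_f[g], dtype=float)
        mean = np.asarray(means[g], dtype=float)
        if vf.shape != (n_kept,) or mean.shape != (n_kept,):
            from .errors import AlignmentError

            raise AlignmentError("v_f/means not aligned with posterior draws")
        v_i = draws.v_individual(g)
        v_y = draws.v_year(g)
        v_r = draws.v_residual(g)
        try:
            v_o = draws.v_observer(g)
        except KeyError:
            v_o = np.zeros(n_kept)
        v_p = v_i + v_y + vf + v_r
        bad = np.nonzero(mean <= 0)[0]
        if bad.size:
            raise UndefinedCVError(
                f"group {g!r}: non-positive marginal mean in draw(s) "
                f"{bad[:5].tolist()}{'...' if bad.size > 5 else ''}; CV undefined"
            )
        comp_rows.append(
            pd.DataFrame(
                {"draw": idx, "group": g, "V_i": v_i, "V_y": v_y, "V_f": vf,
                 "V_r": v_r, "V_o": v_o, "V_p": v_p}
            )
        )
        cv = {
            "draw": idx,
            "group": g,
            "mean": mean,
            "CV_P": np.sqrt(v_p) / mean,
            "CV_I": np.sqrt(v_i) / mean,
            "rpt": v_i / v_p,
        }
        if draws.family != ORDINAL:
            cv["CV_R"] = np.sqrt(v_r) / mean
        cv_rows.append(pd.DataFrame(cv))
    components = VarianceComponents(pd.concat(comp_rows, ignore_index=True))
    summary = CVSummary(pd.concat(cv_rows, ignore_index=True), draws.family)
    return components, summary


def decompose(
    draws: PosteriorDraws,
    table: pd.DataFrame,
    selected_terms: Sequence[str] = DEFAULT_VF_TERMS,
    marginalize_over: Sequence[str] = DEFAULT_MARGINALIZE,
) -> tuple[VarianceComponents, CVSummary]:
    """Convenience wrapper: V_f + marginal means + assemble in one call.

    Unlike :func:`fixed_effect_variance`, requested terms that were not
    fitted are silently skipped here; with nothing to select V_f is 0.
    """
    available = {c.base for c in draws.design.columns}
    terms = [t for t in selected_terms if t in available]
    if terms:
        v_f = fixed_effect_variance(draws, table, terms)
    else:
        v_f = {g: np.zeros(draws.n_kept) for g in draws.groups}
    means = marginal_mean(draws, table, marginalize_over)
    return assemble(draws, v_f, means)


def poisson_data_scale_mean(latent_mean: np.ndarray, latent_var: np.ndarray) -> np.ndarray:
    """Log-normal back-transformation exp(mu + V/2); optional, off by default."""
    return np.exp(latent_mean + 0.5 * latent_var)


def components_summary(components: VarianceComponents, level: float = 0.95) -> pd.DataFrame:
    """Median and equal-tailed CI per component per group (tidy)."""
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    rows = []
    value_cols = [c for c in components.frame.columns if c.startswith("V_")]
    for group, sub in components.frame.groupby("group"):
        for col in value_cols:
            v = sub[col].to_numpy()
            rows.append(
                {"group": group, "component": col, "median": np.median(v),
                 "ci_low": np.quantile(v, lo), "ci_high": np.quantile(v, hi)}
            )
    return pd.DataFrame(rows)
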