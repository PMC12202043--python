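"""Bayesian mixed models with group-specific (heterogeneous) variances.

Two model layouts are supported through ``variance_grouping``:

- ``by_habitat`` ("model a"): two groups, per-group fixed-effect slopes for
  sex, age, date and the (quadratic) hour of day, heterogeneous year and
  observer variances;
- ``by_location`` ("model b"): one variance group per sampling location,
  shared slopes, homogeneous year and observer variances.

Samplers
--------
Gaussian responses use closed-form Gibbs updates throughout (conjugate
normal draws for coefficients and random effects, inverse-gamma draws for
variances under a weakly informative inverse-gamma prior, flat priors on
coefficients). Poisson responses add a latent log-intensity per row updated
by adaptive random-walk Metropolis; the row-level residual acts as
log-normal overdispersion. Ordinal responses use probit liability
augmentation with the residual variance fixed at 1 and the first cutpoint
fixed at 0; the remaining cutpoints are sampled from their uniform full
conditionals.

Diagnostics are autocorrelation-based effective sample sizes (Geyer initial
positive-sequence estimator) and Geweke first-10%/last-50% z-scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

from .errors import (
    ConfigError,
    DegenerateChainError,
    DesignRankError,
    InsufficientDrawsError,
)

GAUSSIAN, ORDINAL, POISSON = "gaussian", "ordinal", "poisson"
_FAMILIES = {GAUSSIAN, ORDINAL, POISSON}

#: covariate bases understood by the design encoder
TERM_BASES = ("sex", "age", "day", "hour", "hour2", "assay_rank", "protocol")

#: bases that get per-group slopes when group interactions are on
INTERACTION_BASES = ("sex", "age", "day", "hour", "hour2")

ORDINAL_SCORE_TO_CAT = {round(0.5 * k, 1): k for k in range(7)}


# ---------------------------------------------------------------------------
# Fixed-effect design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnDef:
    """One fixed-effect design column: a term base, optional group, center."""

    name: str
    base: str
    group: str | None = None
    center: float = 0.0


@dataclass(frozen=True)
class Design:
    """Reproducible encoder for the fixed-effect design matrix."""

    columns: tuple[ColumnDef, ...]
    group_col: str
    hour_center: float
    hour2_center: float
    day_center: float

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.columns]

    def _base_values(self, df: pd.DataFrame, base: str) -> np.ndarray:
        if base == "intercept":
            return np.ones(len(df))
        if base == "sex":
            return (df["sex"].to_numpy() == "M").astype(float)
        if base == "age":
            return (df["age_class"].to_numpy() == "juvenile").astype(float)
        if base == "day":
            return df["day_of_year"].to_numpy(dtype=float) - self.day_center
        if base == "hour":
            return df["decimal_hour"].to_numpy(dtype=float) - self.hour_center
        if base == "hour2":
            hc = df["decimal_hour"].to_numpy(dtype=float) - self.hour_center
            return hc * hc - self.hour2_center
        if base == "assay_rank":
            return df["assay_rank"].to_numpy(dtype=float)
        if base == "protocol":
            return (df["protocol"].to_numpy() == "pre2017").astype(float)
        raise ConfigError(f"unknown term base {base!r}")

    def encode(self, df: pd.DataFrame, only_bases: Sequence[str] | None = None) -> np.ndarray:
        """Encode rows into the design matrix.

        ``only_bases`` zeroes out every column whose base is not listed
        (used for the fixed-effect variance of selected terms).
        """
        groups = df[self.group_col].to_numpy()
        cols = []
        for c in self.columns:
            if only_bases is not None and c.base not in only_bases:
                cols.append(np.zeros(len(df)))
                continue
            v = self._base_values(df, c.base)
            if c.group is not None:
                v = v * (groups == c.group)
            cols.append(v)
        return np.column_stack(cols) if cols else np.empty((len(df), 0))


def build_design(
    table: pd.DataFrame,
    group_col: str,
    groups: Sequence[str],
    fixed_terms: Sequence[str],
    interactions: bool,
) -> Design:
    """Build the design: per-group intercepts, then covariate terms.

    With ``interactions`` on, covariates in :data:`INTERACTION_BASES` get one
    slope per group (cell-means coding); others are shared.
    """
    hour_center = float(table["decimal_hour"].mean())
    hc = table["decimal_hour"].to_numpy(dtype=float) - hour_center
    hour2_center = float(np.mean(hc * hc))
    day_center = float(table["day_of_year"].mean())
    columns: list[ColumnDef] = [
        ColumnDef(f"intercept[{g}]", "intercept", g) for g in groups
    ]
    for base in fixed_terms:
        if base not in TERM_BASES:
            raise ConfigError(f"unknown fixed term {base!r}")
        if interactions and base in INTERACTION_BASES:
            columns.extend(ColumnDef(f"{base}[{g}]", base, g) for g in groups)
        else:
            columns.append(ColumnDef(base, base))
    return Design(
        columns=tuple(columns),
        group_col=group_col,
        hour_center=hour_center,
        hour2_center=hour2_center,
        day_center=day_center,
    )


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    if X.shape[1] == 0:
        return
    _, r, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        aliased = [names[i] for i in piv[rank:]]
        raise DesignRankError(
            f"fixed-effect design is rank deficient; aliased terms: {aliased}"
        )


# ---------------------------------------------------------------------------
# Configuration and posterior container
# ---------------------------------------------------------------------------

@dataclass
class MCMCOptions:
    n_iter: int = 65_000
    burn_in: int = 15_000
    thin: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ConfigError("burn_in must be < n_iter")
        if self.thin < 1:
            raise ConfigError("thin must be >= 1")

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class ModelConfig:
    """Model layout + sampler settings for :func:`fit`."""

    family: str = GAUSSIAN
    variance_grouping: str = "by_habitat"  # or "by_location"
    fixed_terms: Sequence[str] | None = None  # None → family default
    group_interactions: bool | None = None  # None → True for by_habitat
    heterogeneous_year: bool | None = None  # None → grouping default
    heterogeneous_observer: bool | None = None
    heterogeneous_residual: bool = True
    include_individual: bool = True
    include_year: bool = True
    include_observer: bool = True
    mcmc: MCMCOptions = field(default_factory=MCMCOptions)
    # inverse-gamma prior IG(nu/2, nu*V/2) on every variance component
    prior_nu: float = 0.002
    prior_v: float = 1.0
    fixed_beta: Sequence[float] | None = None  # freeze coefficients (testing)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigError(f"unknown family {self.family!r}")
        if self.variance_grouping not in {"by_habitat", "by_location"}:
            raise ConfigError(f"unknown variance_grouping {self.variance_grouping!r}")
        if self.group_interactions is None:
            self.group_interactions = self.variance_grouping == "by_habitat"
        het_default = self.variance_grouping == "by_habitat"
        if self.heterogeneous_year is None:
            self.heterogeneous_year = het_default
        if self.heterogeneous_observer is None:
            self.heterogeneous_observer = het_default

    @property
    def group_col(self) -> str:
        return "habitat" if self.variance_grouping == "by_habitat" else "location_id"

    def resolve_fixed_terms(self, table: pd.DataFrame) -> list[str]:
        if self.fixed_terms is not None:
            return list(self.fixed_terms)
        terms = ["sex", "age", "day", "hour", "hour2", "assay_rank"]
        if self.family == GAUSSIAN and table["protocol"].nunique() > 1:
            terms.append("protocol")
        return terms


@dataclass
class PosteriorDraws:
    """Kept MCMC draws: matrix ``[n_kept, n_params]`` with named columns."""

    draws: np.ndarray
    param_names: list[str]
    metadata: dict

    def __post_init__(self) -> None:
        if self.draws.ndim != 2 or self.draws.shape[1] != len(self.param_names):
            raise ConfigError("draws shape inconsistent with parameter names")
        self._index = {n: i for i, n in enumerate(self.param_names)}

    @property
    def n_kept(self) -> int:
        return self.draws.shape[0]

    @property
    def groups(self) -> list[str]:
        return list(self.metadata["groups"])

    @property
    def family(self) -> str:
        return self.metadata["family"]

    @property
    def design(self) -> Design:
        return self.metadata["design"]

    def get(self, name: str) -> np.ndarray:
        return self.draws[:, self._index[name]]

    def has(self, name: str) -> bool:
        return name in self._index

    def beta(self) -> np.ndarray:
        """Fixed-coefficient draws, columns ordered as ``design.columns``."""
        cols = [self._index[f"beta:{n}"] for n in self.design.names]
        return self.draws[:, cols]

    def _component(self, prefix: str, group: str) -> np.ndarray:
        grouped = f"{prefix}[{group}]"
        if grouped in self._index:
            return self.get(grouped)
        if prefix in self._index:
            return self.get(prefix)
        raise KeyError(f"no draws for {prefix} (group {group!r})")

    def v_individual(self, group: str) -> np.ndarray:
        return self._component("V_i", group)

    def v_residual(self, group: str) -> np.ndarray:
        if self.family == ORDINAL:
            return np.ones(self.n_kept)
        return self._component("V_r", group)

    def v_year(self, group: str) -> np.ndarray:
        try:
            return self._component("V_y", group)
        except KeyError:  # year effect not in the model
            return np.zeros(self.n_kept)

    def v_observer(self, group: str) -> np.ndarray:
        try:
            return self._component("V_o", group)
        except KeyError:  # observer effect not in the model
            return np.zeros(self.n_kept)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=self.param_names)

    def save(self, directory: str | Path) -> None:
        """Write draws (CSV) plus run metadata (YAML) into ``directory``."""
        import yaml

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "posterior_draws.csv", index=False)
        meta = dict(self.metadata)
        design = meta.pop("design")
        meta["design"] = {
            "group_col": design.group_col,
            "hour_center": design.hour_center,
            "hour2_center": design.hour2_center,
            "day_center": design.day_center,
            "columns": [
                {"name": c.name, "base": c.base, "group": c.group, "center": c.center}
                for c in design.columns
            ],
        }
        (directory / "run_metadata.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))

    @classmethod
    def load(cls, directory: str | Path) -> "PosteriorDraws":
        import yaml

        directory = Path(directory)
        frame = pd.read_csv(directory / "posterior_draws.csv")
        meta = yaml.safe_load((directory / "run_metadata.yaml").read_text())
        d = meta["design"]
        meta["design"] = Design(
            columns=tuple(
                ColumnDef(c["name"], c["base"], c["group"], c.get("center", 0.0))
                for c in d["columns"]
            ),
            group_col=d["group_col"],
            hour_center=d["hour_center"],
            hour2_center=d["hour2_center"],
            day_center=d["day_center"],
        )
        return cls(frame.to_numpy(dtype=float), list(frame.columns), meta)


# ---------------------------------------------------------------------------
# Random-effect bookkeeping
# ---------------------------------------------------------------------------

class _RandomEffect:
    """One random-effect block with (possibly) group-specific variances."""

    def __init__(
        self,
        name: str,
        row_levels: np.ndarray,  # level index per row
        n_levels: int,
        level_vargroup: np.ndarray,  # variance-group index per level
        vargroup_names: list[str],
    ) -> None:
        self.name = name
        self.row_levels = row_levels
        self.n_levels = n_levels
        self.level_vargroup = level_vargroup
        self.vargroup_names = vargroup_names
        self.values = np.zeros(n_levels)
        self.variances = np.ones(len(vargroup_names))

    def contribution(self) -> np.ndarray:
        return self.values[self.row_levels]


def _effect_levels(
    keys: pd.Series | np.ndarray,
    groups_per_row: np.ndarray,
    heterogeneous: bool,
    groups: Sequence[str],
    name: str,
    level_group_fixed: np.ndarray | None = None,
) -> _RandomEffect:
    """Index effect levels; heterogeneous effects nest levels within groups."""
    keys = np.asarray(keys)
    if heterogeneous and level_group_fixed is None:
        combo = np.char.add(np.char.add(keys.astype(str), "\x1f"), groups_per_row.astype(str))
        uniq, row_levels = np.unique(combo, return_inverse=True)
        level_groups = np.array([u.split("\x1f")[1] for u in uniq])
        gidx = {g: i for i, g in enumerate(groups)}
        level_vargroup = np.array([gidx[g] for g in level_groups])
        vg_names = [f"{name}[{g}]" for g in groups]
    else:
        uniq, row_levels = np.unique(keys, return_inverse=True)
        if level_group_fixed is not None:
            gidx = {g: i for i, g in enumerate(groups)}
            level_vargroup = np.array([gidx[g] for g in level_group_fixed])
            vg_names = [f"{name}[{g}]" for g in groups]
        else:
            level_vargroup = np.zeros(len(uniq), dtype=int)
            vg_names = [name]
    return _RandomEffect(name, row_levels, len(uniq), level_vargroup, vg_names)


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------

def fit(table: pd.DataFrame, config: ModelConfig) -> PosteriorDraws:
    """Fit the heterogeneous-variance mixed model; returns kept draws.

    Row order of ``table`` is irrelevant beyond Monte-Carlo noise. A warning
    (not an error) is emitted when a variance group has no individual with
    repeated measurements, since its among-individual variance is then
    informed only by the prior and shrinkage.
    """
    table = table.reset_index(drop=True)
    group_col = config.group_col
    if group_col not in table.columns:
        raise ConfigError(f"grouping column {group_col!r} missing from table")
    groups = sorted(table[group_col].astype(str).unique())
    row_group_names = table[group_col].astype(str).to_numpy()
    gidx = {g: i for i, g in enumerate(groups)}
    row_group = np.array([gidx[g] for g in row_group_names])
    n = len(table)

    for g in groups:
        sub = table.loc[row_group_names == g, "individual_id"]
        if sub.value_counts().max() < 2:
            warnings.warn(
                f"variance group {g!r} has no individual with repeated measures; "
                "its among-individual variance is weakly identified",
                stacklevel=2,
            )

    terms = config.resolve_fixed_terms(table)
    design = build_design(table, group_col, groups, terms, bool(config.group_interactions))
    X = design.encode(table)
    _check_rank(X, design.names)
    p = X.shape[1]

    # response / latent initialisation -------------------------------------
    y = table["value"].to_numpy(dtype=float)
    if config.family == ORDINAL:
        try:
            cats = np.array([ORDINAL_SCORE_TO_CAT[round(float(v), 1)] for v in y])
        except KeyError as exc:  # pragma: no cover - validated upstream
            raise ConfigError(f"invalid ordinal score {exc}") from exc
        # interior cutpoints c1..c6 with c1 fixed at 0; category k occupies
        # (c_{k-1}, c_k] on the liability scale
        cuts = np.concatenate([[0.0], 0.6 * np.arange(1, 6)])
        ystar = cuts[np.clip(cats, 0, 5)] - 0.3 + 0.6 * (cats == 6)
    elif config.family == POISSON:
        ystar = np.log(y + 0.5)
        cats = None
        cuts = None
    else:
        ystar = y.copy()
        cats = None
        cuts = None

    # random effects -------------------------------------------------------
    effects: list[_RandomEffect] = []
    if config.include_individual and "individual_id" in table.columns:
        ind_keys, ind_rows = np.unique(table["individual_id"].to_numpy(), return_inverse=True)
        first_row = np.zeros(len(ind_keys), dtype=int)
        first_row[ind_rows[::-1]] = np.arange(n - 1, -1, -1)
        ind_group = row_group_names[first_row]
        eff = _effect_levels(
            table["individual_id"], row_group_names, True, groups, "V_i",
            level_group_fixed=ind_group,
        )
        effects.append(eff)
    if config.include_year and "year" in table.columns:
        effects.append(
            _effect_levels(table["year"], row_group_names, bool(config.heterogeneous_year), groups, "V_y")
        )
    if config.include_observer and "observer_id" in table.columns:
        effects.append(
            _effect_levels(
                table["observer_id"], row_group_names, bool(config.heterogeneous_observer), groups, "V_o"
            )
        )

    # residual variance groups --------------------------------------------
    if config.family == ORDINAL:
        resid_het = False
        v_r = np.ones(1)
        resid_names: list[str] = []
        row_rgroup = np.zeros(n, dtype=int)
        n_rgroups = 1
    elif config.heterogeneous_residual:
        resid_het = True
        v_r = np.full(len(groups), 1.0)
        resid_names = [f"V_r[{g}]" for g in groups]
        row_rgroup = row_group
        n_rgroups = len(groups)
    else:
        resid_het = False
        v_r = np.ones(1)
        resid_names = ["V_r"]
        row_rgroup = np.zeros(n, dtype=int)
        n_rgroups = 1

    # precomputations for the coefficient update
    rgroup_rows = [np.nonzero(row_rgroup == g)[0] for g in range(n_rgroups)]
    Xg = [X[idx] for idx in rgroup_rows]
    XtXg = [x.T @ x for x in Xg]

    a0 = config.prior_nu / 2.0
    b0 = config.prior_nu * config.prior_v / 2.0

    mcmc = config.mcmc
    rng = np.random.default_rng(mcmc.seed)

    beta = np.zeros(p)
    if config.fixed_beta is not None:
        beta = np.asarray(config.fixed_beta, dtype=float)
        if beta.shape != (p,):
            raise ConfigError(f"fixed_beta must have length {p}")
    elif p:
        beta, *_ = np.linalg.lstsq(X, ystar, rcond=None)

    fitted_random = np.zeros(n)
    for eff in effects:
        eff.variances[:] = max(np.var(ystar) / (len(effects) + 1), 0.1)
    if config.family != ORDINAL:
        v_r[:] = max(np.var(ystar - X @ beta) / 2, 0.1)

    # Poisson MH state
    if config.family == POISSON:
        log_step = np.full(n, np.log(0.5))

    param_names = [f"beta:{nm}" for nm in design.names]
    for eff in effects:
        param_names += eff.vargroup_names
    param_names += resid_names
    cut_names = [f"cut{k}" for k in range(2, 7)] if config.family == ORDINAL else []
    param_names += cut_names

    kept = np.empty((mcmc.n_kept, len(param_names)))
    k_out = 0

    w = np.empty(n)
    for it in range(mcmc.n_iter):
        w[:] = 1.0 / v_r[row_rgroup]

        # --- fixed coefficients ------------------------------------------
        if p and config.fixed_beta is None:
            r = ystar - fitted_random
            A = np.zeros((p, p))
            rhs = np.zeros(p)
            for g in range(n_rgroups):
                wg = 1.0 / v_r[g]
                A += wg * XtXg[g]
                rhs += wg * (Xg[g].T @ r[rgroup_rows[g]])
            L = np.linalg.cholesky(A)
            mean = sla.cho_solve((L, True), rhs)
            z = rng.standard_normal(p)
            beta = mean + sla.solve_triangular(L, z, trans="T", lower=True)
        xb = X @ beta if p else np.zeros(n)

        # --- random effects ----------------------------------------------
        for eff in effects:
            fitted_random -= eff.contribution()
            r = ystar - xb - fitted_random
            sw = np.bincount(eff.row_levels, weights=w, minlength=eff.n_levels)
            swr = np.bincount(eff.row_levels, weights=w * r, minlength=eff.n_levels)
            lev_var = eff.variances[eff.level_vargroup]
            prec = sw + 1.0 / lev_var
            eff.values = swr / prec + rng.standard_normal(eff.n_levels) / np.sqrt(prec)
            # conjugate inverse-gamma update per variance group
            ss = np.bincount(
                eff.level_vargroup, weights=eff.values**2, minlength=len(eff.vargroup_names)
            )
            nlev = np.bincount(eff.level_vargroup, minlength=len(eff.vargroup_names))
            shape = a0 + nlev / 2.0
            scale = b0 + ss / 2.0
            eff.variances = scale / rng.gamma(shape)
            fitted_random += eff.contribution()

        # --- residual variances ------------------------------------------
        if config.family != ORDINAL:
            resid = ystar - xb - fitted_random
            ssr = np.bincount(row_rgroup, weights=resid**2, minlength=n_rgroups)
            nres = np.bincount(row_rgroup, minlength=n_rgroups)
            v_r = (b0 + ssr / 2.0) / rng.gamma(a0 + nres / 2.0)

        # --- latent updates ----------------------------------------------
        mu = xb + fitted_random
        if config.family == POISSON:
            step = np.exp(log_step)
            prop = ystar + step * rng.standard_normal(n)
            vr_row = v_r[row_rgroup]
            logr = (
                y * (prop - ystar)
                - (np.exp(prop) - np.exp(ystar))
                - ((prop - mu) ** 2 - (ystar - mu) ** 2) / (2.0 * vr_row)
            )
            accept = np.log(rng.random(n)) < logr
            ystar = np.where(accept, prop, ystar)
            if it < mcmc.burn_in:  # Robbins–Monro adaptation toward 0.44
                gamma = (it + 1) ** -0.6
                log_step += gamma * (accept.astype(float) - 0.44)
        elif config.family == ORDINAL:
            lo_edges = np.concatenate([[-np.inf], cuts])
            hi_edges = np.concatenate([cuts, [np.inf]])
            lo = lo_edges[cats] - mu
            hi = hi_edges[cats] - mu
            ulo = stats.norm.cdf(lo)
            uhi = stats.norm.cdf(hi)
            u = ulo + (uhi - ulo) * rng.random(n)
            ystar = mu + stats.norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))
            # cutpoint Gibbs update (c1 fixed at 0)
            for k in range(1, 6):  # cuts index 1..5 == c2..c6
                in_k = ystar[cats == k]
                above = ystar[cats == k + 1]
                lo_b = in_k.max() if in_k.size else cuts[k - 1]
                lo_b = max(lo_b, cuts[k - 1])
                hi_b = above.min() if above.size else (cuts[k + 1] if k < 5 else lo_b + 1.0)
                if k < 5:
                    hi_b = min(hi_b, cuts[k + 1])
                if hi_b <= lo_b:
                    cuts[k] = lo_b
                else:
                    cuts[k] = rng.uniform(lo_b, hi_b)

        # --- store --------------------------------------------------------
        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0 and k_out < mcmc.n_kept:
            row = list(beta)
            for eff in effects:
                row.extend(eff.variances)
            if config.family != ORDINAL:
                row.extend(v_r)
            if config.family == ORDINAL:
                row.extend(cuts[1:])
            kept[k_out] = row
            k_out += 1

    metadata = {
        "family": config.family,
        "grouping": config.variance_grouping,
        "group_col": group_col,
        "groups": groups,
        "seed": mcmc.seed,
        "n_iter": mcmc.n_iter,
        "burn_in": mcmc.burn_in,
        "thin": mcmc.thin,
        "fixed_terms": terms,
        "group_interactions": bool(config.group_interactions),
        "design": design,
    }
    return PosteriorDraws(kept[:k_out], param_names, metadata)


# ---------------------------------------------------------------------------
# MCMC diagnostics
# ---------------------------------------------------------------------------

def _ess_1d(x: np.ndarray) -> float:
    """Geyer initial positive-sequence effective sample size."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2 or np.ptp(x) == 0.0:
        raise DegenerateChainError("constant chain: effective sample size undefined")
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # pair sums Γ_m = ρ_{2m} + ρ_{2m+1}; truncate at the first negative
    tau = rho[0]  # = 1 (lag 0 counted once)
    m = 1
    while m + 1 < n:
        gamma = rho[m] + rho[m + 1]
        if gamma <= 0:
            break
        tau += 2.0 * gamma
        m += 2
    return float(n / max(tau, 1e-12))


def effective_sample_size(
    draws: "PosteriorDraws | np.ndarray", threshold: float = 1000.0
) -> dict[str, float] | float:
    """Autocorrelation-based ESS.

    Accepts a :class:`PosteriorDraws` (returns a dict per parameter) or a
    1-D array of draws (returns a float). Parameters with ESS below
    ``threshold`` are reported by :func:`convergence_check`.
    """
    if isinstance(draws, PosteriorDraws):
        if draws.n_kept < 100:
            raise InsufficientDrawsError("need >= 100 kept draws for ESS")
        return {name: _ess_1d(draws.get(name)) for name in draws.param_names}
    arr = np.asarray(draws, dtype=float)
    if arr.ndim == 1:
        if arr.size < 100:
            raise InsufficientDrawsError("need >= 100 draws for ESS")
        return _ess_1d(arr)
    raise ConfigError("pass PosteriorDraws or a 1-D array")


@dataclass
class ConvergenceReport:
    table: pd.DataFrame  # parameter, geweke_z, pass_geweke, ess, pass_ess
    failures: list[str]
    ess_threshold: float

    @property
    def passed(self) -> bool:
        return not self.failures


def geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Z-score comparing the means of the first 10% and last 50% of a chain.

    Segment standard errors use the segment variance deflated by its own
    autocorrelation-based ESS, approximating the spectral-density estimate.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    a = x[: max(int(first * n), 2)]
    b = x[-max(int(last * n), 2):]
    if np.ptp(x) == 0.0:
        raise DegenerateChainError("constant chain: Geweke diagnostic undefined")

    def seg_se(seg: np.ndarray) -> float:
        if np.ptp(seg) == 0.0:
            return 0.0
        try:
            ess = _ess_1d(seg)
        except DegenerateChainError:
            return 0.0
        return float(np.sqrt(np.var(seg, ddof=1) / ess))

    se = np.hypot(seg_se(a), seg_se(b))
    if se == 0.0:
        raise DegenerateChainError("zero spectral variance in Geweke segments")
    return float((a.mean() - b.mean()) / se)


def convergence_check(
    draws: PosteriorDraws,
    z_critical: float = 2.58,
    ess_threshold: float = 1000.0,
) -> ConvergenceReport:
    """Per-parameter Geweke + ESS report; failures listed, never raising."""
    if draws.n_kept < 200:
        raise InsufficientDrawsError("need >= 200 kept draws for the convergence check")
    rows = []
    failures = []
    for name in draws.param_names:
        x = draws.get(name)
        try:
            z = geweke_z(x)
            ess = _ess_1d(x)
        except DegenerateChainError:
            rows.append(
                {"parameter": name, "geweke_z": np.nan, "pass_geweke": False,
                 "ess": 0.0, "pass_ess": False}
            )
            failures.append(name)
            continue
        ok_z = abs(z) < z_critical
        ok_e = ess >= ess_threshold
        rows.append(
            {"parameter": name, "geweke_z": z, "pass_geweke": ok_z,
             "ess": ess, "pass_ess": ok_e}
        )
        if not (ok_z and ok_e):
            failures.append(name)
    return ConvergenceReport(pd.DataFrame(rows), failures, ess_threshold)
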