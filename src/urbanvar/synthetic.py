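"""Simulation of long-format repeated behavioral observations.

Generates observation tables with the structure the heterogeneous-variance
models assume: group-specific (habitat or location) among-individual and
residual variances, shared year and observer random effects, and a fixed-
effect part (sex, age, day of year, decimal hour + its square, assay rank,
protocol). Three response families are supported:

- ``gaussian``: the latent predictor is observed directly;
- ``ordinal``: a probit-threshold trait with 7 categories scored 0–3 in 0.5
  steps (latent residual variance fixed at 1);
- ``poisson``: counts with log link; the residual acts as log-normal
  overdispersion on the latent scale.

Continuous covariates enter the predictor centered (day of year at 135,
decimal hour at 13.5) so intercepts stay interpretable as latent group means.

Seeding uses one master seed with per-individual substreams, so enlarging the
design appends individuals without perturbing earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError, EmptyDesignError, UndefinedCVError

ORDINAL_SCORES = tuple(np.arange(0.0, 3.01, 0.5))  # 7 permitted scores
DAY_CENTER = 135.0
HOUR_CENTER = 13.5
DEFAULT_REPEATS = {1: 0.70, 2: 0.18, 3: 0.07, 4: 0.05}

_STREAM_INDIVIDUAL = 0
_STREAM_YEAR = 1
_STREAM_OBSERVER = 2


@dataclass
class VarianceSpec:
    """Ground-truth simulation specification.

    ``groups`` are habitat labels (model-a style) or location labels
    (model-b style); every per-group mapping must cover all of them.
    """

    family: str = "gaussian"
    groups: Sequence[str] = ("forest", "urban")
    intercept: Mapping[str, float] = field(default_factory=lambda: {"forest": 10.0, "urban": 10.0})
    v_individual: Mapping[str, float] = field(default_factory=lambda: {"forest": 1.0, "urban": 1.0})
    v_residual: Mapping[str, float] = field(default_factory=lambda: {"forest": 1.0, "urban": 1.0})
    v_year: float = 0.0
    v_observer: float = 0.0
    beta_sex: float = 0.0            # indicator of sex == M
    beta_age: float = 0.0            # indicator of age_class == juvenile
    beta_day: float = 0.0            # per centered day of year
    beta_hour: float = 0.0           # per centered decimal hour
    beta_hour2: float = 0.0          # per squared centered decimal hour
    beta_assay_rank: float = 0.0
    beta_protocol: float = 0.0       # indicator of protocol == pre2017
    thresholds: Sequence[float] = (-1.5, -0.9, -0.3, 0.3, 0.9, 1.5)
    n_individuals: Mapping[str, int] | int = 200
    repeats_probs: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_REPEATS))
    n_years: int = 9
    first_year: int = 2014
    n_observers: int = 8
    locations: Mapping[str, Sequence[str]] | None = None
    habitat_of: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.family not in {"gaussian", "ordinal", "poisson"}:
            raise ConfigError(f"unknown family {self.family!r}")
        self.groups = tuple(self.groups)
        for name, mapping in (
            ("intercept", self.intercept),
            ("v_individual", self.v_individual),
            ("v_residual", self.v_residual),
        ):
            missing = set(self.groups) - set(mapping)
            if missing:
                raise ConfigError(f"{name} missing groups: {sorted(missing)}")
        for g in self.groups:
            if self.v_individual[g] < 0 or self.v_residual[g] < 0:
                raise ConfigError("variances must be non-negative")
        if self.v_year < 0 or self.v_observer < 0:
            raise ConfigError("variances must be non-negative")
        if self.family == "ordinal":
            if any(abs(self.v_residual[g] - 1.0) > 1e-12 for g in self.groups):
                raise ConfigError("ordinal residual variance is fixed at 1")
            th = np.asarray(self.thresholds, dtype=float)
            if th.size != 6 or np.any(np.diff(th) <= 0):
                raise ConfigError("ordinal thresholds must be 6 strictly increasing cutpoints")
        probs = np.asarray(list(self.repeats_probs.values()), dtype=float)
        if probs.size == 0 or abs(probs.sum() - 1.0) > 1e-8 or np.any(probs < 0):
            raise ConfigError("repeats_probs must be a probability distribution")
        if max(self.repeats_probs) > self.n_years:
            raise ConfigError("maximum repeat count exceeds n_years")

    # -- design helpers ----------------------------------------------------
    def n_individuals_for(self, group: str) -> int:
        if isinstance(self.n_individuals, Mapping):
            return int(self.n_individuals[group])
        return int(self.n_individuals)

    def locations_for(self, group: str) -> Sequence[str]:
        if self.locations is None:
            return (group,)
        return tuple(self.locations[group])

    def habitat_for(self, group: str) -> str:
        if self.habitat_of is not None:
            return self.habitat_of[group]
        if group in {"forest", "urban"}:
            return group
        return "urban"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["groups"] = list(self.groups)
        d["thresholds"] = list(self.thresholds)
        return d


def _individual_seed(seed: int, index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(seed, spawn_key=(_STREAM_INDIVIDUAL, index))


def simulate_observations(spec: VarianceSpec, seed: int) -> pd.DataFrame:
    """Draw an observation table from ``spec``; deterministic given ``seed``.

    The latent predictor for a row of individual *i* (group *g*) is::

        eta = intercept[g] + fixed part + a_i + u_year + w_observer (+ e)

    with ``a_i ~ N(0, V_i[g])``, ``u ~ N(0, V_y)``, ``w ~ N(0, V_o)`` and
    ``e ~ N(0, V_r[g])``. Each individual is assayed at most once per year in
    consecutive years, so ``assay_rank`` increases chronologically.
    """
    year_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAM_YEAR,)))
    year_effects = year_rng.normal(0.0, np.sqrt(spec.v_year), size=spec.n_years)
    obs_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAM_OBSERVER,)))
    observer_effects = obs_rng.normal(0.0, np.sqrt(spec.v_observer), size=spec.n_observers)

    repeat_ks = np.asarray(list(spec.repeats_probs.keys()), dtype=int)
    repeat_ps = np.asarray(list(spec.repeats_probs.values()), dtype=float)
    repeat_ps = repeat_ps / repeat_ps.sum()

    rows: list[dict] = []
    index = 0
    for group in spec.groups:
        locs = spec.locations_for(group)
        habitat = spec.habitat_for(group)
        v_i = spec.v_individual[group]
        v_r = spec.v_residual[group]
        mu0 = spec.intercept[group]
        for j in range(spec.n_individuals_for(group)):
            rng = np.random.default_rng(_individual_seed(seed, index))
            ind_id = f"{group}_{j:04d}"
            location = locs[j % len(locs)]
            k = int(rng.choice(repeat_ks, p=repeat_ps))
            start = int(rng.integers(0, spec.n_years - k + 1))
            sex = "M" if rng.random() < 0.5 else "F"
            age = "juvenile" if rng.random() < 0.5 else "adult"
            a_i = rng.normal(0.0, np.sqrt(v_i))
            for rank in range(k):
                yi = start + rank
                year = spec.first_year + yi
                day = int(rng.integers(90, 181))
                hour = float(rng.uniform(7.0, 20.0))
                observer = int(rng.integers(0, spec.n_observers))
                protocol = "pre2017" if year < 2017 else "post2017"
                hc = hour - HOUR_CENTER
                eta = (
                    mu0
                    + spec.beta_sex * (sex == "M")
                    + spec.beta_age * (age == "juvenile")
                    + spec.beta_day * (day - DAY_CENTER)
                    + spec.beta_hour * hc
                    + spec.beta_hour2 * hc * hc
                    + spec.beta_assay_rank * rank
                    + spec.beta_protocol * (protocol == "pre2017")
                    + a_i
                    + year_effects[yi]
                    + observer_effects[observer]
                )
                resid = rng.normal(0.0, np.sqrt(v_r)) if spec.family != "ordinal" else rng.normal(0.0, 1.0)
                eta += resid
                if spec.family == "gaussian":
                    value = eta
                elif spec.family == "ordinal":
                    cat = int(np.searchsorted(np.asarray(spec.thresholds), eta, side="left"))
                    value = ORDINAL_SCORES[cat]
                else:  # poisson
                    value = int(rng.poisson(np.exp(eta)))
                rows.append(
                    {
                        "individual_id": ind_id,
                        "location_id": location,
                        "habitat": habitat,
                        "year": year,
                        "observer_id": f"obs_{observer:02d}",
                        "sex": sex,
                        "age_class": age,
                        "day_of_year": day,
                        "decimal_hour": hour,
                        "assay_rank": rank,
                        "protocol": protocol,
                        "value": value,
                    }
                )
            index += 1
    if not rows:
        raise EmptyDesignError("simulation design produced zero observation rows")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Closed-form ground truth
# ---------------------------------------------------------------------------

# Moments of the covariate distributions used by the simulator, for the
# "biologically relevant" fixed-effect variance (sex + hour + hour^2).
_VAR_SEX = 0.25  # Bernoulli(0.5)
_VAR_HOUR = 13.0**2 / 12.0  # U(7, 20) centered
_HALF = 6.5
_E_U2 = _HALF**2 / 3.0
_E_U4 = _HALF**4 / 5.0
_VAR_HOUR2 = _E_U4 - _E_U2**2  # Var((hour - 13.5)^2)


def true_fixed_effect_variance(spec: VarianceSpec) -> float:
    """Population variance of the sex + hour + hour² predictor contribution."""
    return (
        spec.beta_sex**2 * _VAR_SEX
        + spec.beta_hour**2 * _VAR_HOUR
        + spec.beta_hour2**2 * _VAR_HOUR2
    )


def true_marginal_mean(spec: VarianceSpec, group: str) -> float:
    """Latent mean marginalized over balanced sex × age, references elsewhere.

    Continuous covariates sit at their centers, assay_rank at 0, protocol at
    post2017 — mirroring the prediction grid of the decomposition stage.
    """
    return spec.intercept[group] + 0.5 * spec.beta_sex + 0.5 * spec.beta_age


def ground_truth(
    spec: VarianceSpec,
    numerator: str | None = None,
    denominator: str | None = None,
) -> dict:
    """Exact latent-scale truth: variance components, CVs and effect sizes.

    Requires exactly two groups for the pairwise log-ratios. The numerator
    defaults to ``urban`` (or the second group) and the denominator to
    ``forest`` (or the first group), matching the urban/rural convention.
    """
    if len(spec.groups) != 2:
        raise ConfigError("pairwise ground truth requires exactly two groups")
    if numerator is None or denominator is None:
        if set(spec.groups) == {"forest", "urban"}:
            numerator, denominator = "urban", "forest"
        else:
            denominator, numerator = spec.groups

    v_f = true_fixed_effect_variance(spec)
    per_group: dict[str, dict[str, float]] = {}
    for g in spec.groups:
        mean = true_marginal_mean(spec, g)
        v_i = spec.v_individual[g]
        v_r = spec.v_residual[g]
        v_p = v_i + spec.v_year + v_f + v_r
        comp = {
            "mean": mean,
            "V_i": v_i,
            "V_y": spec.v_year,
            "V_f": v_f,
            "V_r": v_r,
            "V_o": spec.v_observer,
            "V_p": v_p,
            "rpt": v_i / v_p if v_p > 0 else np.nan,
        }
        for label, v in (("P", v_p), ("I", v_i), ("R", v_r), ("Y", spec.v_year)):
            if v > 0 and mean == 0:
                raise UndefinedCVError(
                    f"group {g!r}: CV_{label} undefined (zero mean, positive variance)"
                )
            comp[f"CV_{label}"] = np.sqrt(v) / mean if mean != 0 else np.nan
        per_group[g] = comp

    num, den = per_group[numerator], per_group[denominator]

    def _ln(a: float, b: float) -> float:
        if a <= 0 or b <= 0:
            return np.nan
        return float(np.log(a / b))

    effects = {
        "lnRR": _ln(num["mean"], den["mean"]),
        "lnRPT": _ln(num["rpt"], den["rpt"]),
    }
    for label in ("P", "I", "R", "Y"):
        effects[f"lnCVR_{label}"] = _ln(num[f"CV_{label}"], den[f"CV_{label}"])
    return {
        "per_group": per_group,
        "effects": effects,
        "numerator": numerator,
        "denominator": denominator,
    }


def write_observations(
    table: pd.DataFrame, path: str | Path, spec: VarianceSpec | None = None, seed: int | None = None
) -> None:
    """Write the table as CSV with a key-value provenance sidecar."""
    path = Path(path)
    table.to_csv(path, index=False)
    if spec is not None:
        import yaml

        meta = {"seed": seed, "spec": spec.to_dict(), "n_rows": int(len(table))}
        path.with_suffix(path.suffix + ".meta.yaml").write_text(
            yaml.safe_dump(meta, sort_keys=False)
        )
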