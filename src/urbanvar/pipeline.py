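"""Pipeline orchestration: typed I/O, run configuration and stage wiring.

A single run directory collects every stage output plus a provenance
manifest (stage list, seeds, SHA-256 of inputs), so any numeric artifact can
be regenerated from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import effects as effects_mod
from . import gradient as gradient_mod
from . import hetvar, landscape, partition, synthetic
from .errors import ConfigError, SchemaError

log = logging.getLogger("urbanvar")

REQUIRED_COLUMNS = (
    "individual_id", "location_id", "habitat", "year", "observer_id", "sex",
    "age_class", "day_of_year", "decimal_hour", "assay_rank", "protocol", "value",
)
_ORDINAL_OK = {round(0.5 * k, 1) for k in range(7)}


def read_observations(path: str | Path, family: str = "gaussian") -> pd.DataFrame:
    """Read and validate an observation CSV.

    Rows with a missing trait value are dropped (and counted in the log);
    ordinal values must be one of the 7 permitted scores 0–3 by 0.5.
    """
    df = pd.read_csv(path)
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"observation CSV missing column(s): {sorted(missing)}")
    n0 = len(df)
    df = df.dropna(subset=["value"]).reset_index(drop=True)
    if len(df) < n0:
        log.info("dropped %d rows with missing trait values", n0 - len(df))
    if family == "ordinal":
        vals = df["value"].astype(float).round(1)
        bad = ~vals.isin(_ORDINAL_OK)
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ValueError(
                f"ordinal value {df['value'].iloc[row]!r} at row {row} "
                "not in {0, 0.5, ..., 3}"
            )
    if family == "poisson":
        vals = df["value"].astype(float)
        if (vals < 0).any() or not np.allclose(vals, vals.round()):
            raise ValueError("poisson trait values must be non-negative integers")
    df["year"] = df["year"].astype(int)
    df["day_of_year"] = df["day_of_year"].astype(int)
    df["assay_rank"] = df["assay_rank"].astype(int)
    return df


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunConfig:
    """Everything one end-to-end run needs; loadable from YAML."""

    trait: str = "trait"
    family: str = "gaussian"
    out_dir: str = "runs/demo"
    seed: int = 0
    observations_csv: str | None = None  # None → simulate
    raster_path: str | None = None       # None → synthetic raster
    nest_boxes_csv: str | None = None
    stages: Sequence[str] = ("simulate", "quantify_isa", "fit", "decompose", "effects", "gradient", "scale_of_effect")
    scales_m: Sequence[float] = landscape.DEFAULT_SCALES_M
    min_obs: int = 30
    gradient_response: str = "CV_I"
    n_iterations_used: int = 1000
    draws_per_iteration: int = 100
    mcmc: Mapping[str, int] = field(default_factory=dict)
    simulation: Mapping[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _demo_spec(config: RunConfig) -> synthetic.VarianceSpec:
    """Model-b style demo design: 1 forest + 8 urban locations."""
    sim = dict(config.simulation)
    locs = ["FOR"] + [f"URB{i}" for i in range(1, 9)]
    defaults = dict(
        family=config.family,
        groups=locs,
        intercept={g: 10.0 + 0.1 * i for i, g in enumerate(locs)},
        v_individual={g: 0.8 + 0.15 * i for i, g in enumerate(locs)},
        v_residual={g: 1.0 for g in locs} if config.family != "ordinal" else {g: 1.0 for g in locs},
        v_year=0.1,
        v_observer=0.05,
        beta_sex=0.5,
        beta_hour=0.05,
        beta_hour2=-0.01,
        n_individuals={g: (20 if g in {"URB1", "URB2"} else 60) for g in locs},
        habitat_of={g: ("forest" if g == "FOR" else "urban") for g in locs},
    )
    if config.family == "ordinal":
        defaults["intercept"] = {g: 1.5 + 0.05 * i for i, g in enumerate(locs)}
        defaults["v_individual"] = {g: 0.4 + 0.08 * i for i, g in enumerate(locs)}
    if config.family == "poisson":
        defaults["intercept"] = {g: 2.0 + 0.03 * i for i, g in enumerate(locs)}
        defaults["v_individual"] = {g: 0.2 + 0.05 * i for i, g in enumerate(locs)}
        defaults["v_residual"] = {g: 0.3 for g in locs}
        defaults["v_year"] = 0.05
        defaults["v_observer"] = 0.02
    defaults.update(sim)
    return synthetic.VarianceSpec(**defaults)


def _demo_boxes(locations: Sequence[str], rng: np.random.Generator, raster: landscape.ISARaster) -> list[landscape.NestBox]:
    xmin, ymin, xmax, ymax = raster.extent
    span_x, span_y = xmax - xmin, ymax - ymin
    boxes = []
    # forest site near the low-ISA (left) edge, urban sites spread rightward
    for i, loc in enumerate(locations):
        cx = xmin + span_x * (0.12 + 0.76 * i / max(len(locations) - 1, 1))
        cy = ymin + span_y * 0.5
        for b in range(6):
            boxes.append(
                landscape.NestBox(
                    box_id=f"{loc}_box{b}",
                    location_id=loc,
                    x_m=float(np.clip(cx + rng.normal(0, span_x * 0.02), xmin, xmax)),
                    y_m=float(np.clip(cy + rng.normal(0, span_y * 0.1), ymin, ymax)),
                )
            )
    return boxes


def run(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Deterministic given the master seed. Each stage appends an entry to the
    provenance manifest; a stage failure leaves earlier outputs in place and
    is recorded in the manifest with ``status: failed``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": config.seed, "trait": config.trait,
                               "family": config.family, "stages": []}
    stage_set = set(config.stages)
    rng = np.random.default_rng(config.seed)

    def record(stage: str, outputs: list[str], status: str = "ok", **extra) -> None:
        entry = {"stage": stage, "status": status, "outputs": outputs, **extra}
        for o in outputs:
            p = out / o
            if p.exists():
                entry.setdefault("hashes", {})[o] = sha256_file(p)
        manifest["stages"].append(entry)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    try:
        # ------------------------------------------------------------------
        if "simulate" in stage_set or config.observations_csv is None:
            spec = _demo_spec(config)
            table = synthetic.simulate_observations(spec, seed=config.seed)
            synthetic.write_observations(table, out / "observations.csv", spec, config.seed)
            record("simulate", ["observations.csv"], seed=config.seed)
        else:
            table = read_observations(config.observations_csv, config.family)
            record("load_observations", [], source=str(config.observations_csv),
                   source_sha256=sha256_file(config.observations_csv))
            spec = None
        locations = sorted(table["location_id"].unique())

        # ------------------------------------------------------------------
        site_frames = {}
        if "quantify_isa" in stage_set:
            if config.raster_path:
                raster = landscape.read_raster(config.raster_path)
            else:
                raster = landscape.generate_synthetic_isa_raster(
                    300, 120, resolution_m=10.0, pattern="gradient", seed=config.seed
                )
                landscape.write_ascii_grid(raster, out / "isa_raster.asc")
            if config.nest_boxes_csv:
                boxes = landscape.read_nest_boxes(config.nest_boxes_csv)
            else:
                boxes = _demo_boxes(locations, rng, raster)
                pd.DataFrame(
                    [{"box_id": b.box_id, "location_id": b.location_id,
                      "x_m": b.x_m, "y_m": b.y_m} for b in boxes]
                ).to_csv(out / "nest_boxes.csv", index=False)
            frames = []
            for scale in config.scales_m:
                summaries = landscape.site_isa_summary(raster, boxes, scale)
                frames.append(landscape.site_summaries_to_frame(summaries))
            site_df = pd.concat(frames, ignore_index=True)
            site_df.to_csv(out / "site_isa.csv", index=False)
            for scale in config.scales_m:
                site_frames[scale] = site_df[site_df["scale_m"] == scale].set_index("location_id")
            record("quantify_isa", ["isa_raster.asc", "nest_boxes.csv", "site_isa.csv"])

        # ------------------------------------------------------------------
        draws = None
        if "fit" in stage_set:
            mcmc_kwargs = dict(n_iter=6000, burn_in=2000, thin=4, seed=config.seed)
            mcmc_kwargs.update(config.mcmc)
            model = hetvar.ModelConfig(
                family=config.family,
                variance_grouping="by_location",
                mcmc=hetvar.MCMCOptions(**mcmc_kwargs),
            )
            draws = hetvar.fit(table, model)
            draws.save(out / "model_b")
            ess = hetvar.effective_sample_size(draws)
            report = hetvar.convergence_check(draws, ess_threshold=min(1000, draws.n_kept))
            report.table.to_csv(out / "model_b" / "convergence.csv", index=False)
            record("fit", ["model_b/posterior_draws.csv", "model_b/run_metadata.yaml",
                           "model_b/convergence.csv"],
                   min_ess=float(min(ess.values())), failures=report.failures)

        # ------------------------------------------------------------------
        summary = None
        if "decompose" in stage_set and draws is not None:
            components, summary = partition.decompose(draws, table)
            components.frame.to_csv(out / "variance_components.csv", index=False)
            summary.frame.to_csv(out / "cv_summary.csv", index=False)
            partition.components_summary(components).to_csv(
                out / "variance_components_summary.csv", index=False
            )
            record("decompose", ["variance_components.csv", "cv_summary.csv",
                                 "variance_components_summary.csv"])

        # ------------------------------------------------------------------
        if "effects" in stage_set and summary is not None:
            hab = table[["location_id", "habitat"]].drop_duplicates().set_index("location_id")["habitat"]
            cvf = summary.frame.copy()
            cvf["habitat"] = cvf["group"].map(hab)
            # aggregate latent CVs to habitat level per draw (mean over locations)
            agg_cols = [c for c in ("mean", "CV_P", "CV_I", "CV_R", "rpt") if c in cvf.columns]
            hab_frame = cvf.groupby(["draw", "habitat"], as_index=False)[agg_cols].mean()
            hab_frame = hab_frame.rename(columns={"habitat": "group"})
            hab_summary = partition.CVSummary(hab_frame, summary.family)
            eff = effects_mod.habitat_effect_sizes(hab_summary)
            (out / "effect_sizes.json").write_text(
                json.dumps(effects_mod.effects_report(eff), indent=2, sort_keys=True)
            )
            pd.DataFrame({k: v.draws for k, v in eff.items()}).to_csv(
                out / "effect_size_draws.csv", index=False
            )
            record("effects", ["effect_sizes.json", "effect_size_draws.csv"])

        # ------------------------------------------------------------------
        r2_by_scale: dict[float, float] = {}
        if "gradient" in stage_set and summary is not None and site_frames:
            counts = table["location_id"].value_counts().to_dict()
            included = gradient_mod.filter_locations(counts, config.min_obs)
            n_use = min(config.n_iterations_used, draws.n_kept)
            forest_locs = set(table.loc[table["habitat"] == "forest", "location_id"])
            for scale, site_df in site_frames.items():
                locs = [l for l in included if l in site_df.index]
                variants = [(locs, True)]
                no_forest = [l for l in locs if l not in forest_locs]
                if len(no_forest) >= 3 and no_forest != locs:
                    variants.append((no_forest, False))
                for use_locs, with_forest in variants:
                    cv = gradient_mod.cv_matrix_from_summary(
                        summary.frame, config.gradient_response, use_locs
                    )
                    try:
                        fit2 = gradient_mod.per_iteration_regression(
                            cv,
                            site_df.loc[use_locs, "mean_isa"].to_numpy(),
                            site_df.loc[use_locs, "var_isa"].to_numpy(),
                            n_iterations_used=n_use,
                            draws_per_iteration=config.draws_per_iteration,
                            seed=config.seed,
                            scale_m=scale,
                            response=config.gradient_response,
                            locations=use_locs,
                            with_forest=with_forest,
                        )
                    except (gradient_mod.CollinearityError,
                            gradient_mod.InsufficientSitesError) as exc:
                        if with_forest:
                            raise
                        # sensitivity variant only: record and move on
                        log.warning("no-forest gradient at %sm skipped: %s", scale, exc)
                        continue
                    suffix = "" if with_forest else "_noforest"
                    name = f"gradient_{config.gradient_response}_{int(scale)}m{suffix}.json"
                    (out / name).write_text(
                        json.dumps(fit2.to_dict(), indent=2, sort_keys=True)
                    )
                    if with_forest:
                        r2_by_scale[scale] = fit2.r2_mean
            pd.DataFrame(
                [{"scale_m": s, "r2_mean": r} for s, r in sorted(r2_by_scale.items())]
            ).to_csv(out / "r2_by_scale.csv", index=False)
            record("gradient",
                   [f"gradient_{config.gradient_response}_{int(s)}m.json" for s in site_frames]
                   + ["r2_by_scale.csv"])

        # ------------------------------------------------------------------
        if "scale_of_effect" in stage_set and r2_by_scale:
            chosen = gradient_mod.scale_of_effect(r2_by_scale)
            (out / "scale_of_effect.json").write_text(
                json.dumps({"response": config.gradient_response,
                            "scale_of_effect_m": chosen,
                            "r2_by_scale": {str(k): v for k, v in sorted(r2_by_scale.items())}},
                           indent=2, sort_keys=True)
            )
            record("scale_of_effect", ["scale_of_effect.json"])
    except Exception as exc:
        record("error", [], status="failed", error=f"{type(exc).__name__}: {exc}")
        raise

    skipped = [s for s in ("simulate", "quantify_isa", "fit", "decompose",
                           "effects", "gradient", "scale_of_effect")
               if s not in stage_set]
    manifest["skipped_stages"] = skipped
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
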