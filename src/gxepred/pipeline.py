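"""End-to-end orchestration of the simulation-to-attribution pipeline.

``run_pipeline`` executes the stages
simulate -> kinship -> erm -> fit -> cv -> project -> stability ->
attribute from a single configuration (YAML path or dict), persisting
every stage's outputs as CSV under the output directory and returning a
manifest (stage, seed, wall time, output digests).  Any stage can be
toggled off; later stages reload persisted intermediates so reruns are
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import climate as climate_mod
from . import stability as stability_mod
from .attribution import attribute
from .config import SimulationConfig
from .envirotyping import gaussian_kernel, standardize_ecs
from .kernels import ModelDesign, build_kernels
from .models import McmcSettings, extract_variance_components, fit_model
from .simulate import simulate_dataset
from .validation import leave_one_year_out_cv, trial_accuracy, year_mean_accuracy

__all__ = ["run_pipeline", "DEFAULT_STAGES"]

logger = logging.getLogger(__name__)

DEFAULT_STAGES = ("simulate", "kinship", "erm", "fit", "cv", "project",
                  "stability", "attribute")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, float_format="%.10g")
    return path


def run_pipeline(config: dict | str | Path) -> list[dict]:
    """Run the toggled stages and return the manifest.

    Config keys: ``out_dir``; ``seed``; ``stages`` (list, default all);
    ``simulation`` (SimulationConfig overrides); ``model_type``; ``mcmc``
    (iterations/burn_in/thin); ``cv_mcmc``; ``n_projection_genotypes``;
    ``projection_locations``.  The stability stage requires the trait to
    have a quality criterion.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    out_dir = Path(config.get("out_dir", "pipeline_out"))
    stages = tuple(config.get("stages", DEFAULT_STAGES))
    unknown = set(stages) - set(DEFAULT_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s) {sorted(unknown)}")
    seed = int(config.get("seed", 0))
    sim_cfg = SimulationConfig(seed=seed, **config.get("simulation", {}))
    if "stability" in stages and \
            sim_cfg.trait not in stability_mod.QUALITY_CRITERIA:
        raise ValueError(
            f"stability stage enabled but no quality criteria for trait "
            f"{sim_cfg.trait!r}")
    model_type = config.get("model_type", "RNMM")
    mcmc = McmcSettings(seed=seed, **config.get(
        "mcmc", {"iterations": 10000, "burn_in": 2000, "thin": 2}))
    cv_mcmc = McmcSettings(seed=seed, **config.get(
        "cv_mcmc", {"iterations": 2000, "burn_in": 500, "thin": 2}))

    manifest: list[dict] = []
    state: dict = {}

    def record(stage, t0, outputs):
        manifest.append({
            "stage": stage, "seed": seed,
            "wall_time_s": round(time.perf_counter() - t0, 3),
            "outputs": {p.name: _digest(p) for p in outputs},
        })

    for stage in DEFAULT_STAGES:
        if stage not in stages:
            continue
        t0 = time.perf_counter()
        try:
            outputs = _run_stage(stage, state, sim_cfg, model_type, mcmc,
                                 cv_mcmc, config, out_dir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        record(stage, t0, outputs)
        logger.info("stage %s done (%.1fs)", stage,
                    manifest[-1]["wall_time_s"])

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _run_stage(stage, state, sim_cfg, model_type, mcmc, cv_mcmc, config,
               out_dir) -> list[Path]:
    if stage == "simulate":
        ds = simulate_dataset(sim_cfg)
        state["ds"] = ds
        return [
            _write(ds.pedigree, out_dir / "pedigree.csv", index=False),
            _write(ds.markers, out_dir / "markers.csv"),
            _write(ds.phenotypes, out_dir / "phenotypes.csv", index=False),
            _write(ds.environments, out_dir / "ec.csv"),
            _write(ds.climate, out_dir / "climate.csv", index=False),
            _write(ds.soil, out_dir / "soil.csv"),
        ]
    ds = state.get("ds")
    if ds is None:
        raise ValueError("pipeline state missing; run the simulate stage")
    if stage == "kinship":
        return [_write(ds.A, out_dir / "A.csv"),
                _write(ds.H, out_dir / "H.csv")]
    if stage == "erm":
        return [_write(ds.Omega, out_dir / "omega.csv")]
    if stage == "fit":
        design = ModelDesign.from_frame(ds.phenotypes)
        kernels = build_kernels(design, ds.H, ds.Omega)
        model = fit_model(ds.phenotypes["value"].to_numpy(), kernels,
                          model_type, mcmc)
        state["model"] = model
        comps = extract_variance_components(model).to_frame("percent")
        return [_write(comps, out_dir / "variance_components.csv")]
    if stage == "cv":
        cv = leave_one_year_out_cv(ds.phenotypes, ds.H, ds.Omega,
                                   model_type, cv_mcmc)
        acc = trial_accuracy(cv)
        summary = pd.DataFrame([{
            "model_type": model_type,
            "year_mean_r": year_mean_accuracy(cv),
            "trial_mean_r": acc["r"].mean(),
            "trial_median_r": acc["r"].median(),
        }])
        return [_write(cv.predictions, out_dir / "cv_predictions.csv",
                       index=False),
                _write(acc, out_dir / "cv_trial_accuracy.csv", index=False),
                _write(summary, out_dir / "cv_summary.csv", index=False)]
    if stage == "project":
        model = state.get("model")
        if model is None:
            raise ValueError("project stage needs the fit stage")
        locs = config.get("projection_locations") \
            or sorted(ds.soil.index)[:3]
        observed = ds.climate[ds.climate["role"] == "observed"]
        raw = ds.climate[ds.climate["role"] == "raw_projection"]
        corrected = climate_mod.bias_correct_series(
            raw, observed, baseline_years=sim_cfg.years,
            future_years=sim_cfg.future_years)
        envs = climate_mod.build_projection_environments(
            locs, observed, corrected, ds.soil, mode="year_samples",
            baseline_years=sim_cfg.years, future_years=sim_cfg.future_years)
        n_g = int(config.get("n_projection_genotypes",
                             len(ds.H.index)))
        genotypes = list(ds.H.index)[:n_g]
        proj = climate_mod.project_traits(model, envs, genotypes, ds.H,
                                          ds.environments,
                                          trait=sim_cfg.trait)
        state["projection"] = proj
        state["proj_envs"] = envs
        return [_write(proj, out_dir / "projection.csv", index=False),
                _write(envs.env_table, out_dir / "projection_envs.csv",
                       index=False)]
    if stage == "stability":
        proj = state.get("projection")
        if proj is None:
            raise ValueError("stability stage needs the project stage")
        envs = state["proj_envs"]
        loc_map = envs.env_table.set_index("environment")["location"]
        records = []
        for loc, env_grp in proj.assign(
                location=proj["environment"].map(loc_map)) \
                .groupby("location"):
            fw = stability_mod.finlay_wilkinson(
                env_grp[["genotype", "environment", "predicted"]],
                trait=sim_cfg.trait, location=loc)
            risk = stability_mod.risk_index(
                env_grp[["genotype", "environment", "predicted"]],
                sim_cfg.trait)
            fw["risk_pct"] = fw["genotype"].map(risk).to_numpy()
            records.append(fw)
        stab = pd.concat(records, ignore_index=True)
        state["stability"] = stab
        return [_write(stab, out_dir / "stability.csv", index=False)]
    if stage == "attribute":
        proj = state.get("projection")
        if proj is None:
            raise ValueError("attribute stage needs the project stage")
        envs = state["proj_envs"]
        result = attribute(proj, envs.ec, envs.env_table,
                           seed=int(config.get("seed", 0)))
        return [_write(result, out_dir / "attribution.csv", index=False)]
    raise ValueError(f"unknown stage {stage!r}")
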