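"""Climate-ensemble bias correction and future-environment projection.

Each ensemble member's monthly series is corrected, per location x
variable x calendar month, so that its baseline-period mean and variance
match the observed series while the projected change signal is preserved:

    Xbc(t) = Obar_B - Xbar_B + Xbar_fut + (sd_O / sd_XB) * (X(t) - Xbar_fut)

Rainfall is corrected on the natural-log scale and relative humidity as
100 - RH so corrected values respect physical bounds.  Corrected series
feed two kinds of projection environments: a climatological pair per
location (observed average vs future average, for mean climate-change
effects) and year samples (one environment per ensemble member x year, for
year-to-year variability, stability and risk analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SEASON_MONTHS, SOIL_VARIABLES, WEATHER_VARIABLES
from .envirotyping import ec_columns, gaussian_kernel, standardize_ecs
from .kernels import MODEL_COMPONENTS
from .models import FittedKernelModel, prediction_coefficients

__all__ = [
    "ProjectedEnvironmentSet", "bias_correct_series",
    "climatological_average", "impute_soil_median",
    "build_projection_environments", "project_traits",
    "BASELINE_YEARS", "FUTURE_YEARS",
]

BASELINE_YEARS = range(2000, 2020)
FUTURE_YEARS = range(2050, 2070)

_RAIN_FLOOR = 0.01   # mm/day floor before the log transform


def _transform(var: str, x: np.ndarray) -> np.ndarray:
    if var == "rainfall":
        if np.any(x < 0):
            raise ValueError("negative rainfall in input series")
        return np.log(np.maximum(x, _RAIN_FLOOR))
    if var == "humidity":
        # correct the saturation deficit on the log scale so the
        # back-transformed humidity stays strictly below 100%
        if np.any((x <= 0) | (x >= 100)):
            raise ValueError("relative humidity outside (0, 100)")
        return np.log(100.0 - x)
    return x


def _back_transform(var: str, z: np.ndarray) -> np.ndarray:
    if var == "rainfall":
        return np.exp(z)
    if var == "humidity":
        return np.maximum(100.0 - np.exp(z), 0.05)
    return z


def bias_correct_series(
    model: pd.DataFrame,
    obs: pd.DataFrame,
    baseline_years=BASELINE_YEARS,
    future_years=FUTURE_YEARS,
) -> pd.DataFrame:
    """Mean/variance bias correction of ensemble members against observations.

    ``model`` holds raw member series covering both the baseline and future
    windows; ``obs`` holds the observed series over the baseline window.
    Correction is applied independently per location x variable x month x
    member, on the transformed scale for rainfall and humidity.  Returns
    the corrected future series (role ``bias_corrected``).
    """
    baseline_years = set(baseline_years)
    future_years = set(future_years)
    obs_b = obs[obs["year"].isin(baseline_years)]
    mod_b = model[model["year"].isin(baseline_years)]
    mod_f = model[model["year"].isin(future_years)]
    if len(obs_b) == 0 or len(mod_b) == 0 or len(mod_f) == 0:
        raise ValueError("series do not cover the baseline/future windows")

    key_obs = ["location", "variable", "month"]
    key_mod = key_obs + ["member"]

    def add_t(df):
        df = df.copy()
        tv = np.empty(len(df))
        for var, idx in df.groupby("variable").groups.items():
            tv[df.index.get_indexer(idx)] = _transform(
                var, df.loc[idx, "value"].to_numpy())
        df["tvalue"] = tv
        return df

    obs_b, mod_b, mod_f = add_t(obs_b), add_t(mod_b), add_t(mod_f)

    o_mean = obs_b.groupby(key_obs)["tvalue"].mean().rename("o_mean")
    o_sd = obs_b.groupby(key_obs)["tvalue"].std(ddof=1).rename("o_sd")
    b_mean = mod_b.groupby(key_mod)["tvalue"].mean().rename("b_mean")
    b_sd = mod_b.groupby(key_mod)["tvalue"].std(ddof=1).rename("b_sd")
    f_mean = mod_f.groupby(key_mod)["tvalue"].mean().rename("f_mean")

    out = mod_f.merge(o_mean, on=key_obs).merge(o_sd, on=key_obs) \
               .merge(b_mean, on=key_mod).merge(b_sd, on=key_mod) \
               .merge(f_mean, on=key_mod)
    if (out["b_sd"] == 0).any():
        bad = out.loc[out["b_sd"] == 0, key_mod].iloc[0].tolist()
        raise ValueError(f"zero baseline variance for series {bad}")
    z = (out["o_mean"] - out["b_mean"] + out["f_mean"]
         + (out["o_sd"] / out["b_sd"]) * (out["tvalue"] - out["f_mean"]))
    corrected = np.empty(len(out))
    for var, idx in out.groupby("variable").groups.items():
        corrected[out.index.get_indexer(idx)] = _back_transform(
            var, z[idx].to_numpy())
    result = out[["member", "location", "year", "month", "variable"]].copy()
    result.insert(0, "role", "bias_corrected")
    result["value"] = corrected
    return result.reset_index(drop=True)


def climatological_average(series: pd.DataFrame, years) -> pd.DataFrame:
    """Per-location monthly means over a span of years (and all members).

    Returns a frame indexed by (location, variable, month) with a ``value``
    column.  Raises when any requested year is absent from the series.
    """
    years = list(years)
    have = set(series["year"].unique())
    missing = [y for y in years if y not in have]
    if missing:
        raise ValueError(f"series does not cover year(s) {missing[:5]}")
    sub = series[series["year"].isin(set(years))]
    return (sub.groupby(["location", "variable", "month"])["value"]
            .mean().to_frame())


def impute_soil_median(soil: pd.DataFrame) -> pd.DataFrame:
    """Replace missing soil cells by the column median over all locations."""
    if soil.notna().sum(axis=0).eq(0).any():
        bad = soil.columns[soil.notna().sum(axis=0) == 0][0]
        raise ValueError(f"soil column {bad!r} is fully missing")
    return soil.fillna(soil.median(axis=0))


@dataclass
class ProjectedEnvironmentSet:
    """Future (or average-climate) environments with full EC rows."""

    env_table: pd.DataFrame   # environment, location, scenario, member, year
    ec: pd.DataFrame          # environment x covariate (unscaled)
    provenance: dict

    def __len__(self) -> int:
        return len(self.env_table)


def _ec_row_from_monthly(monthly: pd.DataFrame, location: str,
                         soil: pd.DataFrame) -> dict:
    row = {}
    for var in WEATHER_VARIABLES:
        for month in SEASON_MONTHS:
            key = (location, var, month)
            if key not in monthly.index:
                raise ValueError(f"no weather value for {key}")
            row[f"{var}_{month}"] = float(monthly.loc[key, "value"])
    if location not in soil.index:
        raise ValueError(f"no soil data for location {location!r}")
    for svar in SOIL_VARIABLES:
        row[svar] = float(soil.loc[location, svar])
    return row


def build_projection_environments(
    locations,
    observed: pd.DataFrame,
    corrected_future: pd.DataFrame,
    soil: pd.DataFrame,
    mode: str = "climatological_pair",
    baseline_years=BASELINE_YEARS,
    future_years=FUTURE_YEARS,
) -> ProjectedEnvironmentSet:
    """Assemble EC rows for projection environments.

    ``climatological_pair`` builds two environments per location (observed
    average over the baseline window, future average over years and
    ensemble members); ``year_samples`` builds one environment per
    (location, member, year) from the corrected member series directly.
    """
    locations = list(locations)
    rows, meta = [], []
    if mode == "climatological_pair":
        obs_avg = climatological_average(observed, baseline_years)
        fut_avg = climatological_average(corrected_future, future_years)
        for loc in locations:
            for scenario, monthly in (("observed_avg", obs_avg),
                                      ("future_avg", fut_avg)):
                env = f"{loc}_{scenario}"
                rows.append(_ec_row_from_monthly(monthly, loc, soil))
                meta.append({"environment": env, "location": loc,
                             "scenario": scenario, "member": pd.NA,
                             "year": pd.NA})
    elif mode == "year_samples":
        sub = corrected_future[
            corrected_future["location"].isin(set(locations))
            & corrected_future["year"].isin(set(future_years))]
        pivot = sub.pivot_table(index=["location", "member", "year"],
                                columns=["variable", "month"],
                                values="value")
        for loc in locations:
            if loc not in pivot.index.get_level_values(0):
                raise ValueError(f"no corrected series for location {loc!r}")
            if loc not in soil.index:
                raise ValueError(f"no soil data for location {loc!r}")
        for (loc, member, year), cells in pivot.iterrows():
            if loc not in locations:
                continue
            row = {}
            for var in WEATHER_VARIABLES:
                for month in SEASON_MONTHS:
                    val = cells.get((var, month), np.nan)
                    if pd.isna(val):
                        raise ValueError(
                            f"missing {var}_{month} for ({loc}, member "
                            f"{member}, {year})")
                    row[f"{var}_{month}"] = float(val)
            for svar in SOIL_VARIABLES:
                row[svar] = float(soil.loc[loc, svar])
            rows.append(row)
            meta.append({"environment": f"{loc}_m{int(member):02d}_y{year}",
                         "location": loc, "scenario": "year_sample",
                         "member": int(member), "year": int(year)})
    else:
        raise ValueError(f"unknown mode {mode!r}")
    env_table = pd.DataFrame(meta)
    ec = pd.DataFrame(rows, index=pd.Index(env_table["environment"],
                                           name="environment"))
    ec = ec[ec_columns()]
    ec.attrs["scaled"] = False
    return ProjectedEnvironmentSet(
        env_table=env_table, ec=ec,
        provenance={"mode": mode, "baseline_years": list(baseline_years),
                    "future_years": list(future_years),
                    "n_locations": len(locations)})


def project_traits(
    model: FittedKernelModel,
    envs: ProjectedEnvironmentSet,
    genotypes,
    H: pd.DataFrame,
    training_ecs: pd.DataFrame,
    trait: str = "trait",
) -> pd.DataFrame:
    """Predict every genotype in every projection environment.

    The joint enviromic kernel is rebuilt over training + projection
    environments from the raw EC tables (scaled jointly).  The genotype x
    environment grid is predicted through the factorised cross-kernel, so
    the full record set (e.g. 20 genotypes x 1707 grid cells x 2 scenarios)
    is produced without materialising an observation-level kernel.

    Returns one record per genotype x environment with columns
    ``genotype, environment, trait, predicted``.
    """
    genotypes = list(genotypes)
    missing = set(genotypes) - set(H.index)
    if missing:
        raise ValueError(f"genotype(s) {sorted(missing)[:3]} absent from H")
    needs_omega = "gW" in MODEL_COMPONENTS[model.model_type]
    env_labels = envs.ec.index.tolist()

    omega_joint = None
    if needs_omega:
        joint_ec = pd.concat([training_ecs, envs.ec], axis=0)
        if joint_ec.index.has_duplicates:
            raise ValueError("projection environment labels collide with "
                             "training environments")
        omega_joint = gaussian_kernel(standardize_ecs(joint_ec)).matrix

    coef = prediction_coefficients(model, H, omega_joint)
    train = model.design

    # accumulate representer coefficients per training genotype (for g) and
    # per genotype x environment pair (for gW); the grid prediction then
    # factorises into small matrix products
    tg = pd.unique(train.genotype)
    te = pd.unique(train.environment)
    gi = train.genotype.map({g: i for i, g in enumerate(tg)}).to_numpy()
    ei = train.environment.map({e: i for i, e in enumerate(te)}).to_numpy()
    sg = np.bincount(gi, weights=coef, minlength=len(tg))
    S = np.zeros((len(tg), len(te)))
    np.add.at(S, (gi, ei), coef)

    Hc = H.loc[genotypes, list(tg)].to_numpy()
    pred = model.mu + model.variances["g"] * (Hc @ sg)[:, None]
    pred = np.tile(pred, (1, len(env_labels)))
    if needs_omega:
        Oc = omega_joint.loc[env_labels, list(te)].to_numpy()
        se = S.sum(axis=0)                       # per-environment totals
        if "W" in MODEL_COMPONENTS[model.model_type]:
            pred += model.variances["W"] * (Oc @ se)[None, :]
        pred += model.variances["gW"] * (Hc @ S @ Oc.T)

    out = pd.DataFrame(pred, index=pd.Index(genotypes, name="genotype"),
                       columns=pd.Index(env_labels, name="environment"))
    long = out.reset_index().melt(id_vars="genotype",
                                  value_name="predicted")
    long["trait"] = trait
    return long[["genotype", "environment", "trait", "predicted"]]
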