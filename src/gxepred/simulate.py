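"""Synthetic trial networks, genomes, weather and phenotypes.

Every downstream stage of the pipeline (relationship matrices, kernel
models, cross-validation, climate projection, stability analysis) is
exercised on data produced here.  The generator mirrors the statistical
structure of a long-running national variety-testing series:

* inbred-line pedigrees (biparental crosses followed by repeated selfing);
* marker genotypes obtained by Mendelian gene dropping through the
  pedigree, so pedigree and marker relationship matrices agree in
  expectation;
* an unbalanced trial network in which each genotype is tested only during
  a contiguous window of years;
* seasonal monthly weather per trial location with shared year effects,
  plus a climate-model ensemble whose members carry mean biases and
  inflated variance (so that bias correction is a non-trivial step);
* phenotypes drawn from the full reaction-norm variance-component model
  y = mu + E + g + gE + gW + eps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import (MONTH_NUMBER, SEASON_MONTHS, SOIL_VARIABLES,
                     WEATHER_VARIABLES, ClimateShift, SimulationConfig)

__all__ = [
    "SyntheticDataset",
    "simulate_pedigree",
    "simulate_marker_matrix",
    "simulate_trial_network",
    "simulate_weather_series",
    "simulate_soil",
    "simulate_phenotypes",
    "simulate_dataset",
]


# ---------------------------------------------------------------------------
# pedigree and markers
# ---------------------------------------------------------------------------

def simulate_pedigree(config: SimulationConfig) -> pd.DataFrame:
    """Simulate an inbred-line pedigree of biparental crosses.

    Founders are unrelated lines with unknown parents.  Each later
    generation is produced by crossing two distinct parents drawn from any
    earlier generation; all lines carry ``inbreeding_gens`` extra selfing
    generations (inbred-line development after the cross).

    Returns a frame with columns ``id, parent1, parent2, generation,
    inbreeding_gens``; parents of founders are ``<NA>``.
    """
    if config.n_founders < 2:
        raise ValueError("n_founders must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    ids = [f"F{i:03d}" for i in range(config.n_founders)]
    rows = [(i, pd.NA, pd.NA, 0) for i in ids]
    n_extra = max(config.n_genotypes - config.n_founders, 0)
    if config.n_generations > 0 and n_extra > 0:
        per_gen = _split_counts(n_extra, config.n_generations)
        for gen in range(1, config.n_generations + 1):
            pool = [r[0] for r in rows]
            for j in range(per_gen[gen - 1]):
                p1, p2 = rng.choice(len(pool), size=2, replace=False)
                rows.append((f"G{gen}_{j:03d}", pool[p1], pool[p2], gen))
    ped = pd.DataFrame(rows, columns=["id", "parent1", "parent2", "generation"])
    # selfing generations of inbred-line development, distinct from the
    # crossing depth of the pedigree
    ped["inbreeding_gens"] = 6
    return ped


def _split_counts(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def simulate_marker_matrix(
    pedigree: pd.DataFrame,
    n_markers: int,
    founder_maf_range: tuple[float, float] = (0.1, 0.45),
    seed: int = 0,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Gene-drop biallelic markers through an inbred-line pedigree.

    Founder alleles are drawn per marker at a frequency uniform in
    ``founder_maf_range``; founders are fully homozygous (calls 0 or 2).
    An offspring line, after selfing to homozygosity, inherits each
    marker's homozygous call from one of its two parents with equal
    probability.  ``missing_rate`` masks calls at random with ``NaN``.
    """
    if len(pedigree) == 0:
        raise ValueError("empty pedigree")
    lo, hi = founder_maf_range
    if not (0 < lo <= hi < 0.5):
        raise ValueError("founder_maf_range must satisfy 0 < lo <= hi < 0.5")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    freqs = rng.uniform(lo, hi, size=n_markers)
    calls: dict[str, np.ndarray] = {}
    for rec in pedigree.itertuples(index=False):
        if pd.isna(rec.parent1) or pd.isna(rec.parent2):
            calls[rec.id] = 2.0 * (rng.random(n_markers) < freqs)
        else:
            from_p1 = rng.random(n_markers) < 0.5
            calls[rec.id] = np.where(from_p1, calls[rec.parent1],
                                     calls[rec.parent2])
    mat = pd.DataFrame.from_dict(calls, orient="index",
                                 columns=[f"M{i:05d}" for i in range(n_markers)])
    mat = mat.loc[pedigree["id"].tolist()]
    if missing_rate > 0:
        mask = rng.random(mat.shape) < missing_rate
        mat = mat.mask(mask)
    return mat


# ---------------------------------------------------------------------------
# trial network
# ---------------------------------------------------------------------------

def simulate_trial_network(config: SimulationConfig) -> pd.DataFrame:
    """Simulate the unbalanced year x location x genotype trial design.

    Each year holds a number of single-location trials drawn uniformly in
    ``trials_per_year_range``.  Each genotype is tested during a contiguous
    window of years (entry year uniform, window length geometric with the
    configured mean), reproducing the entry/exit turnover of a variety
    testing series; within its window a genotype appears in every trial.

    Returns one row per observation slot with columns ``environment, year,
    location, genotype``.
    """
    if config.n_years < 2:
        raise ValueError("n_years must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 37]))
    years = list(config.years)
    locations = [f"LOC{i:02d}" for i in range(config.n_locations)]
    lo, hi = config.trials_per_year_range

    ped_like_ids = _genotype_ids(config)
    p_geom = min(1.0, 1.0 / config.mean_window_years)
    entry = rng.integers(0, config.n_years, size=len(ped_like_ids))
    length = rng.geometric(p_geom, size=len(ped_like_ids))
    windows = {
        g: (years[e], years[min(e + w - 1, config.n_years - 1)])
        for g, e, w in zip(ped_like_ids, entry, length)
    }
    # guarantee every year tests at least 3 genotypes (or all of them)
    active = {y: [g for g, (a, b) in windows.items() if a <= y <= b]
              for y in years}
    floor = min(3, len(ped_like_ids))
    for y in years:
        while len(active[y]) < floor:
            g = ped_like_ids[rng.integers(len(ped_like_ids))]
            a, b = windows[g]
            windows[g] = (min(a, y), max(b, y))
            active = {yy: [gg for gg, (aa, bb) in windows.items()
                           if aa <= yy <= bb] for yy in years}

    rows = []
    for y in years:
        n_trials = int(rng.integers(lo, hi + 1))
        locs = rng.choice(config.n_locations, size=n_trials, replace=False)
        for li in locs:
            loc = locations[li]
            env = f"E{y}_{loc}"
            for g in active[y]:
                rows.append((env, y, loc, g))
    return pd.DataFrame(rows, columns=["environment", "year", "location",
                                       "genotype"])


def _genotype_ids(config: SimulationConfig) -> list[str]:
    return simulate_pedigree(config)["id"].tolist()


# ---------------------------------------------------------------------------
# weather, soil
# ---------------------------------------------------------------------------

# (annual mean, seasonal amplitude, peak calendar month) per variable;
# rainfall is generated on the natural-log scale (mm/day)
_SEASONAL = {
    "temp_mean": (9.5, 6.5, 7),
    "temp_min": (5.5, 5.5, 7),
    "temp_max": (13.5, 7.5, 7),
    "rainfall": (0.92, 0.30, 1),
    "humidity": (84.0, 5.0, 1),
    "pressure": (1013.0, 2.0, 6),
    "wind_speed": (1.504, 0.22, 1),   # log m/s, winter peak
}

# (location sd, shared year sd, residual monthly sd); location contrasts
# reflect persistent regional climate gradients (several degC of mean
# temperature and a 2-4x rainfall range between the mildest and harshest
# growing regions), which is what makes enviromic similarity transfer
# across years
_NOISE = {
    "temp_mean": (1.8, 0.7, 1.0),
    "temp_min": (1.8, 0.7, 1.1),
    "temp_max": (2.0, 0.8, 1.2),
    "rainfall": (0.45, 0.15, 0.30),
    "humidity": (3.0, 1.5, 2.5),
    "pressure": (0.5, 1.0, 2.5),
    "wind_speed": (0.22, 0.09, 0.16),   # log scale
}

# anomaly loadings (thermal factor, moisture factor, variable-own noise);
# unit norm, so the _NOISE sds are preserved.  Monthly-mean temperature
# variables are nearly collinear in observations and humidity co-varies
# with moisture (+) and temperature (-); without these couplings the EC
# space has an unrealistically high effective dimensionality and the
# Gaussian kernel loses its contrast between environments.
_LOADINGS = {
    "temp_mean": (0.97, 0.0, 0.243),
    "temp_min": (0.95, 0.0, 0.312),
    "temp_max": (0.95, 0.0, 0.312),
    "rainfall": (0.0, 0.90, 0.436),
    "humidity": (-0.45, 0.60, 0.661),
    "pressure": (0.0, -0.30, 0.954),
    "wind_speed": (0.0, 0.30, 0.954),
}

#: variables generated (and shifted) on the natural-log scale; strictly
#: positive by construction
_LOG_VARS = {"rainfall", "wind_speed"}


def _seasonal_values(var: str) -> np.ndarray:
    mean, amp, peak = _SEASONAL[var]
    months = np.array([MONTH_NUMBER[m] for m in SEASON_MONTHS], float)
    return mean + amp * np.cos(2 * np.pi * (months - peak) / 12.0)


def simulate_weather_series(
    locations: Sequence[str],
    years: Sequence[int],
    members: int = 0,
    shift: ClimateShift | None = None,
    seed: int = 0,
    future_years: Sequence[int] | None = None,
    member_bias_sd: float = 0.6,
    member_var_jitter: float = 0.15,
) -> pd.DataFrame:
    """Simulate observed and ensemble-member monthly weather series.

    Monthly values follow a seasonal sinusoid plus a per-location offset,
    a year effect shared across locations (the driver of year-to-year
    environment quality) and residual monthly noise.  Rainfall is generated
    on the log scale (hence strictly positive) and humidity is clipped to
    (0, 100).

    With ``members > 0``, each ensemble member receives a member-specific
    mean bias (sd ``member_bias_sd`` in units of the year-effect sd) and a
    noise-variance inflation factor (log-normal with sd
    ``member_var_jitter``), making bias correction non-trivial; members
    cover ``years`` (baseline) and, if given, ``future_years`` with the
    configured ``shift`` applied.

    Returns a long frame with columns ``role, member, location, year,
    month, variable, value``; ``role`` is ``observed`` or
    ``raw_projection``, ``year`` indexes the growing season (harvest year).
    """
    if len(locations) < 1 or len(years) < 1:
        raise ValueError("need at least one location and one year")
    shift = shift or ClimateShift()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 53]))
    nL = len(locations)
    z_loc = {"t": rng.standard_normal(nL), "m": rng.standard_normal(nL)}
    loc_anom = {}
    for var in WEATHER_VARIABLES:
        wt, wm, wo = _LOADINGS[var]
        loc_anom[var] = _NOISE[var][0] * (
            wt * z_loc["t"] + wm * z_loc["m"]
            + wo * rng.standard_normal(nL))

    frames = [_gen_block(rng, locations, years, loc_anom, role="observed",
                         member=None, bias={}, infl={}, shift=None)]
    if members > 0:
        for m in range(members):
            bias = {var: rng.normal(0.0, member_bias_sd * _NOISE[var][1])
                    for var in WEATHER_VARIABLES}
            infl = {var: math.exp(rng.normal(0.0, member_var_jitter))
                    for var in WEATHER_VARIABLES}
            frames.append(_gen_block(rng, locations, years, loc_anom,
                                     role="raw_projection", member=m,
                                     bias=bias, infl=infl, shift=None))
            if future_years is not None:
                frames.append(_gen_block(rng, locations, future_years,
                                         loc_anom, role="raw_projection",
                                         member=m, bias=bias, infl=infl,
                                         shift=shift))
    return pd.concat(frames, ignore_index=True)


def _gen_block(rng, locations, years, loc_anom, role, member, bias, infl,
               shift) -> pd.DataFrame:
    nL, nY, nM = len(locations), len(years), len(SEASON_MONTHS)
    z_yr = {"t": rng.standard_normal(nY), "m": rng.standard_normal(nY)}
    z_mo = {"t": rng.standard_normal((nL, nY, nM)),
            "m": rng.standard_normal((nL, nY, nM))}
    out = {}
    for var in WEATHER_VARIABLES:
        _, sd_year, sd_month = _NOISE[var]
        wt, wm, wo = _LOADINGS[var]
        year_eff = sd_year * (wt * z_yr["t"] + wm * z_yr["m"]
                              + wo * rng.standard_normal(nY))
        noise = sd_month * (wt * z_mo["t"] + wm * z_mo["m"]
                            + wo * rng.standard_normal((nL, nY, nM)))
        anom = year_eff[None, :, None] + noise
        f = infl.get(var, 1.0)
        if shift is not None:
            f = f * shift.scale(var)
        base = _seasonal_values(var)[None, None, :]
        vals = base + loc_anom[var][:, None, None] + f * anom
        vals = vals + bias.get(var, 0.0)
        if shift is not None:
            vals = vals + shift.mean(var)
        if var in _LOG_VARS:
            vals = np.exp(vals)
        elif var == "humidity":
            vals = np.clip(vals, 0.5, 99.5)
        out[var] = vals
    idx = pd.MultiIndex.from_product(
        [locations, list(years), list(SEASON_MONTHS)],
        names=["location", "year", "month"])
    frame = pd.DataFrame(
        {var: out[var].reshape(-1) for var in WEATHER_VARIABLES}, index=idx)
    long = frame.reset_index().melt(
        id_vars=["location", "year", "month"],
        var_name="variable", value_name="value")
    long.insert(0, "role", role)
    long.insert(1, "member", np.nan if member is None else member)
    return long


def simulate_soil(locations: Sequence[str], seed: int = 0) -> pd.DataFrame:
    """Draw static soil properties per location.

    Texture fractions (sand/clay/silt, %) come from a Dirichlet on the
    simplex; soil organic carbon (dg/kg), nitrogen (cg/kg) and cation
    exchange capacity (mmol_c/kg) are log-normal; pH is normal.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 71]))
    texture = rng.dirichlet([4.0, 2.0, 3.0], size=len(locations)) * 100.0
    frame = pd.DataFrame({
        "sand": texture[:, 0],
        "clay": texture[:, 1],
        "silt": texture[:, 2],
        "soc": np.exp(rng.normal(np.log(250.0), 0.4, len(locations))),
        "nitrogen": np.exp(rng.normal(np.log(150.0), 0.35, len(locations))),
        "ph": rng.normal(6.5, 0.6, len(locations)),
        "cec": np.exp(rng.normal(np.log(180.0), 0.3, len(locations))),
    }, index=pd.Index(locations, name="location"))
    return frame[list(SOIL_VARIABLES)]


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _chol_psd(K: np.ndarray, jitter: float = 1e-8) -> np.ndarray:
    try:
        return np.linalg.cholesky(K + jitter * np.eye(len(K)))
    except np.linalg.LinAlgError as exc:
        raise ValueError("kernel is not positive semi-definite "
                         f"(jitter {jitter})") from exc


def simulate_phenotypes(
    design: pd.DataFrame,
    H: pd.DataFrame,
    Omega: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, dict]:
    """Draw phenotypes under the full reaction-norm component model.

    For each observation (genotype i in environment e):
    ``y = mu + E_e + g_i + gE_ie + gW_ie + eps`` with
    ``E ~ iid N(0, s2_E)`` per environment, ``g ~ MVN(0, s2_g H)``,
    ``gE`` independent MVN(0, s2_gE H) draws per environment,
    ``gW ~ MVN(0, s2_gW H (x) Omega)`` (matrix normal over genotype x
    environment) and iid residual noise.  Component variances are the
    configured fractions of the squared trait sd, divided by the mean
    kernel diagonal so realised variances hit the fractions.

    Returns the long phenotype table and a ``truth`` dict holding the
    fractions, component variances and realised per-observation components.
    """
    fr = dict(config.variance_fractions)
    fr.setdefault("W", 0.0)
    if abs(sum(fr.values()) - 1.0) > 1e-8:
        raise ValueError("variance fractions must sum to 1")
    genos = design["genotype"].unique().tolist()
    envs = design["environment"].unique().tolist()
    if not set(genos) <= set(H.index):
        raise ValueError("H does not cover all design genotypes")
    if not set(envs) <= set(Omega.index):
        raise ValueError("Omega does not cover all design environments")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 97]))
    mu, sd = config.trait_scale
    vp = sd * sd

    Hm = H.loc[genos, genos].to_numpy()
    Om = Omega.loc[envs, envs].to_numpy()
    Lh = _chol_psd(Hm)
    Lw = _chol_psd(Om)
    nG, nE = len(genos), len(envs)

    s2 = {
        "E": fr["E"] * vp,
        "W": fr["W"] * vp,
        "g": fr["g"] * vp / max(np.mean(np.diag(Hm)), 1e-12),
        "gE": fr["gE"] * vp / max(np.mean(np.diag(Hm)), 1e-12),
        "gW": fr["gW"] * vp / max(np.mean(np.diag(Hm)) * np.mean(np.diag(Om)),
                                  1e-12),
        "eps": fr["eps"] * vp,
    }

    E_env = rng.normal(0.0, math.sqrt(s2["E"]), size=nE)
    W_env = math.sqrt(s2["W"]) * (Lw @ rng.standard_normal(nE))
    g = math.sqrt(s2["g"]) * (Lh @ rng.standard_normal(nG))
    gE = math.sqrt(s2["gE"]) * (Lh @ rng.standard_normal((nG, nE)))
    gW = math.sqrt(s2["gW"]) * (Lh @ rng.standard_normal((nG, nE)) @ Lw.T)

    gi = design["genotype"].map({g_: i for i, g_ in enumerate(genos)}).to_numpy()
    ei = design["environment"].map({e: i for i, e in enumerate(envs)}).to_numpy()
    comp = pd.DataFrame({
        "E": E_env[ei],
        "W": W_env[ei],
        "g": g[gi],
        "gE": gE[gi, ei],
        "gW": gW[gi, ei],
        "eps": rng.normal(0.0, math.sqrt(s2["eps"]), size=len(design)),
    }, index=design.index)
    value = mu + comp.sum(axis=1)

    pheno = design.copy()
    pheno["trait"] = config.trait
    pheno["value"] = value
    truth = {
        "fractions": fr,
        "variances": s2,
        "mu": mu,
        "components": comp,
        "genetic_effects": pd.Series(g, index=genos),
        "E_effects": pd.Series(E_env, index=envs),
        "W_effects": pd.Series(W_env, index=envs),
        "gE_matrix": pd.DataFrame(gE, index=genos, columns=envs),
        "gW_matrix": pd.DataFrame(gW, index=genos, columns=envs),
    }
    return pheno, truth


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """A complete simulated study: genomes, trials, weather and phenotypes."""

    config: SimulationConfig
    pedigree: pd.DataFrame
    markers: pd.DataFrame
    design: pd.DataFrame            # observation slots (environment rows)
    phenotypes: pd.DataFrame        # long trait observations
    environments: pd.DataFrame      # unscaled EC matrix (env x covariate)
    env_table: pd.DataFrame         # environment -> (year, location)
    soil: pd.DataFrame
    climate: pd.DataFrame           # long weather incl. ensemble members
    A: pd.DataFrame
    H: pd.DataFrame
    Omega: pd.DataFrame
    omega_theta: float
    truth: dict = field(default_factory=dict)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run the full generator: pedigree -> markers -> trials -> weather ->
    relationship matrices -> enviromic kernel -> phenotypes."""
    from . import envirotyping, relatedness

    pedigree = simulate_pedigree(config)
    markers = simulate_marker_matrix(
        pedigree, config.n_markers, config.founder_maf_range, config.seed)
    design = simulate_trial_network(config)

    env_table = (design[["environment", "year", "location"]]
                 .drop_duplicates().reset_index(drop=True))
    locations = sorted(env_table["location"].unique())
    climate = simulate_weather_series(
        locations, list(config.years), members=config.ensemble_members,
        shift=config.climate_shift, seed=config.seed,
        future_years=list(config.future_years),
        member_bias_sd=config.member_bias_sd,
        member_var_jitter=config.member_var_jitter)
    soil = simulate_soil(locations, config.seed)

    observed = climate[climate["role"] == "observed"]
    ec = envirotyping.assemble_ec_matrix(observed, soil, env_table)
    ec_scaled = envirotyping.standardize_ecs(ec)
    kernel = envirotyping.gaussian_kernel(ec_scaled)

    A = relatedness.compute_pedigree_kinship(pedigree)
    qc = relatedness.filter_markers(markers)
    if qc.isna().any().any():
        qc = relatedness.impute_markers(qc, seed=config.seed)
    qc = relatedness.prune_markers(qc)
    G = relatedness.compute_genomic_kinship(qc)
    Gs = relatedness.scale_g_to_a(G, A)
    H = relatedness.combine_h(A, Gs)

    pheno, truth = simulate_phenotypes(design, H, kernel.matrix, config)
    truth["fractions_config"] = dict(config.variance_fractions)
    return SyntheticDataset(
        config=config, pedigree=pedigree, markers=markers, design=design,
        phenotypes=pheno, environments=ec, env_table=env_table, soil=soil,
        climate=climate, A=A, H=H, Omega=kernel.matrix,
        omega_theta=kernel.theta, truth=truth)
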