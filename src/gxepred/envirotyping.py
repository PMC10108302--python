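"""Environmental covariate assembly and the enviromic relationship matrix.

Each trial environment (a year x location combination) is characterised by
7 monthly weather variables over the October-August growing season plus 7
static soil properties, giving an environments x covariates (EC) matrix.
Environmental similarity is a Gaussian kernel on the scaled EC rows:

    Omega = exp(-h * D / theta)

where D holds squared Euclidean distances between environment rows, theta
is the mean of the full distance matrix (including its zero diagonal) and
h is a bandwidth, 1 by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .config import SEASON_MONTHS, SOIL_VARIABLES, WEATHER_VARIABLES

__all__ = ["EnviromicKernel", "assemble_ec_matrix", "standardize_ecs",
           "gaussian_kernel", "ec_columns"]


def ec_columns() -> list[str]:
    """Canonical EC column order: 7 weather vars x 11 months, then soil."""
    cols = [f"{var}_{month}" for var in WEATHER_VARIABLES
            for month in SEASON_MONTHS]
    return cols + list(SOIL_VARIABLES)


def assemble_ec_matrix(
    weather: pd.DataFrame,
    soil: pd.DataFrame,
    env_table: pd.DataFrame,
) -> pd.DataFrame:
    """Build the environment x covariate matrix.

    Parameters
    ----------
    weather
        Long monthly series with columns ``location, year, month,
        variable, value`` (one value per cell); season-year indexed.
    soil
        Location-indexed frame of soil properties (constant over years).
    env_table
        Mapping of ``environment`` labels to ``year`` and ``location``.

    Returns one row per environment with columns ``<variable>_<month>``
    followed by the soil columns, in a deterministic order.  Raises if any
    environment misses a weather cell or a soil row.
    """
    if env_table["environment"].duplicated().any():
        dup = env_table.loc[env_table["environment"].duplicated(),
                            "environment"].iloc[0]
        raise ValueError(f"duplicate environment label {dup!r}")
    wide = weather.pivot_table(index=["location", "year"],
                               columns=["variable", "month"],
                               values="value", aggfunc="mean")
    rows = []
    for rec in env_table.itertuples(index=False):
        key = (rec.location, rec.year)
        if key not in wide.index:
            raise ValueError(
                f"no weather for environment {rec.environment!r} "
                f"(location {rec.location!r}, year {rec.year})")
        cells = wide.loc[key]
        row = {}
        for var in WEATHER_VARIABLES:
            for month in SEASON_MONTHS:
                if (var, month) not in cells.index or pd.isna(cells[(var, month)]):
                    raise ValueError(
                        f"environment {rec.environment!r} missing "
                        f"{var}_{month}")
                row[f"{var}_{month}"] = cells[(var, month)]
        if rec.location not in soil.index:
            raise ValueError(f"no soil data for location {rec.location!r}")
        for svar in SOIL_VARIABLES:
            row[svar] = soil.loc[rec.location, svar]
        rows.append(row)
    out = pd.DataFrame(rows, index=pd.Index(env_table["environment"],
                                            name="environment"))
    out = out[ec_columns()]
    out.attrs["scaled"] = False
    return out


def standardize_ecs(table: pd.DataFrame) -> pd.DataFrame:
    """Centre and scale each EC column to mean 0, sample sd 1.

    Zero-variance columns are dropped with a warning; applying the
    function twice is the identity on the surviving columns.
    """
    sd = table.std(axis=0, ddof=1)
    constant = sd[(sd == 0) | sd.isna()].index
    if len(constant) == len(table.columns):
        raise ValueError("all EC columns are constant")
    if len(constant):
        warnings.warn(f"dropping {len(constant)} zero-variance EC column(s): "
                      f"{list(constant)[:5]}...", stacklevel=2)
    kept = table.drop(columns=list(constant))
    out = (kept - kept.mean(axis=0)) / kept.std(axis=0, ddof=1)
    out.attrs["scaled"] = True
    return out


@dataclass
class EnviromicKernel:
    """Gaussian-kernel similarity among environments (unit diagonal)."""

    matrix: pd.DataFrame
    theta: float
    h: float = 1.0

    @property
    def environments(self) -> list[str]:
        return list(self.matrix.index)


def gaussian_kernel(table: pd.DataFrame, h: float = 1.0) -> EnviromicKernel:
    """Enviromic relationship matrix from a scaled EC table.

    theta is the mean of all q^2 entries of the squared-distance matrix
    (the zero diagonal included); environments with identical EC rows get
    similarity exactly 1.  Raises when all environments are identical
    (theta = 0).
    """
    if len(table) < 2:
        raise ValueError("need at least two environments")
    X = table.to_numpy(dtype=float)
    D = squareform(pdist(X, metric="sqeuclidean"))
    theta = float(D.mean())
    if theta == 0.0:
        raise ValueError("all environments identical; kernel undefined")
    Omega = np.exp(-h * D / theta)
    np.fill_diagonal(Omega, 1.0)
    out = pd.DataFrame(Omega, index=table.index.copy(),
                       columns=table.index.copy())
    out.attrs["kind"] = "Omega"
    return EnviromicKernel(matrix=out, theta=theta, h=h)
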