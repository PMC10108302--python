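"""Finlay-Wilkinson joint regression, quality-risk scoring and stability
correlations over projected year environments.

Joint regression regresses each genotype's predicted values on the mean
of all genotypes per environment (the environmental index); the slope b
measures sensitivity to environmental variation (b = 1 average, b < 1
stable).  The risk index is the percentage of projected year environments
in which a genotype misses the UK bread-wheat quality criteria.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = ["QUALITY_CRITERIA", "StabilityRecord", "finlay_wilkinson",
           "risk_index", "stability_cross_correlations", "meets_criteria"]

#: milling-quality rules per trait: ("min", x) passes when value > x,
#: ("max", x) when value < x, ("range", lo, hi) when lo <= value <= hi
QUALITY_CRITERIA: dict[str, tuple] = {
    "protein": ("range", 11.0, 13.0),
    "hfn": ("min", 250.0),
    "specific_weight": ("min", 76.0),
    "chopin_w": ("min", 170.0),
    "chopin_pl": ("max", 0.9),
    "zeleny": ("min", 30.0),
}


@dataclass
class StabilityRecord:
    genotype: str
    location: str
    trait: str
    intercept: float
    slope_b: float
    mean_value: float
    risk_pct: float | None = None


def _as_matrix(predictions: pd.DataFrame) -> pd.DataFrame:
    """Accept a genotype x environment matrix or a long prediction frame."""
    if {"genotype", "environment", "predicted"} <= set(predictions.columns):
        mat = predictions.pivot(index="genotype", columns="environment",
                                values="predicted")
    else:
        mat = predictions
    if mat.isna().any().any():
        raise ValueError("joint regression needs a completely balanced "
                         "genotype x environment matrix (no missing cells)")
    return mat


def finlay_wilkinson(predictions: pd.DataFrame, trait: str = "trait",
                     location: str = "all") -> pd.DataFrame:
    """Per-genotype joint regression against the environment-mean index.

    Returns one row per genotype with ``intercept``, ``slope_b`` and
    ``mean_value``.  On any balanced matrix the slopes average exactly to
    one (the index is the genotype-mean of the responses), so intercepts
    average to zero.
    """
    mat = _as_matrix(predictions)
    if mat.shape[1] < 3:
        raise ValueError("need >= 3 environments")
    index = mat.mean(axis=0).to_numpy()
    x = index - index.mean()
    varx = float(x @ x)
    if varx == 0:
        raise ValueError("environment index is constant")
    Y = mat.to_numpy()
    slopes = (Y - Y.mean(axis=1, keepdims=True)) @ x / varx
    means = Y.mean(axis=1)
    intercepts = means - slopes * index.mean()
    return pd.DataFrame({
        "genotype": mat.index, "location": location, "trait": trait,
        "intercept": intercepts, "slope_b": slopes, "mean_value": means,
    }).reset_index(drop=True)


def meets_criteria(values: np.ndarray, trait: str) -> np.ndarray:
    """Boolean pass/fail of the quality rule, with strict one-sided
    comparisons as printed in the criteria (e.g. HFN *over* 250 s)."""
    if trait not in QUALITY_CRITERIA:
        raise ValueError(f"no quality criteria for trait {trait!r}")
    rule = QUALITY_CRITERIA[trait]
    values = np.asarray(values, dtype=float)
    if rule[0] == "min":
        return values > rule[1]
    if rule[0] == "max":
        return values < rule[1]
    return (values >= rule[1]) & (values <= rule[2])


def risk_index(predictions: pd.DataFrame, trait: str) -> pd.Series:
    """Percentage of environments in which each genotype fails the trait's
    quality criterion."""
    mat = _as_matrix(predictions)
    ok = meets_criteria(mat.to_numpy(), trait)
    risk = 100.0 * (1.0 - ok.mean(axis=1))
    return pd.Series(risk, index=mat.index, name="risk_pct")


def stability_cross_correlations(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Correlate stability slopes across traits and locations.

    ``records`` stacks joint-regression outputs (columns genotype,
    location, trait, slope_b, mean_value).  Returns Pearson correlations
    of b between trait pairs within location (``trait_pairs``), between
    location pairs within trait (``location_pairs``), and the mean-vs-b
    association per trait x location (``mean_vs_b``).
    """
    out_tp, out_lp, out_mb = [], [], []
    for loc, grp in records.groupby("location"):
        wide = grp.pivot(index="genotype", columns="trait", values="slope_b")
        for t1, t2 in combinations(sorted(wide.columns), 2):
            pair = wide[[t1, t2]].dropna()
            if len(pair) < 3:
                raise ValueError(
                    f"fewer than 3 shared genotypes for {t1}/{t2} at {loc}")
            out_tp.append({"location": loc, "trait_a": t1, "trait_b": t2,
                           "r": float(np.corrcoef(pair[t1], pair[t2])[0, 1]),
                           "n": len(pair)})
    for trait, grp in records.groupby("trait"):
        wide = grp.pivot(index="genotype", columns="location",
                         values="slope_b")
        for l1, l2 in combinations(sorted(wide.columns), 2):
            pair = wide[[l1, l2]].dropna()
            if len(pair) < 3:
                raise ValueError(
                    f"fewer than 3 shared genotypes for {trait} at {l1}/{l2}")
            out_lp.append({"trait": trait, "location_a": l1,
                           "location_b": l2,
                           "r": float(np.corrcoef(pair[l1], pair[l2])[0, 1]),
                           "n": len(pair)})
    for (trait, loc), grp in records.groupby(["trait", "location"]):
        if len(grp) < 3:
            raise ValueError(
                f"fewer than 3 genotypes for {trait} at {loc}")
        out_mb.append({"trait": trait, "location": loc,
                       "r": float(np.corrcoef(grp["mean_value"],
                                              grp["slope_b"])[0, 1]),
                       "n": len(grp)})
    return {"trait_pairs": pd.DataFrame(out_tp),
            "location_pairs": pd.DataFrame(out_lp),
            "mean_vs_b": pd.DataFrame(out_mb)}
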