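"""Leave-one-year-out cross-validation and model comparison.

The CV scheme mimics the breeder's hardest realistic task: predicting
untested genotypes in untested years.  Each year is held out in turn; any
genotype occurring in the held-out year is also removed from the training
fold, so test genotypes are connected to training data only through the
relationship matrix.  Accuracy is summarised two ways: the correlation of
year-mean observed vs predicted values across years (how well overall
seasonal effects are anticipated), and the within-trial correlation across
genotypes (genomic accuracy), compared between models by paired t-tests
over trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .kernels import ModelDesign, build_kernels
from .models import FittedKernelModel, McmcSettings, fit_model, predict

__all__ = ["CVResult", "leave_one_year_out_cv", "year_mean_accuracy",
           "trial_accuracy", "compare_models"]

logger = logging.getLogger(__name__)


@dataclass
class CVResult:
    """Out-of-fold predictions and the fold manifest for one model type."""

    model_type: str
    predictions: pd.DataFrame      # genotype, environment, year, value, predicted
    folds: dict[int, dict] = field(default_factory=dict)
    models: dict[int, FittedKernelModel] = field(default_factory=dict)


def leave_one_year_out_cv(
    phenotypes: pd.DataFrame,
    H: pd.DataFrame,
    Omega: pd.DataFrame | None,
    model_type: str = "RNMM",
    mcmc: McmcSettings | None = None,
    keep_models: bool = False,
) -> CVResult:
    """Run leave-one-year-out CV for untested genotypes in untested years.

    ``phenotypes`` is the long table (genotype, environment, year, value);
    ``Omega`` must cover all environments for reaction-norm models.  Per
    fold, the held-out year's observations form the test set, training
    drops that year and every genotype present in it, the model is
    refitted and test rows predicted.
    """
    if hasattr(Omega, "matrix"):
        Omega = Omega.matrix
    years = sorted(phenotypes["year"].unique())
    if len(years) < 3:
        raise ValueError("need >= 3 distinct years for leave-one-year-out CV")
    mcmc = mcmc or McmcSettings()
    preds = []
    folds: dict[int, dict] = {}
    models: dict[int, FittedKernelModel] = {}
    for k, year in enumerate(years):
        test = phenotypes[phenotypes["year"] == year]
        test_genos = set(test["genotype"])
        train = phenotypes[(phenotypes["year"] != year)
                           & ~phenotypes["genotype"].isin(test_genos)]
        if len(train) == 0:
            raise ValueError(f"empty training fold for year {year}")
        design_tr = ModelDesign.from_frame(train)
        kernels = build_kernels(design_tr, H, Omega)
        fold_mcmc = McmcSettings(iterations=mcmc.iterations,
                                 burn_in=mcmc.burn_in, thin=mcmc.thin,
                                 seed=mcmc.seed + k)
        model = fit_model(train["value"].to_numpy(), kernels, model_type,
                          fold_mcmc)
        design_te = ModelDesign.from_frame(test)
        out = predict(model, design_te, H, Omega)
        out["year"] = year
        out["value"] = test["value"].to_numpy()
        preds.append(out)
        folds[year] = {
            "train_genotypes": sorted(set(train["genotype"])),
            "test_genotypes": sorted(test_genos),
            "n_train": len(train), "n_test": len(test),
        }
        if keep_models:
            models[year] = model
    return CVResult(model_type=model_type,
                    predictions=pd.concat(preds, ignore_index=True),
                    folds=folds, models=models)


def year_mean_accuracy(cv: CVResult) -> float:
    """Correlation across years of year-mean observed vs predicted values.

    Year means pool all trials and genotypes of the year (observations
    weighted equally)."""
    by_year = cv.predictions.groupby("year")[["value", "predicted"]].mean()
    if len(by_year) < 3:
        raise ValueError("need >= 3 years for a stable correlation")
    return float(np.corrcoef(by_year["value"], by_year["predicted"])[0, 1])


def trial_accuracy(cv: CVResult, min_genotypes: int = 3) -> pd.DataFrame:
    """Within-trial correlation of observed vs predicted across genotypes.

    Trials with fewer than ``min_genotypes`` test genotypes, or constant
    observed values, are skipped with a log message.  Returns one row per
    usable trial (environment, year, n, r).
    """
    rows = []
    for env, grp in cv.predictions.groupby("environment"):
        if len(grp) < min_genotypes:
            logger.info("skipping trial %s: only %d test genotypes",
                        env, len(grp))
            continue
        if np.std(grp["value"]) == 0 or np.std(grp["predicted"]) == 0:
            logger.info("skipping trial %s: constant values", env)
            continue
        r = float(np.corrcoef(grp["value"], grp["predicted"])[0, 1])
        rows.append({"environment": env, "year": grp["year"].iloc[0],
                     "model_type": cv.model_type, "n": len(grp), "r": r})
    return pd.DataFrame(rows)


def compare_models(acc_a: pd.Series | np.ndarray,
                   acc_b: pd.Series | np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test on per-trial accuracy vectors.

    The vectors must be paired by trial (same trial set, same order).
    Returns (t statistic, p value).
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("accuracy vectors must be paired (equal length)")
    if len(a) < 3:
        raise ValueError("need >= 3 paired trials")
    if np.allclose(a, b):
        raise ValueError("all paired differences are zero; t-test undefined")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
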