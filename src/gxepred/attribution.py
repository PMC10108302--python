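"""Weather-covariate importance and effect direction on projected traits.

A random-forest regression of environment-mean predicted trait values on
the environmental covariates quantifies each covariate's relative
importance (mean decrease in node MSE, max-scaled per trait x location);
signed Pearson correlations give the direction of effect.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

__all__ = ["random_forest_importance", "ec_correlations", "attribute"]


def random_forest_importance(env_means: pd.Series, ecs: pd.DataFrame,
                             seed: int = 0, n_trees: int = 500,
                             min_obs: int = 30) -> pd.Series:
    """Random-forest importance of each EC for the environment-mean trait.

    Forest settings follow the classical regression defaults: a third of
    the features tried at each split, minimum terminal node size five,
    500 trees.  Importances are the impurity decrease (mean decrease in
    MSE) scaled so the top covariate scores 1.
    """
    X = ecs.loc[env_means.index]
    if len(env_means) < min_obs:
        raise ValueError(f"need >= {min_obs} environments")
    y = env_means.to_numpy(dtype=float)
    if np.std(y) == 0:
        raise ValueError("constant target; importances undefined")
    mtry = max(1, math.ceil(X.shape[1] / 3))
    forest = RandomForestRegressor(
        n_estimators=n_trees, max_features=mtry, min_samples_leaf=5,
        random_state=seed, n_jobs=1)
    forest.fit(X.to_numpy(), y)
    imp = forest.feature_importances_
    return pd.Series(imp / imp.max(), index=X.columns, name="importance")


def ec_correlations(env_means: pd.Series, ecs: pd.DataFrame) -> pd.Series:
    """Signed Pearson correlation of each EC with the environment means."""
    X = ecs.loc[env_means.index]
    if len(env_means) < 3:
        raise ValueError("need >= 3 environments")
    y = env_means.to_numpy(dtype=float)
    out = {}
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        if np.std(x) == 0:
            warnings.warn(f"EC {col!r} has zero variance; correlation "
                          "undefined", stacklevel=2)
            out[col] = np.nan
        else:
            out[col] = float(np.corrcoef(x, y)[0, 1])
    return pd.Series(out, name="correlation")


def attribute(predictions: pd.DataFrame, ecs: pd.DataFrame,
              env_table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Per trait x location attribution table (importance + correlation).

    ``predictions`` is a long projection result (genotype, environment,
    trait, predicted); targets are environment means across genotypes,
    one forest per trait x location.
    """
    loc = env_table.set_index("environment")["location"]
    rows = []
    for (trait, location), grp in predictions.assign(
            location=predictions["environment"].map(loc)) \
            .groupby(["trait", "location"]):
        means = grp.groupby("environment")["predicted"].mean()
        imp = random_forest_importance(means, ecs, seed=seed)
        corr = ec_correlations(means, ecs)
        for cov in imp.index:
            rows.append({"trait": trait, "location": location,
                         "covariate": cov, "importance": imp[cov],
                         "correlation": corr[cov]})
    return pd.DataFrame(rows)
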