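"""Leave-one-year-out cross-validation of untested genotypes in untested
years: does adding environmental covariates improve prediction?

Each year is held out in turn and its genotypes are also removed from
training.  Reports year-mean accuracy (how well overall seasonal effects
are anticipated) and within-trial genomic accuracy for MM vs RNMM and
MDs vs RNMDs, with paired t-tests over trials.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import MCMC, RESULTS, STUDY  # noqa: E402

from gxepred import (compare_models, leave_one_year_out_cv,  # noqa: E402
                     simulate_dataset, trial_accuracy, year_mean_accuracy)


def main() -> None:
    ds = simulate_dataset(STUDY)
    acc_tables = {}
    summary = []
    for model_type in ("MM", "MDs", "RNMM", "RNMDs"):
        cv = leave_one_year_out_cv(ds.phenotypes, ds.H, ds.Omega,
                                   model_type, MCMC)
        acc = trial_accuracy(cv)
        acc_tables[model_type] = acc.set_index("environment")["r"]
        summary.append({
            "model": model_type,
            "year_mean_r": year_mean_accuracy(cv),
            "trial_mean_r": acc["r"].mean(),
            "trial_median_r": acc["r"].median(),
            "n_trials": len(acc),
        })
    table = pd.DataFrame(summary).set_index("model").round(3)
    table.to_csv(RESULTS / "cv_summary.csv")
    print(table.to_string())

    for a, b in (("MM", "RNMM"), ("MDs", "RNMDs")):
        paired = pd.concat([acc_tables[a], acc_tables[b]], axis=1,
                           keys=[a, b]).dropna()
        t, p = compare_models(paired[a], paired[b])
        print(f"paired t-test {a} vs {b} over {len(paired)} trials: "
              f"t = {t:.2f}, p = {p:.3g}")


if __name__ == "__main__":
    main()
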