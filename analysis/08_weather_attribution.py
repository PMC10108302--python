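"""Which weather covariates drive the projected year-to-year variation in
trait values?

For each location, a random-forest regression predicts the environment-
mean trait value in each projected year environment from its covariates;
relative importance (mean decrease in MSE, max-scaled) ranks the
covariates and signed Pearson correlations give effect direction.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import MCMC, PROJECTION_LOCATIONS, RESULTS, STUDY  # noqa: E402

from gxepred import (ModelDesign, attribute, build_kernels,  # noqa: E402
                     fit_model, simulate_dataset)
from gxepred.climate import (bias_correct_series,  # noqa: E402
                             build_projection_environments, project_traits)


def main() -> None:
    ds = simulate_dataset(STUDY)
    obs = ds.climate[ds.climate.role == "observed"]
    raw = ds.climate[ds.climate.role == "raw_projection"]
    corrected = bias_correct_series(raw, obs, STUDY.years,
                                    STUDY.future_years)
    locs = sorted(ds.soil.index)[:PROJECTION_LOCATIONS]
    envs = build_projection_environments(locs, obs, corrected, ds.soil,
                                         "year_samples", STUDY.years,
                                         STUDY.future_years)
    kernels = build_kernels(ModelDesign.from_frame(ds.phenotypes), ds.H,
                            ds.Omega)
    model = fit_model(ds.phenotypes["value"].to_numpy(), kernels, "RNMM",
                      MCMC)
    proj = project_traits(model, envs, list(ds.H.index), ds.H,
                          ds.environments, trait=STUDY.trait)

    result = attribute(proj, envs.ec, envs.env_table, seed=STUDY.seed)
    result.round(4).to_csv(RESULTS / "attribution.csv", index=False)

    for loc, grp in result.groupby("location"):
        top = grp.nlargest(5, "importance")
        print(f"\n{loc}: top covariates for {STUDY.trait}")
        for rec in top.itertuples(index=False):
            print(f"  {rec.covariate:24s} importance {rec.importance:.2f} "
                  f"correlation {rec.correlation:+.2f}")


if __name__ == "__main__":
    main()
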