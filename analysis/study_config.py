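"""Shared study configuration for the numbered analysis scripts.

One synthetic multi-environment trial study: 120 inbred wheat lines bred
from 12 founders, tested over 10 harvest years in an unbalanced network of
5-6 trials per year across 10 locations, with a 6-member climate ensemble
projecting 10 future seasons.  Phenotypes are Hagberg falling number
(seconds) generated under the full reaction-norm model; a fifth of the
phenotypic variance is predictable environmental signal (W) and 15% is
predictable G x E (gW).

Scripts re-simulate deterministically from this config instead of parsing
each other's CSV output; every script writes its tables under results/.
"""

from pathlib import Path

from gxepred import McmcSettings, SimulationConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"

STUDY = SimulationConfig(
    seed=2023,
    n_founders=12,
    n_generations=4,
    n_genotypes=120,
    n_markers=1500,
    n_years=10,
    trials_per_year_range=(5, 6),
    n_locations=10,
    mean_window_years=4.0,
    variance_fractions={"E": 0.12, "W": 0.23, "g": 0.25, "gE": 0.10,
                        "gW": 0.15, "eps": 0.15},
    trait="hfn",
    ensemble_members=6,
    projection_years=10,
)

MCMC = McmcSettings(iterations=2000, burn_in=500, thin=2, seed=2023)

PROJECTION_LOCATIONS = 3      # contrasting regions for year-sample study
GRID_CELLS = 150              # reduced national grid for the map stage
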