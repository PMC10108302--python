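"""Configuration objects for the synthetic trial-network simulator.

The simulator emulates a two-decade UK winter-wheat variety-testing network:
an unbalanced set of trials (year x location), inbred-line pedigrees with
marker data, monthly weather and static soil covariates per trial
environment, a perturbed climate-model ensemble, and quality-trait
phenotypes generated under the full reaction-norm variance-component model
(environment + genetic + GxE deviation + enviromic reaction norm + noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

#: weather covariates recorded for every trial environment (monthly means)
WEATHER_VARIABLES = (
    "rainfall",      # mm/day, monthly mean of daily totals
    "temp_mean",     # degC
    "temp_min",      # degC
    "temp_max",      # degC
    "humidity",      # % relative humidity
    "pressure",      # hPa at sea level
    "wind_speed",    # m/s at 10 m
)

#: static soil properties, constant per location
SOIL_VARIABLES = ("sand", "clay", "silt", "soc", "nitrogen", "ph", "cec")

#: growing-season months for UK winter wheat, sowing (Oct) to harvest (Aug).
#: The season is indexed by harvest year; Oct-Dec values belong to the
#: preceding autumn of the same season.
SEASON_MONTHS = ("Oct", "Nov", "Dec", "Jan", "Feb", "Mar",
                 "Apr", "May", "Jun", "Jul", "Aug")

#: calendar month numbers, used for the seasonal cycle phase
MONTH_NUMBER = {"Jan": 1, "Feb": 2, "Mar": 3, "Apr": 4, "May": 5, "Jun": 6,
                "Jul": 7, "Aug": 8, "Sep": 9, "Oct": 10, "Nov": 11, "Dec": 12}

#: trait intercepts/scales: midpoints of the milling-quality criteria with
#: field-realistic dispersions (trait units)
TRAIT_PRESETS = {
    "protein": (12.0, 1.0),          # %, criterion window 11-13
    "hfn": (280.0, 45.0),            # s, criterion > 250
    "specific_weight": (77.5, 2.5),  # kg/hl, criterion > 76
    "zeleny": (38.0, 9.0),           # ml, criterion > 30
    "chopin_w": (220.0, 50.0),       # 1e-4 J, criterion > 170
    "chopin_pl": (0.7, 0.2),         # ratio, criterion < 0.9
}


@dataclass(frozen=True)
class ClimateShift:
    """Additive mean change and noise-variance multiplier per weather variable.

    ``mean_shift`` is applied to future-period ensemble values in the
    variable's generative space (log scale for rainfall and wind speed);
    ``var_scale`` multiplies the interannual + monthly noise standard
    deviation.
    """

    mean_shift: Mapping[str, float] = field(default_factory=lambda: {
        "temp_mean": 2.0, "temp_min": 2.0, "temp_max": 2.2,
        "rainfall": -0.10, "humidity": -2.0, "pressure": 0.5,
        "wind_speed": 0.0,
    })
    var_scale: Mapping[str, float] = field(default_factory=lambda: {
        "temp_mean": 1.15, "temp_min": 1.15, "temp_max": 1.15,
        "rainfall": 1.10, "humidity": 1.0, "pressure": 1.0,
        "wind_speed": 1.0,
    })

    def mean(self, var: str) -> float:
        return float(self.mean_shift.get(var, 0.0))

    def scale(self, var: str) -> float:
        return float(self.var_scale.get(var, 1.0))


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth settings for one synthetic trial-network dataset.

    ``variance_fractions`` are the generative shares of phenotypic variance
    for the environment main effect (E), genetic main effect (g), GxE
    deviation (gE), enviromic reaction norm (gW) and residual (eps); they
    must be non-negative and sum to one.  An optional ``W`` key (default 0)
    adds an enviromic-predictable environment main effect drawn with the
    Gaussian-kernel covariance, emulating weather-driven year effects.
    """

    seed: int = 0
    n_founders: int = 30
    n_generations: int = 6
    n_genotypes: int = 240
    n_markers: int = 3000
    n_years: int = 20
    first_year: int = 2001
    trials_per_year_range: tuple[int, int] = (15, 29)
    n_locations: int = 35
    mean_window_years: float = 4.0
    variance_fractions: Mapping[str, float] = field(default_factory=lambda: {
        "E": 0.35, "g": 0.25, "gE": 0.10, "gW": 0.15, "eps": 0.15,
    })
    trait: str = "hfn"
    trait_mean: float | None = None
    trait_sd: float | None = None
    founder_maf_range: tuple[float, float] = (0.1, 0.45)
    ensemble_members: int = 12
    projection_years: int = 20
    future_first_year: int = 2050
    climate_shift: ClimateShift = field(default_factory=ClimateShift)
    member_bias_sd: float = 0.6
    member_var_jitter: float = 0.15

    def __post_init__(self) -> None:
        fr = dict(self.variance_fractions)
        missing = {"E", "g", "gE", "gW", "eps"} - fr.keys()
        if missing:
            raise ValueError(f"variance_fractions missing {sorted(missing)}")
        if not set(fr) <= {"E", "W", "g", "gE", "gW", "eps"}:
            raise ValueError(f"unknown variance fraction keys in {sorted(fr)}")
        if any(v < 0 for v in fr.values()):
            raise ValueError("variance_fractions must be non-negative")
        if abs(sum(fr.values()) - 1.0) > 1e-8:
            raise ValueError("variance_fractions must sum to 1")
        for name in ("n_founders", "n_genotypes", "n_markers", "n_years",
                     "n_locations", "ensemble_members", "projection_years"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_founders < 2:
            raise ValueError("n_founders must be >= 2")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        lo, hi = self.trials_per_year_range
        if not (1 <= lo <= hi <= self.n_locations):
            raise ValueError(
                "trials_per_year_range must satisfy "
                "1 <= min <= max <= n_locations")
        if self.trait not in TRAIT_PRESETS and (
                self.trait_mean is None or self.trait_sd is None):
            raise ValueError(
                f"unknown trait {self.trait!r}: give trait_mean and trait_sd")

    @property
    def trait_scale(self) -> tuple[float, float]:
        """(mean, sd) of the simulated trait in trait units."""
        mean, sd = TRAIT_PRESETS.get(self.trait, (0.0, 1.0))
        if self.trait_mean is not None:
            mean = self.trait_mean
        if self.trait_sd is not None:
            sd = self.trait_sd
        return float(mean), float(sd)

    @property
    def years(self) -> range:
        return range(self.first_year, self.first_year + self.n_years)

    @property
    def future_years(self) -> range:
        return range(self.future_first_year,
                     self.future_first_year + self.projection_years)

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)
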