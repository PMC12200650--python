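"""Configuration objects for the simulation, phenotyping and regression layers.

All calendar arithmetic in this package is in whole days with fixed
conventions: "12 months" = 365 days, "6 months" = 183 days, "5 years" =
1825 days, "10 years" = 3650 days.  Leap days are deliberately ignored so
every window is a testable constant.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import yaml

from .products import DEFAULT_FORMULARY, DEFAULT_PRODUCT_WEIGHTS, Product

DAYS_PER_YEAR = 365
SIX_MONTHS_DAYS = 183
FIVE_YEARS_DAYS = 1825
TEN_YEARS_DAYS = 3650


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class PhenotypingConstants:
    """Windows (in days relative to the index date, index = day 0) that define
    long-term opioid therapy (L-TOT) and its discontinuation.

    L-TOT: >=3 opioid issues within a 90-day span, or >=90 supply-covered
    days, within the first year of follow-up excluding the initial 30 days
    (evaluation window = days 30..364 inclusive).  Discontinuation: an
    opioid-free gap of >=180 days starting in the second year of follow-up
    (days 365..729), fully confirmable within the observable data.
    """

    washout_days: int = DAYS_PER_YEAR
    window_start: int = 30
    window_end: int = 364          # inclusive
    span_days: int = 90
    min_issues: int = 3
    min_covered_days: int = 90
    gap_days: int = 180
    disc_start: int = DAYS_PER_YEAR          # 365: gap must start in 2nd year
    disc_end: int = 2 * DAYS_PER_YEAR - 1    # 729
    horizon_extra_days: int = 550  # data usable past study_end for confirmation

    def __post_init__(self) -> None:
        for name in ("washout_days", "span_days", "min_issues",
                     "min_covered_days", "gap_days", "horizon_extra_days"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not (0 <= self.window_start < self.window_end):
            raise ConfigurationError("invalid evaluation window")
        if not (self.window_end < self.disc_start <= self.disc_end):
            raise ConfigurationError("discontinuation window must follow the "
                                     "evaluation window")

    @property
    def window_length(self) -> int:
        return self.window_end - self.window_start + 1


@dataclass
class SegmentedModelSpec:
    """Specification of one segmented count regression.

    Design coding for retained year ``y``: ``t = y - first_year``;
    ``I = 1`` iff ``y > break_year``; ``X = (y - (break_year + 1)) * I``.
    The centering of ``X`` at ``break_year + 1`` makes ``exp(beta2)`` the
    ratio of the observed to the pre-trend-projected level in the first
    post-break year.
    """

    first_year: int = 2009
    last_year: int = 2019
    break_year: int = 2014
    excluded_years: frozenset[int] = frozenset({2014})
    family: str = "negative_binomial"
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        self.excluded_years = frozenset(self.excluded_years)
        if not (self.first_year < self.break_year < self.last_year):
            raise ConfigurationError("break_year must lie strictly inside the "
                                     "year range")
        if not self.excluded_years <= set(range(self.first_year, self.last_year + 1)):
            raise ConfigurationError("excluded_years outside the year range")
        if self.family not in ("negative_binomial", "poisson"):
            raise ConfigurationError(f"unknown family {self.family!r}")
        if not 0 < self.ci_level < 1:
            raise ConfigurationError("ci_level must be in (0,1)")


def _default_annual_incidence() -> dict[int, float]:
    # Planted per-patient-year hazard of an incident opioid episode.  The
    # schedule emulates the observed UK primary-care trajectory (incidence
    # ~22% of registered patients falling to ~15% by 2019), inflated by
    # ~1.25x because patients inside an episode or its washout are not at
    # risk, which deflates realized incidence relative to the planted hazard.
    target = {2009: 21.8, 2010: 22.0, 2011: 21.9, 2012: 22.1, 2013: 21.9,
              2014: 20.7, 2015: 21.0, 2016: 20.3, 2017: 18.7, 2018: 16.9,
              2019: 14.7}
    return {y: round(1.25 * r / 100.0, 4) for y, r in target.items()}


def _default_missingness() -> dict[str, float]:
    return {
        "quantity": 0.06,
        "daily_dose_units": 0.04,
        "quantity_implausible": 0.01,
        "daily_dose_implausible": 0.005,
        "imd_quintile": 0.02,
        "ethnicity": 0.10,
        "smoking": 0.002,
        "drinking": 0.29,
    }


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic CPRD-Aurum-like generator.

    Defaults target the published cohort's magnitudes scaled down ~100x
    (~13k registered patients per year) so the full pipeline runs in
    seconds.  ``p_ltot``/``p_discontinue`` are the planted probabilities
    that an incident episode transitions to L-TOT and that an L-TOT episode
    discontinues in the following year (headline magnitudes 11.4% / 4.8%).
    """

    n_patients: int = 16000
    study_start: date = date(2009, 1, 1)
    study_end: date = date(2019, 12, 31)
    data_end: date | None = None   # default: study_end + horizon_extra_days
    annual_incidence: dict[int, float] = field(default_factory=_default_annual_incidence)
    p_ltot: float = 0.114
    p_discontinue: float = 0.048
    break_year: int = 2014
    step_multiplier: float = 1.0
    slope_multiplier: float = 1.0
    formulary: tuple[Product, ...] = DEFAULT_FORMULARY
    product_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PRODUCT_WEIGHTS))
    missingness: dict[str, float] = field(default_factory=_default_missingness)
    p_no_cncp: float = 0.03        # episode patients with no CNCP code (excluded)
    p_prior_cancer: float = 0.02   # episode patients with pre-index cancer (excluded)
    p_nmsc: float = 0.03           # episode patients with NMSC (retained)
    p_transfer: float = 0.08
    p_death: float = 0.025
    p_excluded_product_noise: float = 0.01  # patients with methadone/SL-bup issues
    refill_interval: int = 28
    seed: int = 20090101
    phenotyping: PhenotypingConstants = field(default_factory=PhenotypingConstants)

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        if self.data_end is None:
            self.data_end = self.study_end + timedelta(
                days=self.phenotyping.horizon_extra_days)
        if not (self.study_start < self.study_end <= self.data_end):
            raise ConfigurationError("need study_start < study_end <= data_end")
        if not (self.study_start.year < self.break_year < self.study_end.year):
            raise ConfigurationError("break_year must lie inside the study years")
        for name in ("p_ltot", "p_discontinue", "p_no_cncp", "p_prior_cancer",
                     "p_nmsc", "p_transfer", "p_death",
                     "p_excluded_product_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0,1]")
        for y, v in self.annual_incidence.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"annual_incidence[{y}]={v} outside [0,1]")
        for k, v in self.missingness.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"missingness[{k}]={v} outside [0,1]")
        if self.step_multiplier <= 0 or self.slope_multiplier <= 0:
            raise ConfigurationError("multipliers must be positive")
        if not self.formulary:
            raise ConfigurationError("formulary must be non-empty")

    @property
    def years(self) -> list[int]:
        return list(range(self.study_start.year, self.study_end.year + 1))

    def hazard(self, year: int) -> float:
        """Planted incident-episode hazard for a year, with post-break
        step/slope multipliers applied."""
        h = self.annual_incidence.get(year, 0.0)
        if year > self.break_year:
            h *= self.step_multiplier * self.slope_multiplier ** (
                year - self.break_year - 1)
        return min(h, 1.0)

    # -- serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("study_start", "study_end", "data_end"):
            d[key] = d[key].isoformat()
        d["formulary"] = [dataclasses.asdict(p) for p in self.formulary]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("study_start", "study_end", "data_end"):
            if key in d and isinstance(d[key], str):
                d[key] = date.fromisoformat(d[key])
        if "formulary" in d and d["formulary"] and isinstance(d["formulary"][0], dict):
            d["formulary"] = tuple(Product(**p) for p in d["formulary"])
        if "annual_incidence" in d:
            d["annual_incidence"] = {int(k): float(v)
                                     for k, v in d["annual_incidence"].items()}
        if "phenotyping" in d and isinstance(d["phenotyping"], dict):
            d["phenotyping"] = PhenotypingConstants(**d["phenotyping"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineConfig:
    """End-to-end run configuration: where tables live plus the three blocks."""

    out_dir: Path = Path("results")
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    model: SegmentedModelSpec = field(default_factory=SegmentedModelSpec)
    verbosity: int = 1

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
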