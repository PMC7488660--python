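"""Scenario configurations for the synthetic claims generator.

A :class:`ScenarioConfig` is a complete statement of the world the generator
simulates: the sociodemographic structure of a statutory-health-insurance
population aged 25+, an annual churn (fund-switching) model, and annual
hospitalization hazards for the two index conditions (myocardial infarction,
stroke).  Three presets are provided:

``default_scenario``
    Population margins matching a large German statutory fund, mild churn.
``null_scenario``
    No churn and no pre-index events — the degenerate world in which every
    lookback subpopulation equals the base population and washout removes
    nobody.  Used as an exact fixture.
``selective_churn_scenario``
    Churn decreasing with age, elevated for persons without income
    information and for a latent "precarious" subgroup that also carries
    elevated cardiovascular risk; hazards increase with age and follow a
    low > middle > high income gradient.  This preset reproduces, by design,
    the qualitative selection-bias patterns seen in single-fund claims data:
    heavy exclusion of the young under long lookbacks, rising crude rates,
    and a narrowing social gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .bins import FIVE_YEAR_BINS, AgeBinScheme

__all__ = [
    "ChurnModel",
    "HazardModel",
    "ScenarioConfig",
    "ScenarioConfigError",
    "default_scenario",
    "null_scenario",
    "selective_churn_scenario",
    "income_independent_churn_scenario",
    "QUALIFICATION_LEVELS",
    "INCOME_GROUPS",
]

QUALIFICATION_LEVELS = (
    "no_vocational_training",
    "vocational_training",
    "master_craftsman",
    "bachelor",
    "diploma_master",
    "phd",
    "unknown",
)
INCOME_GROUPS = ("low", "middle", "high", "unknown")

# income_value bounds (EUR/year) used when drawing values within a group;
# the classification cutoffs are <14,000 (low) and >29,000 (high), and the
# statutory contribution ceiling caps salaries at 76,200.
INCOME_VALUE_BOUNDS = {
    "low": (1_000.0, 13_999.0),
    "middle": (14_000.0, 29_000.0),
    "high": (29_001.0, 76_200.0),
}


class ScenarioConfigError(ValueError):
    """Invalid scenario configuration; the message names the offending field."""


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ScenarioConfigError(f"{name} must be a probability in [0, 1], got {value}")


def _check_simplex(name: str, vec, n: int) -> np.ndarray:
    arr = np.asarray(vec, dtype=float)
    if arr.shape != (n,):
        raise ScenarioConfigError(f"{name} must have {n} entries, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ScenarioConfigError(f"{name} entries must be >= 0")
    if abs(arr.sum() - 1.0) > 1e-9:
        raise ScenarioConfigError(f"{name} must sum to 1 (got {arr.sum()!r})")
    return arr


@dataclass(frozen=True)
class ChurnModel:
    """Annual per-person probability of leaving the fund.

    The probability is a logistic function of age with additive logit
    offsets: ``p = expit(intercept + age_slope * age + unknown_income_offset
    * [income unknown] + precarious_offset * [precarious])``.  A
    non-positive ``age_slope`` makes younger members churn more, the pattern
    observed in single-fund enrollment data.
    """

    intercept: float
    age_slope: float = 0.0
    unknown_income_offset: float = 0.0
    precarious_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.age_slope > 0:
            raise ScenarioConfigError("churn_model.age_slope must be <= 0")
        if self.unknown_income_offset < 0:
            raise ScenarioConfigError("churn_model.unknown_income_offset must be >= 0")
        if self.precarious_offset < 0:
            raise ScenarioConfigError("churn_model.precarious_offset must be >= 0")

    def annual_probability(
        self, age, income_unknown, precarious
    ) -> np.ndarray:
        lp = (
            self.intercept
            + self.age_slope * np.asarray(age, dtype=float)
            + self.unknown_income_offset * np.asarray(income_unknown, dtype=float)
            + self.precarious_offset * np.asarray(precarious, dtype=float)
        )
        # numerically safe logistic
        return 1.0 / (1.0 + np.exp(-np.clip(lp, -60.0, 60.0)))


@dataclass(frozen=True)
class HazardModel:
    """Annual first-event hospitalization probability for one disease.

    ``base_rates`` gives the annual probability per 5-year age bin for the
    reference stratum (male, high income, non-precarious); multipliers are
    applied multiplicatively and the product is clipped to [0, 1].
    """

    name: str
    base_rates: tuple[float, ...]
    income_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"low": 1.0, "middle": 1.0, "high": 1.0, "unknown": 1.0}
    )
    female_multiplier: float = 1.0
    precarious_multiplier: float = 1.0
    age_bins: AgeBinScheme = FIVE_YEAR_BINS

    def __post_init__(self) -> None:
        if len(self.base_rates) != self.age_bins.n_bins:
            raise ScenarioConfigError(
                f"hazard_model[{self.name}].base_rates needs "
                f"{self.age_bins.n_bins} entries (one per age bin)"
            )
        for i, r in enumerate(self.base_rates):
            _check_prob(f"hazard_model[{self.name}].base_rates[{i}]", r)
        m = self.income_multipliers
        missing = set(INCOME_GROUPS) - set(m)
        if missing:
            raise ScenarioConfigError(
                f"hazard_model[{self.name}].income_multipliers missing {sorted(missing)}"
            )
        if not (m["low"] >= m["middle"] >= m["high"]):
            raise ScenarioConfigError(
                f"hazard_model[{self.name}].income_multipliers must satisfy "
                "low >= middle >= high"
            )
        if self.female_multiplier < 0:
            raise ScenarioConfigError(
                f"hazard_model[{self.name}].female_multiplier must be >= 0"
            )
        if self.precarious_multiplier < 1.0:
            raise ScenarioConfigError(
                f"hazard_model[{self.name}].precarious_multiplier must be >= 1"
            )

    def annual_probability(
        self, age, income_group, female, precarious
    ) -> np.ndarray:
        """Annual event probability; ``income_group`` is an array of integer
        codes into :data:`INCOME_GROUPS` or of the group names themselves."""
        idx = self.age_bins.assign_index(np.asarray(age))
        base = np.asarray(self.base_rates)[idx]
        income_group = np.asarray(income_group)
        inc_table = np.array([self.income_multipliers[g] for g in INCOME_GROUPS])
        if np.issubdtype(income_group.dtype, np.integer):
            mult = inc_table[income_group]
        else:
            lut = {g: self.income_multipliers[g] for g in INCOME_GROUPS}
            mult = np.array([lut[g] for g in income_group])
        p = base * mult
        p = p * np.where(np.asarray(female, dtype=bool), self.female_multiplier, 1.0)
        p = p * np.where(
            np.asarray(precarious, dtype=bool), self.precarious_multiplier, 1.0
        )
        return np.clip(p, 0.0, 1.0)


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete specification of one synthetic claims world (see module doc)."""

    n_persons: int
    index_year: int = 2017
    history_years: int = 5
    seed: int = 0
    age_distribution: tuple[float, ...] = ()
    sex_ratio_female: float = 0.513
    employment_prob: float = 0.508
    qualification_probs: tuple[float, ...] = ()
    income_group_probs: tuple[float, ...] = ()
    precarious_probs: Mapping[str, float] = field(
        default_factory=lambda: {g: 0.0 for g in INCOME_GROUPS}
    )
    churn_model: ChurnModel = field(default_factory=lambda: ChurnModel(-60.0))
    entry_prob: float = 0.0
    hazard_models: Mapping[str, HazardModel] = field(default_factory=dict)
    recurrence_multiplier: float = 1.0
    i252_prob: float = 0.0
    background_admission_prob: float = 0.0
    pre_index_hazard_scale: float = 1.0
    age_bins: AgeBinScheme = FIVE_YEAR_BINS

    def __post_init__(self) -> None:
        if self.n_persons <= 0:
            raise ScenarioConfigError("n_persons must be a positive integer")
        if self.history_years < 5:
            raise ScenarioConfigError("history_years must be >= 5")
        object.__setattr__(
            self,
            "age_distribution",
            tuple(_check_simplex("age_distribution", self.age_distribution,
                                 self.age_bins.n_bins)),
        )
        _check_prob("sex_ratio_female", self.sex_ratio_female)
        if not (0.0 < self.sex_ratio_female < 1.0):
            raise ScenarioConfigError("sex_ratio_female must lie strictly in (0, 1)")
        _check_prob("employment_prob", self.employment_prob)
        object.__setattr__(
            self,
            "qualification_probs",
            tuple(_check_simplex("qualification_probs", self.qualification_probs,
                                 len(QUALIFICATION_LEVELS))),
        )
        object.__setattr__(
            self,
            "income_group_probs",
            tuple(_check_simplex("income_group_probs", self.income_group_probs,
                                 len(INCOME_GROUPS))),
        )
        for g in INCOME_GROUPS:
            if g not in self.precarious_probs:
                raise ScenarioConfigError(f"precarious_probs missing group {g!r}")
            _check_prob(f"precarious_probs[{g}]", self.precarious_probs[g])
        _check_prob("entry_prob", self.entry_prob)
        if self.recurrence_multiplier < 1.0:
            raise ScenarioConfigError("recurrence_multiplier must be >= 1")
        _check_prob("i252_prob", self.i252_prob)
        _check_prob("background_admission_prob", self.background_admission_prob)
        if not (0.0 <= self.pre_index_hazard_scale <= 1.0):
            raise ScenarioConfigError("pre_index_hazard_scale must be in [0, 1]")

    @property
    def first_year(self) -> int:
        return self.index_year - self.history_years


# ---------------------------------------------------------------------------
# Presets

# 5-year age-bin weights consistent with the 10-year population margins of a
# large German statutory fund (25-34: 19.2%, 35-44: 15.7%, 45-54: 19.8%,
# 55-64: 17.2%, 65-74: 11.6%, 75-84: 11.7%, 85+: 4.8%).
_AGE_WEIGHTS = (
    0.098, 0.094,  # 25-29, 30-34
    0.078, 0.079,  # 35-39, 40-44
    0.099, 0.099,  # 45-49, 50-54
    0.086, 0.086,  # 55-59, 60-64
    0.059, 0.057,  # 65-69, 70-74
    0.063, 0.054,  # 75-79, 80-84
    0.031, 0.013, 0.004,  # 85-89, 90-94, 95+
)

# pooled-sexes qualification mix among the ever-employed
_QUALIFICATION_PROBS = (0.122, 0.570, 0.030, 0.014, 0.039, 0.002, 0.223)

# pooled-sexes income-group mix (low, middle, high, unknown)
_INCOME_PROBS = (0.192, 0.278, 0.195, 0.335)

# Annual first-event probabilities per 5-year age bin for the reference
# stratum (male, high income, non-precarious).  Roughly twice real-world
# German incidence so that desk-scale runs (1e5-2e5 persons standing in for a
# 2e6-person fund) produce enough events for directional tests.
_MI_BASE = (
    0.0004, 0.0006, 0.0010, 0.0016, 0.0026, 0.0040,
    0.0060, 0.0090, 0.0160, 0.0230, 0.0300, 0.0380,
    0.0450, 0.0500, 0.0540,
)
_STROKE_BASE = (
    0.0003, 0.0005, 0.0008, 0.0013, 0.0022, 0.0036,
    0.0058, 0.0092, 0.0180, 0.0280, 0.0410, 0.0590,
    0.0780, 0.0940, 0.1060,
)


def _hazards(precarious_multiplier: float = 1.0) -> dict[str, HazardModel]:
    return {
        "MI": HazardModel(
            name="MI",
            base_rates=_MI_BASE,
            income_multipliers={"low": 1.8, "middle": 1.3, "high": 1.0,
                                "unknown": 1.55},
            female_multiplier=0.45,
            precarious_multiplier=precarious_multiplier,
        ),
        "stroke": HazardModel(
            name="stroke",
            base_rates=_STROKE_BASE,
            income_multipliers={"low": 1.7, "middle": 1.25, "high": 1.0,
                                "unknown": 1.45},
            female_multiplier=0.80,
            precarious_multiplier=precarious_multiplier,
        ),
    }


def default_scenario(n_persons: int = 100_000, seed: int = 0,
                     index_year: int = 2017) -> ScenarioConfig:
    """Population margins as above with a flat 2%/year churn (the published
    system-wide average rate of switching between statutory funds)."""
    return ScenarioConfig(
        n_persons=n_persons,
        index_year=index_year,
        seed=seed,
        age_distribution=_AGE_WEIGHTS,
        qualification_probs=_QUALIFICATION_PROBS,
        income_group_probs=_INCOME_PROBS,
        churn_model=ChurnModel(intercept=float(np.log(0.02 / 0.98))),
        entry_prob=0.30,
        hazard_models=_hazards(),
        recurrence_multiplier=1.5,
        i252_prob=0.35,
        background_admission_prob=0.12,
    )


def null_scenario(n_persons: int = 10_000, seed: int = 0,
                  index_year: int = 2017) -> ScenarioConfig:
    """Zero churn, no entries, no pre-index events: the exact-identity world.

    Every person is insured from the start of the history window through the
    index year, so BASE and every CONk coincide and lookback washout removes
    nobody; rates are identical across lookbacks by construction.
    """
    return ScenarioConfig(
        n_persons=n_persons,
        index_year=index_year,
        seed=seed,
        age_distribution=_AGE_WEIGHTS,
        qualification_probs=_QUALIFICATION_PROBS,
        income_group_probs=_INCOME_PROBS,
        churn_model=ChurnModel(intercept=-60.0),
        entry_prob=0.0,
        hazard_models=_hazards(),
        recurrence_multiplier=1.0,
        i252_prob=0.0,
        background_admission_prob=0.10,
        pre_index_hazard_scale=0.0,
    )


def selective_churn_scenario(n_persons: int = 100_000, seed: int = 0,
                        index_year: int = 2017) -> ScenarioConfig:
    """Preset reproducing the qualitative selection-bias patterns of
    single-fund claims data (see module docstring).

    Churn declines with age (roughly 9-11%/year in the late twenties down to
    under 1%/year above 80 for the reference stratum), is elevated for
    persons without income information, and is strongly elevated for the
    latent precarious subgroup, which is most prevalent in the low and
    unknown income groups and carries elevated cardiovascular risk.
    """
    return ScenarioConfig(
        n_persons=n_persons,
        index_year=index_year,
        seed=seed,
        age_distribution=_AGE_WEIGHTS,
        qualification_probs=_QUALIFICATION_PROBS,
        income_group_probs=_INCOME_PROBS,
        precarious_probs={"low": 0.50, "middle": 0.20, "high": 0.03,
                          "unknown": 0.25},
        churn_model=ChurnModel(
            intercept=-0.84,
            age_slope=-0.062,
            unknown_income_offset=0.45,
            precarious_offset=1.50,
        ),
        entry_prob=0.50,
        hazard_models=_hazards(precarious_multiplier=3.0),
        recurrence_multiplier=1.0,
        i252_prob=0.35,
        background_admission_prob=0.12,
        pre_index_hazard_scale=0.03,
    )


def income_independent_churn_scenario(
    n_persons: int = 100_000, seed: int = 0, index_year: int = 2017
) -> ScenarioConfig:
    """Counterfactual twin of :func:`selective_churn_scenario` whose churn depends
    on age only (no unknown-income or precarious offsets).

    Hazards are unchanged, so exclusion under a lookback is random within
    every age x income cell and age-standardized stratum rates — hence the
    social gradient — are unaffected in expectation.  Serves as the
    independent oracle for the gradient-narrowing property.
    """
    cfg = selective_churn_scenario(n_persons=n_persons, seed=seed, index_year=index_year)
    return replace(
        cfg,
        churn_model=ChurnModel(
            intercept=cfg.churn_model.intercept,
            age_slope=cfg.churn_model.age_slope,
            unknown_income_offset=0.0,
            precarious_offset=0.0,
        ),
    )
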