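"""Simulation configuration for the synthetic iCBT cohort generator.

The defaults encode the statistical structure of a large routine-care
internet-CBT service cohort (n=6701): module-completion proportions, a
dropout model dominated by treatment completion (odds ratios in the
100s for minimal completers), and proportional symptom change moderated by
completion and baseline severity.  A cohort is fully reproducible from
``(SimConfig, seed)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


class ConfigError(ValueError):
    """A SimConfig field is out of range or inconsistent."""


#: Module-completion proportions (levels 1..5), from the observed counts
#: 513/715/718/653/4102 over 6701, so they sum to exactly 1.
DEFAULT_COMPLETION_PROPORTIONS = (
    513 / 6701, 715 / 6701, 718 / 6701, 653 / 6701, 4102 / 6701,
)

#: Posttreatment-missingness odds ratios for completion levels 1..4 versus
#: full completers (level 5).
DEFAULT_COMPLETION_ORS = {1: 162.104, 2: 106.01, 3: 33.715, 4: 9.104}

#: Reference (full completer, average covariates) missingness probability.
DEFAULT_REFERENCE_MISSING_PROB = 0.098

#: Per-scale pre->post expected-score ratio for the reference group
#: (full completers at average baseline severity).
DEFAULT_TIME_COEFFICIENTS = {"phq9": 0.51, "gad7": 0.51, "k10": 0.62}

#: Multiplicative attenuation of the change ratio for partial completers,
#: relative to full completers (ratio_level = time_coefficient * multiplier).
#: Derived from the printed per-level change rates of the source tables.
DEFAULT_COMPLETION_CHANGE_MULTIPLIERS = {
    "phq9": {1: 1.392, 2: 1.314, 3: 1.275, 4: 1.137, 5: 1.0},
    "gad7": {1: 1.176, 2: 1.216, 3: 1.275, 4: 1.118, 5: 1.0},
    "k10": {1: 1.323, 2: 1.129, 3: 1.177, 4: 1.065, 5: 1.0},
}

#: Per offset-adjusted baseline point (centred at the cohort mean),
#: multiplicative moderation of the change ratio by own-scale severity.
DEFAULT_SEVERITY_CHANGE_MULTIPLIERS = {"phq9": 0.988, "gad7": 0.976, "k10": 0.994}

#: Baseline negative-binomial parameters on the offset-adjusted scale
#: (mean, dispersion r with variance mu + mu^2/r).
DEFAULT_BASELINE_PARAMS = {
    "phq9": {"mean": 12.5, "dispersion": 8.0},
    "gad7": {"mean": 11.0, "dispersion": 9.0},
    "k10": {"mean": 18.8, "dispersion": 8.0},
}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Attributes
    ----------
    n : int
        Number of participants.
    completion_proportions : tuple of 5 floats
        Fractions completing 1..5 modules; must sum to 1.
    reference_missing_prob : float
        Posttreatment missingness probability for full completers at
        average baseline severity and age.
    completion_odds_ratios : dict
        Missingness odds ratios for completion levels 1..4 vs level 5.
    severity_or_per_point : float
        Missingness OR per offset-adjusted baseline PHQ-9 point (centred).
    age_or_per_year : float
        Missingness OR per year of age (centred).
    baseline_params : dict
        Per-scale ``{"mean", "dispersion"}`` of the offset-scale negative
        binomial baseline distribution.
    interscale_correlation : float
        Gaussian-copula correlation between the three baseline scores.
    time_coefficients : dict
        Per-scale reference pre->post expected ratio, in (0, 1].
    completion_change_multipliers : dict
        Per-scale, per-level change-ratio multipliers (level 5 == 1).
    severity_change_multipliers : dict
        Per-scale multiplier applied per centred offset baseline point.
    within_subject_correlation : float
        Target correlation between pretreatment and later scores, in [0, 1);
        the multiplicative gamma noise variance is derived from it.
    integer_scores : bool
        Round and clip simulated scores to the integer scale range
        (disable for closed-form noise-free checks).
    noise : bool
        Apply multiplicative gamma noise to mid/post scores.
    """

    n: int = 6701
    completion_proportions: tuple = DEFAULT_COMPLETION_PROPORTIONS
    reference_missing_prob: float = DEFAULT_REFERENCE_MISSING_PROB
    completion_odds_ratios: dict = field(
        default_factory=lambda: dict(DEFAULT_COMPLETION_ORS))
    severity_or_per_point: float = 1.037
    age_or_per_year: float = 0.967
    demographic_missing_ors: dict = field(
        default_factory=lambda: {
            "gender": 1.0, "employment": 1.0, "relationship": 1.0,
            "education": 1.0,
        })
    age_mean: float = 37.57
    age_sd: float = 10.9
    prop_female: float = 4866 / 6701
    prop_relationship: float = 4458 / 6701
    prop_employed: float = 4908 / 6701
    prop_tertiary: float = 3239 / 6701
    baseline_params: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_BASELINE_PARAMS.items()})
    interscale_correlation: float = 0.6
    time_coefficients: dict = field(
        default_factory=lambda: dict(DEFAULT_TIME_COEFFICIENTS))
    completion_change_multipliers: dict = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_COMPLETION_CHANGE_MULTIPLIERS.items()})
    severity_change_multipliers: dict = field(
        default_factory=lambda: dict(DEFAULT_SEVERITY_CHANGE_MULTIPLIERS))
    demographic_change_multipliers: dict = field(default_factory=dict)
    within_subject_correlation: float = 0.72
    integer_scores: bool = True
    noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        props = tuple(self.completion_proportions)
        if len(props) != 5:
            raise ConfigError("completion_proportions must have 5 entries")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ConfigError("completion_proportions must sum to 1")
        if any(p < 0 for p in props):
            raise ConfigError("completion_proportions must be nonnegative")
        if not 0 < self.reference_missing_prob < 1:
            raise ConfigError("reference_missing_prob must be in (0, 1)")
        for lvl, odds in self.completion_odds_ratios.items():
            if odds <= 0:
                raise ConfigError(f"completion OR for level {lvl} must be > 0")
        if self.severity_or_per_point <= 0 or self.age_or_per_year <= 0:
            raise ConfigError("odds ratios must be > 0")
        for key, tc in self.time_coefficients.items():
            if not 0 < tc <= 1:
                raise ConfigError(f"time_coefficient[{key}] must be in (0, 1]")
        if not 0 <= self.within_subject_correlation < 1:
            raise ConfigError("within_subject_correlation must be in [0, 1)")
        if not -1 < self.interscale_correlation < 1:
            raise ConfigError("interscale_correlation must be in (-1, 1)")
        for key, params in self.baseline_params.items():
            if params["mean"] <= 0 or params["dispersion"] <= 0:
                raise ConfigError(f"baseline_params[{key}] must be positive")

    # ------------------------------------------------------------------- io
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["completion_proportions"] = list(self.completion_proportions)
        # JSON objects have string keys; normalise level dicts
        d["completion_odds_ratios"] = {
            str(k): v for k, v in self.completion_odds_ratios.items()}
        d["completion_change_multipliers"] = {
            s: {str(k): v for k, v in m.items()}
            for s, m in self.completion_change_multipliers.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "completion_proportions" in d:
            d["completion_proportions"] = tuple(d["completion_proportions"])
        if "completion_odds_ratios" in d:
            d["completion_odds_ratios"] = {
                int(k): v for k, v in d["completion_odds_ratios"].items()}
        if "completion_change_multipliers" in d:
            d["completion_change_multipliers"] = {
                s: {int(k): v for k, v in m.items()}
                for s, m in d["completion_change_multipliers"].items()}
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)
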