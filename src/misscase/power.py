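"""Simulation-based power analysis for the dropout and change models.

Both curves answer the question the replication design poses: *how small a
departure from the whole-sample reference could a subsample of size n refute
as a false negative at 80% power?*  Accordingly the Monte-Carlo tests are
one-sample tests against the known reference:

* change (moderation): simulate n (pre, post) pairs from pilot parameters,
  half of them with the change rate shifted by ``effect`` percentage points,
  fit the moderated gamma/log GEE and Wald-test the time-by-group
  interaction;
* missingness: simulate n Bernoulli outcomes with the probability shifted by
  ``effect`` points and Wald-test the intercept of a logistic fit with the
  reference log odds as offset (the subsample against the known
  whole-sample rate).

The minimal detectable effect at the target power is linearly interpolated
on the evaluated grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

from .change import SymptomChangeModel, ChangeModelSpec, change_rate
from .cohort import Cohort
from .scales import get_scale

__all__ = [
    "PowerConfig", "PowerCurve", "PilotParameters",
    "extract_pilot_parameters", "power_curve_change",
    "power_curve_missingness",
]


@dataclass
class PilotParameters:
    """Observed quantities a power simulation is anchored to."""

    change_ratio: float             # pre->post expected ratio
    baseline_mean: float            # shifted-scale mean at pre
    baseline_dispersion: float      # squared CV of shifted scores at pre
    post_dispersion: float          # squared CV at post (observed cases)
    residual_dispersion: float      # squared CV of post/(pre*ratio): the noise
    within_subject_correlation: float
    n_source: int


@dataclass
class PowerConfig:
    """Settings of one Monte-Carlo power curve."""

    n: int = 1341
    effects: tuple = (0.0, 2.0, 4.0, 6.0, 8.0)   # percentage points
    replications: int = 200
    alpha: float = 0.05
    target_power: float = 0.80
    reference_rate: float = 0.36    # missingness probability, or change rate/100
    pilot: PilotParameters | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must be in (0, 1)")
        if self.replications < 1:
            raise ValueError("replications must be >= 1")


@dataclass
class PowerCurve:
    """Rejection rates over an effect grid, with the interpolated MDE."""

    effects: np.ndarray
    rejection_rates: np.ndarray
    rejections: np.ndarray
    replications: int
    alpha: float
    target_power: float
    minimal_detectable_effect: float | None
    out_of_range: bool

    def monte_carlo_ci(self, alpha: float = 0.05) -> pd.DataFrame:
        """Binomial (Wilson) CI on each rejection rate."""
        rows = []
        for e, k in zip(self.effects, self.rejections):
            lo, hi = _wilson(k, self.replications, alpha)
            rows.append({"effect": e, "rate": k / self.replications,
                         "lower": lo, "upper": hi})
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        df = self.monte_carlo_ci()
        df["rejections"] = self.rejections
        df["replications"] = self.replications
        return df


def _wilson(k: int, n: int, alpha: float) -> tuple[float, float]:
    z = stats.norm.ppf(1 - alpha / 2)
    p = k / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return max(centre - half, 0.0), min(centre + half, 1.0)


def _interpolate_mde(effects, rates, target) -> tuple[float | None, bool]:
    effects = np.asarray(effects, dtype=float)
    rates = np.asarray(rates, dtype=float)
    order = np.argsort(effects)
    effects, rates = effects[order], rates[order]
    above = np.nonzero(rates >= target)[0]
    if len(above) == 0:
        return None, True
    j = above[0]
    if j == 0:
        return float(effects[0]), effects[0] > 0
    e0, e1 = effects[j - 1], effects[j]
    r0, r1 = rates[j - 1], rates[j]
    if r1 == r0:
        return float(e1), False
    return float(e0 + (target - r0) * (e1 - e0) / (r1 - r0)), False


# ------------------------------------------------------------------- pilot
def extract_pilot_parameters(cohort: Cohort, scale: str = "phq9") -> PilotParameters:
    """Rate of change, per-timepoint dispersion and within-subject
    correlation from a fitted time-only change model on a pilot cohort."""
    fitted = SymptomChangeModel(cohort, scale).fit()
    spec = get_scale(scale)
    wide = cohort.scores_wide(scale)
    pre_sh = wide["pre"].values - spec.analysis_offset + 1.0
    post_sh = wide["post"].dropna().values - spec.analysis_offset + 1.0
    pairs = wide.dropna(subset=["pre", "post"])
    corr = float(np.corrcoef(pairs["pre"], pairs["post"])[0, 1]) \
        if len(pairs) > 2 else 0.0
    disp = lambda x: float(np.var(x) / np.mean(x) ** 2)
    off = spec.analysis_offset
    ratio_resid = ((pairs["post"].values - off + 1.0)
                   / ((pairs["pre"].values - off + 1.0)
                      * fitted.exp_beta_time))
    return PilotParameters(
        change_ratio=fitted.exp_beta_time,
        baseline_mean=float(np.mean(pre_sh)),
        baseline_dispersion=disp(pre_sh),
        post_dispersion=disp(post_sh) if len(post_sh) else 0.0,
        residual_dispersion=disp(ratio_resid) if len(pairs) > 2 else 0.0,
        within_subject_correlation=corr,
        n_source=cohort.n,
    )


# ------------------------------------------------------------------ change
def _simulate_pairs(rng, n: int, pilot: PilotParameters, ratio: float):
    """(pre, post) shifted-score pairs matching the pilot moments."""
    mu, d = pilot.baseline_mean, max(pilot.baseline_dispersion, 1e-6)
    pre = rng.gamma(1.0 / d, d * mu, n)
    v = pilot.residual_dispersion
    if v <= 0:
        # fall back: derive the noise from the pre-post correlation
        rho = min(max(pilot.within_subject_correlation, 0.0), 0.99)
        v = (1.0 / rho**2 - 1.0) * d / (1.0 + d) if rho > 0 else 24.0
    eps = rng.gamma(1.0 / v, v, n) if v > 0 else np.ones(n)
    post = pre * ratio * eps
    return pre, post


def power_curve_change(config: PowerConfig) -> PowerCurve:
    """Power to detect moderation of the symptom change rate.

    Half the simulated sample changes at the pilot rate, half at a rate
    shifted by ``effect`` percentage points; the test is the Wald test of
    the time-by-group interaction in the gamma/log GEE.
    """
    pilot = config.pilot
    if pilot is None:
        raise ValueError("power_curve_change requires pilot parameters")
    ref_ratio = pilot.change_ratio
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(11,)))
    rejections = []
    for effect in config.effects:
        # moderated half changes `effect` rate points more slowly
        ratio = ref_ratio + effect / 100.0
        hits = 0
        for _ in range(config.replications):
            n1 = config.n // 2
            n2 = config.n - n1
            pre1, post1 = _simulate_pairs(rng, n1, pilot, ref_ratio)
            pre2, post2 = _simulate_pairs(rng, n2, pilot, ratio)
            y = np.concatenate([pre1, post1, pre2, post2])
            time = np.concatenate([np.zeros(n1), np.ones(n1),
                                   np.zeros(n2), np.ones(n2)])
            groups = np.concatenate([np.arange(n1), np.arange(n1),
                                     np.arange(n1, config.n),
                                     np.arange(n1, config.n)])
            grp = (groups >= n1).astype(float)
            X = np.column_stack([np.ones_like(time), time, grp, time * grp])
            gee = sm.GEE(y, X, groups=groups,
                         family=sm.families.Gamma(sm.families.links.Log()),
                         cov_struct=sm.cov_struct.Exchangeable())
            res = gee.fit(maxiter=30)
            z = res.params[3] / res.bse[3]
            if 2 * stats.norm.sf(abs(z)) < config.alpha:
                hits += 1
        rejections.append(hits)
    rejections = np.asarray(rejections)
    rates = rejections / config.replications
    mde, oor = _interpolate_mde(config.effects, rates, config.target_power)
    return PowerCurve(np.asarray(config.effects, float), rates, rejections,
                      config.replications, config.alpha, config.target_power,
                      mde, oor)


# -------------------------------------------------------------- missingness
def power_curve_missingness(config: PowerConfig) -> PowerCurve:
    """Power to refute a shift of the missingness probability away from the
    reference, in absolute percentage points (e.g. 3.6 of 36)."""
    p0 = config.reference_rate
    if not 0 < p0 < 1:
        raise ValueError("reference_rate must be in (0, 1)")
    offset = np.log(p0 / (1 - p0))
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(12,)))
    rejections = []
    for effect in config.effects:
        p = min(max(p0 + effect / 100.0, 1e-6), 1 - 1e-6)
        hits = 0
        for _ in range(config.replications):
            y = (rng.random(config.n) < p).astype(float)
            if y.min() == y.max():
                continue
            X = np.ones((config.n, 1))
            res = sm.GLM(y, X, family=sm.families.Binomial(),
                         offset=np.full(config.n, offset)).fit()
            if res.pvalues[0] < config.alpha:
                hits += 1
        rejections.append(hits)
    rejections = np.asarray(rejections)
    rates = rejections / config.replications
    mde, oor = _interpolate_mde(config.effects, rates, config.target_power)
    return PowerCurve(np.asarray(config.effects, float), rates, rejections,
                      config.replications, config.alpha, config.target_power,
                      mde, oor)
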