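"""Synthetic cohort generator.

Emulates the statistical structure of a large routine-care internet-CBT
cohort so that every downstream stage (dropout models, proportional-change
GEEs, replacement comparison, power) is testable without external data:

* bounded, positively skewed integer baseline scores on three symptom
  scales, drawn from negative binomials coupled by a Gaussian copula;
* proportional pre->post change on the log scale (``post = pre * ratio``)
  with the ratio moderated multiplicatively by module completion and by
  centred baseline severity; the mid score is the geometric midpoint;
* multiplicative mean-one gamma noise at mid and post, with its variance
  derived from the configured within-subject (pre vs later) correlation;
* posttreatment dropout as a participant-level logistic event dominated by
  module completion, with secondary baseline-severity and age effects.

All scores are simulated on the shifted analysis scale
``offset score + 1`` (so the log link is defined at zero) and shifted back
before storage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .cohort import Cohort
from .config import SimConfig
from .scales import SCALES, get_scale

__all__ = [
    "generate_cohort", "simulate_trajectories", "apply_dropout", "simulate",
]


def _rng_for(config: SimConfig, seed: int | None, stream: int) -> np.random.Generator:
    base = config.seed if seed is None else seed
    return np.random.default_rng(np.random.SeedSequence(entropy=base, spawn_key=(stream,)))


def _noise_variance(pre_sh: np.ndarray, expected: np.ndarray, rho: float) -> float:
    """Variance of mean-one multiplicative noise giving corr(pre, later) == rho.

    With A the shifted baseline, B the deterministic expected later score and
    eps independent mean-one noise of variance v,
    ``corr(A, B*eps) = cov(A,B) / sqrt(varA * (varB*(1+v) + v*E[B]^2))``;
    solving for v matches the target correlation exactly (before rounding).
    Returns 0 when the moderation heterogeneity alone already pushes the
    correlation below the target.
    """
    if rho <= 0:
        return 24.0  # shape 1/24 gamma: effectively decorrelated
    if len(pre_sh) < 3 or np.var(pre_sh) <= 0:
        return 0.0   # no between-subject spread to calibrate against
    var_a = float(np.var(pre_sh))
    var_b = float(np.var(expected))
    cov = float(np.cov(pre_sh, expected)[0, 1])
    mean_b = float(np.mean(expected))
    v = (cov**2 / (var_a * rho**2) - var_b) / (var_b + mean_b**2)
    return max(v, 0.0)


# --------------------------------------------------------------------------
def generate_cohort(config: SimConfig, seed: int | None = None) -> Cohort:
    """Draw a complete cohort: demographics, adherence, baselines and full
    (dropout-free) trajectories.

    Parameters
    ----------
    config : SimConfig
        Generator parameters; validated on construction.
    seed : int, optional
        Overrides ``config.seed``.
    """
    config.validate()
    rng = _rng_for(config, seed, 0)
    n = config.n

    # adherence and demographics
    modules = rng.choice(
        np.arange(1, 6), size=n, p=np.asarray(config.completion_proportions))
    participants = pd.DataFrame({
        "id": np.arange(n),
        "age": np.clip(rng.normal(config.age_mean, config.age_sd, n), 16.0, 90.0),
        "gender": (rng.random(n) < config.prop_female).astype(int),
        "employment": (rng.random(n) < config.prop_employed).astype(int),
        "relationship": (rng.random(n) < config.prop_relationship).astype(int),
        "education": (rng.random(n) < config.prop_tertiary).astype(int),
        "modules_completed": modules,
    })

    # correlated skewed baselines via a Gaussian copula over negative binomials
    keys = list(SCALES)
    rho = config.interscale_correlation
    corr = np.full((len(keys), len(keys)), rho)
    np.fill_diagonal(corr, 1.0)
    z = rng.multivariate_normal(np.zeros(len(keys)), corr, size=n)
    u = stats.norm.cdf(z)
    rows = []
    for j, key in enumerate(keys):
        spec = get_scale(key)
        params = config.baseline_params[key]
        mu, r = params["mean"], params["dispersion"]
        p_nb = r / (r + mu)
        off = stats.nbinom.ppf(np.clip(u[:, j], 1e-12, 1 - 1e-12), r, p_nb)
        off = np.clip(off, 0, spec.span)
        raw = off + spec.minimum
        rows.append(pd.DataFrame({
            "id": participants["id"], "scale": key, "timepoint": "pre",
            "score": raw.astype(float),
        }))
    measurements = pd.concat(rows, ignore_index=True)
    cohort = Cohort(participants, measurements,
                    meta={"config": config.to_dict(), "seed": seed if seed is not None else config.seed})
    return simulate_trajectories(cohort, config, seed=seed)


def expected_change_ratio(cohort: Cohort, config: SimConfig, scale: str) -> pd.Series:
    """Per-participant expected pre->post ratio implied by the generator.

    ``ratio_i = time_coefficient * completion multiplier * severity
    multiplier^(centred offset baseline)``, indexed by participant id.
    """
    spec = get_scale(scale)
    pre_off = cohort.baseline(scale) - spec.analysis_offset
    centred = pre_off - pre_off.mean()
    mods = cohort.participants.set_index("id")["modules_completed"]
    comp_mult = mods.map(config.completion_change_multipliers[scale]).astype(float)
    sev_mult = config.severity_change_multipliers[scale] ** centred
    ratio = config.time_coefficients[scale] * comp_mult * sev_mult
    for cov, mults in config.demographic_change_multipliers.items():
        values = cohort.participants.set_index("id")[cov]
        ratio = ratio * values.map(mults).astype(float)
    return ratio


def simulate_trajectories(cohort: Cohort, config: SimConfig,
                          seed: int | None = None) -> Cohort:
    """Fill in mid (week 4) and post (week 8) scores for every participant.

    The expected shifted post score is ``(pre_off + 1) * ratio``; the mid
    score sits at the geometric midpoint (``ratio**0.5``).  Mean-one gamma
    noise multiplies both, independently, unless ``config.noise`` is False.
    """
    rng = _rng_for(config, seed, 1)
    pieces = [cohort.measurements[cohort.measurements["timepoint"] == "pre"]]
    for key in SCALES:
        spec = get_scale(key)
        pre_off = cohort.baseline(key).values - spec.analysis_offset
        pre_sh = pre_off + 1.0
        ratio = expected_change_ratio(cohort, config, key).values
        for tp, frac in (("mid", 0.5), ("post", 1.0)):
            expected = pre_sh * ratio**frac
            if config.noise:
                v = _noise_variance(pre_sh, expected,
                                    config.within_subject_correlation)
                eps = rng.gamma(1.0 / v, v, cohort.n) if v > 0 else np.ones(cohort.n)
            else:
                eps = np.ones(cohort.n)
            sh = expected * eps
            off = sh - 1.0
            if config.integer_scores:
                off = np.clip(np.round(off), 0, spec.span)
            else:
                off = np.clip(off, 0.0, float(spec.span))
            pieces.append(pd.DataFrame({
                "id": cohort.participants["id"], "scale": key,
                "timepoint": tp, "score": off + spec.minimum,
            }))
    measurements = pd.concat(pieces, ignore_index=True)
    return Cohort(cohort.participants, measurements, meta=dict(cohort.meta))


def missingness_probability(cohort: Cohort, config: SimConfig) -> pd.Series:
    """Per-participant posttreatment-missingness probability (by id).

    ``logit(p) = logit(reference) + log OR_completion + log OR_severity *
    centred baseline PHQ-9 + log OR_age * centred age`` plus any demographic
    log-odds terms.
    """
    d = cohort.design_frame().set_index("id")
    eta = np.full(cohort.n, special.logit(config.reference_missing_prob))
    ors = dict(config.completion_odds_ratios)
    ors[5] = 1.0
    eta = eta + np.log(d["modules_completed"].map(ors).values.astype(float))
    phq = d["phq9_pre"].values
    eta = eta + np.log(config.severity_or_per_point) * (phq - phq.mean())
    age = d["age"].values
    eta = eta + np.log(config.age_or_per_year) * (age - age.mean())
    for cov, odds in config.demographic_missing_ors.items():
        if odds != 1.0:
            eta = eta + np.log(odds) * d[cov].values
    return pd.Series(special.expit(eta), index=d.index)


def apply_dropout(cohort: Cohort, config: SimConfig,
                  seed: int | None = None) -> Cohort:
    """Delete posttreatment rows as a joint participant-level event.

    Pre and mid assessments are never removed.
    """
    rng = _rng_for(config, seed, 2)
    p = missingness_probability(cohort, config)
    drop_ids = set(p.index[rng.random(cohort.n) < p.values])
    m = cohort.measurements
    keep = ~((m["timepoint"] == "post") & (m["id"].isin(drop_ids)))
    return Cohort(cohort.participants, m[keep], meta=dict(cohort.meta))


def simulate(config: SimConfig | None = None, seed: int | None = None) -> Cohort:
    """Generate a cohort and apply dropout: the full study-condition draw."""
    config = config or SimConfig()
    return apply_dropout(generate_cohort(config, seed=seed), config, seed=seed)
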