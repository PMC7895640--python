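"""Replacement of missing posttreatment scores under competing assumptions.

Each method produces a :class:`ReplacementEstimate`: the mean replacement
score assigned to the posttreatment missing cases, its 95% CI, the percent
difference relative to the completer-only (MCAR) estimate, and an
equivalence verdict.

Methods
-------
MCAR
    time-only marginal model: every missing case receives the completer
    marginal posttreatment mean.
MAR(<covariates>)
    covariate-stratified GEE: each missing case receives the model
    prediction at its own covariate values.
MI
    multiple stochastic imputation on the log scale with Rubin pooling.
MLM
    subject-level mixed model (random intercepts and slopes): missing cases
    predicted from their own partial trajectories.
LOCF / BOCF
    last / baseline observation carried forward.

The default reported mean averages over the missing subset (the "mean
predicted posttreatment score" convention); a cohort-level mean (observed
completer scores plus replacements) is also carried on each estimate.

The equivalence rule compares confidence intervals: an adjusted model is
*equivalent* to MCAR when its CI lies within the MCAR CI, *above*/*below*
when its CI excludes the MCAR point mean on one side, and *inconclusive*
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats

import statsmodels.api as sm

from .change import COVARIATE_TERMS, SymptomChangeModel, ChangeModelSpec
from .cohort import Cohort, WEEKS
from .scales import get_scale

__all__ = [
    "ReplacementEstimate", "MIConfig", "ReplacementAnalysis",
    "compare_to_mcar", "replace_mcar", "replace_mar", "replace_locf",
    "replace_bocf", "replace_mi", "replace_mlm",
]

VERDICTS = ("equivalent", "above", "below", "inconclusive")


@dataclass
class ReplacementEstimate:
    """One replacement model's summary for the missing cases of one scale."""

    method: str
    mean: float                     # mean replacement score, missing subset
    ci: tuple[float, float]
    se: float
    cohort_mean: float              # observed completers + replacements
    relative_pct: float | None = None       # 100 * (mean - mcar) / mcar
    relative_ci: tuple[float, float] | None = None
    verdict: str | None = None
    n_missing: int = 0
    extrapolated: bool = False      # covariate level unseen among completers


@dataclass
class MIConfig:
    """Multiple-imputation settings (Rubin pooling).

    With ``covariates=()`` and ``use_pre=use_mid=False`` the imputation
    model is intercept-only, i.e. draws from the completers' posttreatment
    distribution (the MCAR reduction).
    """

    m: int = 20
    covariates: tuple = ("completion", "phq9_pre")
    use_pre: bool = True
    use_mid: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("number of imputations m must be >= 2")


def compare_to_mcar(estimate: ReplacementEstimate,
                    mcar_estimate: ReplacementEstimate) -> tuple[float, str]:
    """Percent difference from MCAR and the CI-containment verdict."""
    m0 = mcar_estimate.mean
    if m0 == 0:
        raise ZeroDivisionError("MCAR mean is zero")
    percent = 100.0 * (estimate.mean - m0) / m0
    lo, hi = estimate.ci
    lo0, hi0 = mcar_estimate.ci
    if lo0 <= lo and hi <= hi0:
        verdict = "equivalent"
    elif lo > m0:
        verdict = "above"
    elif hi < m0:
        verdict = "below"
    else:
        verdict = "inconclusive"
    return percent, verdict


class ReplacementAnalysis:
    """Side-by-side replacement comparison for one scale of one cohort.

    All stochastic pieces (relative-percent Monte Carlo, carried-forward
    bootstrap, MI draws) are driven by ``seed``.
    """

    def __init__(self, cohort: Cohort, scale: str, seed: int = 0,
                 alpha: float = 0.05, mc_draws: int = 2000):
        self.cohort = cohort
        self.scale = scale.lower()
        self.spec = get_scale(self.scale)
        self.seed = seed
        self.alpha = alpha
        self.mc_draws = mc_draws
        wide = cohort.scores_wide(self.scale)
        self.wide = wide
        self.missing_mask = wide["post"].isna()
        if (~self.missing_mask).sum() < 1:
            raise ValueError("no observed posttreatment scores")
        self.n_missing = int(self.missing_mask.sum())
        self._fits: dict = {}
        self._mcar: ReplacementEstimate | None = None

    # ----------------------------------------------------------- utilities
    def _z(self) -> float:
        return stats.norm.ppf(1 - self.alpha / 2)

    def _fit_gee(self, covariates: tuple):
        if covariates not in self._fits:
            cov = covariates[0] if len(covariates) == 1 else None
            model = SymptomChangeModel(self.cohort, self.scale, cov)
            if len(covariates) > 1:
                frags = " + ".join(
                    COVARIATE_TERMS.get(c, c) for c in covariates)
                model.covariate = None
                model._multi_formula = f"y ~ time * ({frags})"
                # rebuild with the combined formula
                import statsmodels.formula.api as smf
                gee = smf.gee(model._multi_formula, groups="id",
                              data=model.data,
                              time=model.data["time_index"].values.astype(int),
                              family=model.spec.build_family(),
                              cov_struct=model.spec.build_cov_struct())
                res = gee.fit()
                from .change import SymptomChangeResults
                fitted = SymptomChangeResults(model, res)
            else:
                fitted = model.fit()
            self._fits[covariates] = fitted
        return self._fits[covariates]

    def _predict_missing(self, fitted) -> tuple[np.ndarray, np.ndarray]:
        """Model predictions (raw scale) for missing cases at post, plus the
        delta-method SE of their mean.

        For the time-only model the SE is that of the marginal mean.  For
        adjusted models the SE is that of the *adjustment*: the difference
        between the missing-subset prediction mean and the same model's
        whole-cohort marginal post mean (the shared level and time effect
        cancel in the gradient), so the CI expresses how far the covariate
        moves the replacement away from the marginal estimate.
        """
        gee = fitted.gee_results
        data = fitted.model.data
        base_all = data[data["timepoint"] == "pre"].copy()
        base_all = base_all.assign(time=1.0)
        design_info = gee.model.data.design_info
        (X_all,) = patsy.build_design_matrices([design_info], base_all)
        X_all = np.asarray(X_all)
        miss = base_all["id"].isin(
            self.missing_mask.index[self.missing_mask]).values
        if not miss.any():      # no missing cases: the marginal estimate
            miss = np.ones(len(base_all), dtype=bool)
        mu_all = np.exp(X_all @ gee.params.values)   # shifted scale
        mu = mu_all[miss]
        X = X_all[miss]
        V = gee.cov_params().values
        grad_miss = (mu[:, None] * X).mean(axis=0)
        if X_all.shape[1] > 2:
            grad_marg = (mu_all[:, None] * X_all).mean(axis=0)
            grad = grad_miss - grad_marg
        else:
            grad = grad_miss
        se = float(np.sqrt(grad @ V @ grad))
        scores = mu - 1.0 + self.spec.analysis_offset
        return scores, se

    def _finalize(self, method: str, values: np.ndarray, se: float,
                  extrapolated: bool = False,
                  relative_se_mode: str = "model") -> ReplacementEstimate:
        mean = float(np.mean(values))
        z = self._z()
        est = ReplacementEstimate(
            method=method, mean=mean, ci=(mean - z * se, mean + z * se),
            se=se, cohort_mean=self._cohort_mean(values),
            n_missing=self.n_missing, extrapolated=extrapolated)
        if method != "MCAR":
            mcar = self.mcar()
            est.relative_pct, est.verdict = compare_to_mcar(est, mcar)
            est.relative_ci = self._relative_ci(est, mcar)
        else:
            est.relative_pct, est.verdict = 0.0, "equivalent"
            est.relative_ci = (0.0, 0.0)
        return est

    def _cohort_mean(self, replacement_values: np.ndarray) -> float:
        observed = self.wide["post"][~self.missing_mask].values
        if self.n_missing == 0:
            return float(observed.mean())
        return float((observed.sum() + np.sum(replacement_values))
                     / self.cohort.n)

    def _relative_ci(self, est: ReplacementEstimate,
                     mcar: ReplacementEstimate) -> tuple[float, float]:
        """Seeded parametric Monte Carlo over the two means' normal
        approximations (independence assumed)."""
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(9,)))
        a = rng.normal(est.mean, max(est.se, 1e-12), self.mc_draws)
        b = rng.normal(mcar.mean, max(mcar.se, 1e-12), self.mc_draws)
        rel = 100.0 * (a - b) / b
        lo, hi = np.percentile(rel, [100 * self.alpha / 2,
                                     100 * (1 - self.alpha / 2)])
        return float(lo), float(hi)

    # ------------------------------------------------------------- methods
    def mcar(self) -> ReplacementEstimate:
        """Completer-only (time-only) replacement: the marginal post mean."""
        if self._mcar is None:
            fitted = self._fit_gee(())
            scores, se = self._predict_missing(fitted)
            self._mcar = self._finalize("MCAR", scores, se)
        return self._mcar

    def mar(self, covariates) -> ReplacementEstimate:
        """Covariate-adjusted (MAR) replacement.

        ``covariates`` is a list of short names; empty reduces to MCAR.
        """
        covariates = tuple(covariates)
        if not covariates:
            est = self.mcar()
            return ReplacementEstimate(
                method="MAR:()", mean=est.mean, ci=est.ci, se=est.se,
                cohort_mean=est.cohort_mean, relative_pct=0.0,
                relative_ci=(0.0, 0.0), verdict="equivalent",
                n_missing=est.n_missing)
        extrapolated = self._check_support(covariates)
        fitted = self._fit_gee(covariates)
        scores, se = self._predict_missing(fitted)
        return self._finalize("MAR:" + "+".join(covariates), scores, se,
                              extrapolated=extrapolated)

    def _check_support(self, covariates) -> bool:
        """Flag covariate levels present among missing cases only."""
        d = self.cohort.design_frame().set_index("id")
        miss_ids = self.missing_mask.index[self.missing_mask]
        comp_ids = self.missing_mask.index[~self.missing_mask]
        for cov in covariates:
            col = "modules_completed" if cov == "completion" else cov
            if d[col].nunique() <= 10:  # categorical-ish
                unseen = set(d.loc[miss_ids, col]) - set(d.loc[comp_ids, col])
                if unseen:
                    import warnings
                    warnings.warn(
                        f"extrapolating over unobserved level(s) {unseen} "
                        f"of {cov!r}", stacklevel=3)
                    return True
        return False

    def locf(self) -> ReplacementEstimate:
        """Last observation carried forward (mid if present, else pre)."""
        carried = self.wide["mid"].where(self.wide["mid"].notna(),
                                         self.wide["pre"])
        values = carried[self.missing_mask].values.astype(float)
        if self.n_missing == 0:  # nothing to replace: the observed mean
            values = self.wide["post"].values.astype(float)
        se = self._bootstrap_se(values, stream=3)
        return self._finalize("LOCF", values, se)

    def bocf(self) -> ReplacementEstimate:
        """Baseline observation carried forward."""
        values = self.wide["pre"][self.missing_mask].values.astype(float)
        if self.n_missing == 0:
            values = self.wide["post"].values.astype(float)
        se = self._bootstrap_se(values, stream=4)
        return self._finalize("BOCF", values, se)

    def _bootstrap_se(self, values: np.ndarray, stream: int,
                      n_boot: int = 1000) -> float:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,)))
        idx = rng.integers(0, len(values), size=(n_boot, len(values)))
        return float(np.std(values[idx].mean(axis=1), ddof=1))

    def mi(self, config: MIConfig | None = None) -> ReplacementEstimate:
        """Multiple imputation on the log scale, Rubin-pooled.

        The imputation model regresses the log shifted post score on the
        configured covariates plus the log shifted earlier scores among
        completers; each imputation draws the residual variance and
        coefficients from their posterior, then posterior-predictive values
        for the missing cases.
        """
        config = config or MIConfig(seed=self.seed)
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(5,)))
        X_all, y_obs, obs_mask = self._imputation_design(config)
        X_obs = X_all[obs_mask.values]
        X_mis = X_all[self.missing_mask.values]
        n, k = X_obs.shape
        if n <= k + 2:
            raise ValueError("too few completers for the imputation model")
        XtX_inv = np.linalg.pinv(X_obs.T @ X_obs)
        beta_hat = XtX_inv @ X_obs.T @ y_obs
        resid = y_obs - X_obs @ beta_hat
        dof = n - k
        s2 = float(resid @ resid) / dof
        chol = np.linalg.cholesky(XtX_inv + 1e-12 * np.eye(k))
        means, variances = [], []
        for _ in range(config.m):
            sigma2 = s2 * dof / rng.chisquare(dof)
            beta = beta_hat + np.sqrt(sigma2) * chol @ rng.standard_normal(k)
            z = X_mis @ beta + np.sqrt(sigma2) * rng.standard_normal(len(X_mis))
            scores = np.exp(z) - 1.0 + self.spec.analysis_offset
            scores = np.clip(scores, self.spec.minimum, self.spec.maximum)
            means.append(float(np.mean(scores)))
            variances.append(float(np.var(scores, ddof=1) / len(scores)))
        qbar = float(np.mean(means))
        wbar = float(np.mean(variances))
        b = float(np.var(means, ddof=1))
        total = wbar + (1 + 1 / config.m) * b
        se = float(np.sqrt(total))
        # Rubin degrees of freedom; normal when between-variance is tiny
        if b > 0:
            df = (config.m - 1) * (1 + wbar / ((1 + 1 / config.m) * b)) ** 2
            tcrit = stats.t.ppf(1 - self.alpha / 2, df)
        else:
            tcrit = self._z()
        label = "MI:" + "+".join(config.covariates) + f"(m={config.m})"
        # the pooled point estimate stands in for every missing case when
        # forming the cohort-level mean
        est = ReplacementEstimate(
            method=label, mean=qbar, ci=(qbar - tcrit * se, qbar + tcrit * se),
            se=se, cohort_mean=self._cohort_mean(
                np.full(self.n_missing, qbar)),
            n_missing=self.n_missing)
        est.mi_between = b
        est.mi_within = wbar
        mcar = self.mcar()
        est.relative_pct, est.verdict = compare_to_mcar(est, mcar)
        est.relative_ci = self._relative_ci(est, mcar)
        return est

    def _imputation_design(self, config: MIConfig):
        d = self.cohort.design_frame().set_index("id")
        wide = self.wide
        off = self.spec.analysis_offset
        parts = [np.ones(len(wide))]
        names = ["const"]
        if config.use_pre:
            parts.append(np.log(wide["pre"].values - off + 1.0))
            names.append("log_pre")
        if config.use_mid and wide["mid"].notna().all():
            parts.append(np.log(wide["mid"].values - off + 1.0))
            names.append("log_mid")
        for cov in config.covariates:
            if cov == "completion":
                for lvl in (1, 2, 3, 4):
                    parts.append((d["modules_completed"].values == lvl)
                                 .astype(float))
                    names.append(f"completed_{lvl}")
            else:
                parts.append(d[cov].values.astype(float))
                names.append(cov)
        X = np.column_stack(parts)
        obs_mask = ~self.missing_mask
        y_obs = np.log(wide["post"][obs_mask].values - off + 1.0)
        return X, y_obs, obs_mask

    def mlm(self, covariates=("completion",)) -> ReplacementEstimate:
        """Mixed-model replacement: random intercepts and time slopes.

        Fits a linear mixed model to the log shifted scores over all three
        timepoints; missing cases are predicted at week 8 from the fixed
        effects plus their own estimated random intercept and slope (their
        pre and mid assessments identify the subject-level trajectory).
        """
        covariates = tuple(covariates)
        m = self.cohort.measurements
        m = m[m["scale"] == self.scale].copy()
        m["z"] = np.log(m["score"] - self.spec.analysis_offset + 1.0)
        m["time"] = m["timepoint"].map(
            {tp: WEEKS[tp] / WEEKS["post"] for tp in WEEKS})
        d = self.cohort.design_frame().set_index("id")
        m = m.join(d.drop(columns=["missing"]), on="id")
        frags = " + ".join(COVARIATE_TERMS.get(c, c) for c in covariates)
        formula = f"z ~ time * ({frags})" if covariates else "z ~ time"
        import statsmodels.formula.api as smf
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, m, groups=m["id"], re_formula="~time")
            try:
                res = model.fit(method="lbfgs", maxiter=200)
            except Exception as err:  # pragma: no cover - surfaced to caller
                raise RuntimeError(f"mixed model failed to converge: {err}")
        # fixed-effect prediction at week 8 for missing cases
        miss_ids = self.missing_mask.index[self.missing_mask]
        if not len(miss_ids):
            miss_ids = self.missing_mask.index
        base = m[(m["timepoint"] == "pre") & m["id"].isin(miss_ids)].copy()
        base = base.assign(time=1.0)
        fe_names = [p for p in res.fe_params.index]
        (X,) = patsy.build_design_matrices(
            [model.data.design_info], base)
        fixed = np.asarray(X) @ res.fe_params.values
        re = res.random_effects
        blup = np.array([
            re[i].iloc[0] + (re[i].iloc[1] if len(re[i]) > 1 else 0.0)
            for i in base["id"]])
        z_pred = fixed + blup
        scores = np.exp(z_pred) - 1.0 + self.spec.analysis_offset
        scores = np.clip(scores, self.spec.minimum, self.spec.maximum)
        se = float(np.std(scores, ddof=1) / np.sqrt(len(scores)))
        return self._finalize("MLM:" + "+".join(covariates), scores, se)

    # --------------------------------------------------------------- table
    def table(self, mi_config: MIConfig | None = None) -> pd.DataFrame:
        """Full comparison table (a Tables 8-10 analogue for this scale)."""
        pre_missing = self.wide["pre"][self.missing_mask]
        rows = [{
            "method": "pretreatment scores of missing cases",
            "mean": float(pre_missing.mean()),
            "ci_lower": float(pre_missing.mean()
                              - self._z() * pre_missing.sem()),
            "ci_upper": float(pre_missing.mean()
                              + self._z() * pre_missing.sem()),
            "relative_pct": np.nan, "relative_lower": np.nan,
            "relative_upper": np.nan, "verdict": "",
        }]
        estimates = [self.mcar()]
        for cov in ("age", "gender", "employment", "relationship",
                    "education"):
            estimates.append(self.mar([cov]))
        own_pre = f"{self.scale}_pre"
        for cov in ("gad7_pre", "phq9_pre", "k10_pre", "comorbid"):
            estimates.append(self.mar([cov]))
        estimates.append(self.mar(["completion"]))
        estimates.append(self.mar(["completion", own_pre]))
        estimates.append(self.mlm(("completion",)))
        estimates.append(self.mi(mi_config or MIConfig(
            covariates=("completion", own_pre), seed=self.seed)))
        estimates.append(self.locf())
        estimates.append(self.bocf())
        for est in estimates:
            rows.append({
                "method": est.method, "mean": est.mean,
                "ci_lower": est.ci[0], "ci_upper": est.ci[1],
                "relative_pct": est.relative_pct,
                "relative_lower": est.relative_ci[0],
                "relative_upper": est.relative_ci[1],
                "verdict": est.verdict,
            })
        return pd.DataFrame(rows)


# -------------------------------------------------------------- functions
def replace_mcar(cohort: Cohort, scale: str, **kw) -> ReplacementEstimate:
    return ReplacementAnalysis(cohort, scale, **kw).mcar()


def replace_mar(cohort: Cohort, scale: str, covariates, **kw) -> ReplacementEstimate:
    return ReplacementAnalysis(cohort, scale, **kw).mar(covariates)


def replace_locf(cohort: Cohort, scale: str, **kw) -> ReplacementEstimate:
    return ReplacementAnalysis(cohort, scale, **kw).locf()


def replace_bocf(cohort: Cohort, scale: str, **kw) -> ReplacementEstimate:
    return ReplacementAnalysis(cohort, scale, **kw).bocf()


def replace_mi(cohort: Cohort, scale: str, mi_config: MIConfig | None = None,
               **kw) -> ReplacementEstimate:
    return ReplacementAnalysis(cohort, scale, **kw).mi(mi_config)


def replace_mlm(cohort: Cohort, scale: str, covariates=("completion",),
                **kw) -> ReplacementEstimate:
    return ReplacementAnalysis(cohort, scale, **kw).mlm(covariates)
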