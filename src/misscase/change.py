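"""Population-averaged models of proportional symptom change.

Symptom scores are modelled with generalized estimating equations using a
log link, gamma variance function and an unstructured working correlation,
so the time coefficient ``exp(beta_time)`` is the multiplicative pre-to-post
ratio of expected scores and ``100 * (1 - ratio)`` is the percent symptom
change.  Moderation is expressed through time-by-covariate interactions.

Scores enter on the shifted analysis scale ``offset score + 1`` (the log
link is undefined at zero); ratios are scale-free so no back-shift is needed
for rates, while marginal means are reported after subtracting the shift.

Only observed assessments contribute; a missing posttreatment row is simply
absent (no replacement happens here).  The default model uses the pre and
post assessments only; with two timepoints the unstructured working
correlation degenerates to a single free parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf

from .cohort import Cohort, WEEKS
from .missingness import CATEGORICAL, LEVEL_LABELS
from .scales import get_scale

__all__ = [
    "SymptomChangeModel", "SymptomChangeResults", "ChangeModelSpec",
    "StabilityEstimate", "change_rate", "fit_change_model", "stability_icc",
]

#: Covariate short name -> (design column, patsy fragment) used in formulas.
COVARIATE_TERMS = {
    "completion": "C(modules_completed, Treatment(reference=5))",
    "age": "age",
    "gender": "gender",
    "employment": "employment",
    "relationship": "relationship",
    "education": "education",
    "comorbid": "comorbid",
    "phq9_pre": "phq9_pre",
    "gad7_pre": "gad7_pre",
    "k10_pre": "k10_pre",
}


def change_rate(ratio: float) -> float:
    """Percent symptom change implied by a pre->post ratio.

    ``100 * (1 - ratio)``; negative values mean worsening.
    """
    if np.any(np.asarray(ratio) <= 0):
        raise ValueError("ratio must be > 0")
    return 100.0 * (1.0 - ratio)


@dataclass
class ChangeModelSpec:
    """Link/variance/correlation choices for the change model."""

    link: str = "log"
    family: str = "gamma"
    working_correlation: str = "unstructured"
    timepoints: tuple = ("pre", "post")

    def build_family(self):
        if self.family != "gamma" or self.link != "log":
            raise ValueError("only the gamma family with log link is supported")
        return sm.families.Gamma(sm.families.links.Log())

    def build_cov_struct(self):
        kind = self.working_correlation
        if kind == "unstructured" and len(self.timepoints) == 2:
            # with two timepoints the unstructured matrix has one free
            # off-diagonal parameter, identical to exchangeable (and much
            # cheaper to estimate)
            kind = "exchangeable"
        return {"unstructured": sm.cov_struct.Unstructured,
                "exchangeable": sm.cov_struct.Exchangeable,
                "independence": sm.cov_struct.Independence,
                }[kind]()


@dataclass
class StabilityEstimate:
    scale: str
    icc: float
    ci: tuple[float, float]
    n_pairs: int


class ChangeModelError(RuntimeError):
    """Estimation failed (non-convergence or degenerate scores)."""


class SymptomChangeModel:
    """GEE model of one scale's change, optionally moderated by a covariate.

    Parameters
    ----------
    cohort : Cohort
    scale : str
        ``"phq9"``, ``"gad7"`` or ``"k10"``.
    covariate : str, optional
        Short covariate name; adds a main effect and a time interaction.
        ``None`` fits the time-only (sample average) model.
    spec : ChangeModelSpec, optional
        Three-timepoint fits use ``timepoints=("pre", "mid", "post")`` with
        time as the week fraction (0, 0.5, 1).
    """

    def __init__(self, cohort: Cohort, scale: str, covariate: str | None = None,
                 spec: ChangeModelSpec | None = None):
        self.cohort = cohort
        self.scale = scale.lower()
        self.covariate = covariate
        self.spec = spec or ChangeModelSpec()
        self.scale_spec = get_scale(self.scale)
        self.data = self._long_frame()

    def _long_frame(self) -> pd.DataFrame:
        m = self.cohort.measurements
        m = m[(m["scale"] == self.scale)
              & m["timepoint"].isin(self.spec.timepoints)].copy()
        m["y"] = m["score"] - self.scale_spec.analysis_offset + 1.0
        if (m["y"] <= 0).any():
            raise ChangeModelError("nonpositive shifted scores")
        if m.loc[m["timepoint"] == "pre", "y"].nunique() == 1 and \
                m["y"].nunique() == 1:
            raise ChangeModelError("scores are constant; nothing to model")
        m["time"] = m["timepoint"].map(
            {tp: WEEKS[tp] / WEEKS["post"] for tp in self.spec.timepoints})
        m["time_index"] = m["timepoint"].map(
            {tp: i for i, tp in enumerate(self.spec.timepoints)})
        d = self.cohort.design_frame().set_index("id")
        m = m.join(d.drop(columns=["missing"]), on="id")
        # deterministic row order: participants x timepoints
        return m.sort_values(["id", "time_index"]).reset_index(drop=True)

    @property
    def formula(self) -> str:
        if self.covariate is None:
            return "y ~ time"
        frag = COVARIATE_TERMS.get(self.covariate, self.covariate)
        return f"y ~ time * ({frag})"

    def fit(self, maxiter: int = 60) -> "SymptomChangeResults":
        model = smf.gee(
            self.formula, groups="id", data=self.data,
            time=self.data["time_index"].values.astype(int),
            family=self.spec.build_family(),
            cov_struct=self.spec.build_cov_struct())
        try:
            res = model.fit(maxiter=maxiter)
        except (np.linalg.LinAlgError, ValueError) as err:
            raise ChangeModelError(f"GEE estimation failed: {err}") from err
        if not getattr(res, "converged", True):
            raise ChangeModelError(
                f"GEE did not converge within {maxiter} iterations "
                f"(params so far: {dict(res.params.round(4))})")
        return SymptomChangeResults(self, res)


@dataclass
class SymptomChangeResults:
    """Fitted proportional-change model (robust/sandwich standard errors)."""

    model: SymptomChangeModel
    gee_results: object
    alpha: float = 0.05

    # ----------------------------------------------------------- coefficients
    @property
    def params(self) -> pd.Series:
        return self.gee_results.params

    @property
    def cov(self) -> pd.DataFrame:
        return self.gee_results.cov_params()

    @property
    def exp_beta_time(self) -> float:
        """Pre->post expected-score ratio for the reference group."""
        return float(np.exp(self.params["time"]))

    @property
    def sample_change_rate(self) -> float:
        return change_rate(self.exp_beta_time)

    def interaction_multipliers(self) -> pd.DataFrame:
        """exp(beta) of each time-by-covariate interaction with P values."""
        idx = [c for c in self.params.index if c.startswith("time:")]
        out = pd.DataFrame({
            "exp_beta": np.exp(self.params[idx]),
            "se": self.gee_results.bse[idx],
            "pvalue": self.gee_results.pvalues[idx],
        })
        out.index = [c.removeprefix("time:") for c in idx]
        return out

    def interaction_pvalue(self) -> float:
        """Joint Wald P of all time-by-covariate terms (moderation test)."""
        idx = [c for c in self.params.index if c.startswith("time:")]
        if not idx:
            raise ValueError("time-only model has no interaction")
        c = self.params[idx].values
        V = self.cov.loc[idx, idx].values
        statistic = float(c @ np.linalg.solve(V, c))
        return float(stats.chi2.sf(statistic, len(idx)))

    # ------------------------------------------------------------- subgroups
    def _covariate_levels(self):
        cov = self.model.covariate
        col = "modules_completed" if cov == "completion" else cov
        return sorted(self.model.data[col].unique(), reverse=True)

    def _log_ratio_vector(self, level) -> np.ndarray:
        """Contrast picking beta_time + the level's interaction term."""
        x = np.zeros(len(self.params))
        names = list(self.params.index)
        x[names.index("time")] = 1.0
        for i, name in enumerate(names):
            if name.startswith("time:") and (
                    f"[T.{level}]" in name or f"[T.{float(level)}]" in name):
                x[i] = 1.0
        return x

    def subgroup_change_rates(self, levels=None) -> pd.DataFrame:
        """Per-level change rates with delta-method CIs on the log scale.

        For a categorical covariate each row is
        ``rate = 100 * (1 - exp(beta_time + beta_interaction))``; for a
        continuous covariate a single per-unit row is returned,
        ``100 * (exp(beta_interaction) - 1)`` (the per-unit percent change of
        the ratio).
        """
        cov = self.model.covariate
        if cov is None:
            raise ValueError("fit with a covariate to get subgroup rates")
        z = stats.norm.ppf(1 - self.alpha / 2)
        rows = []
        if cov in CATEGORICAL:
            known = self._covariate_levels()
            levels = known if levels is None else list(levels)
            unknown = [lv for lv in levels if lv not in known]
            if unknown:
                raise KeyError(f"unknown level(s) {unknown} for {cov!r}")
            for level in levels:
                x = self._log_ratio_vector(level)
                lr = float(x @ self.params.values)
                se = float(np.sqrt(x @ self.cov.values @ x))
                label = LEVEL_LABELS.get(cov, {}).get(level, f"{cov}={level}")
                rows.append({
                    "level": label, "ratio": np.exp(lr),
                    "rate": change_rate(np.exp(lr)),
                    "rate_lower": change_rate(np.exp(lr + z * se)),
                    "rate_upper": change_rate(np.exp(lr - z * se)),
                })
        else:
            name = [c for c in self.params.index if c.startswith("time:")][0]
            b, se = self.params[name], self.gee_results.bse[name]
            rows.append({
                "level": f"{cov} (per unit)", "ratio": np.exp(b),
                "rate": 100.0 * (np.exp(b) - 1.0),
                "rate_lower": 100.0 * (np.exp(b - z * se) - 1.0),
                "rate_upper": 100.0 * (np.exp(b + z * se) - 1.0),
            })
        return pd.DataFrame(rows).set_index("level")

    def marginal_means(self) -> pd.DataFrame:
        """Model-based mean scores by timepoint (and subgroup), evaluated at
        the observed covariate distribution and reported on the raw scale."""
        data = self.model.data
        rows = []
        groups = [None]
        cov = self.model.covariate
        if cov in CATEGORICAL:
            groups = self._covariate_levels()
        for tp in self.model.spec.timepoints:
            t = WEEKS[tp] / WEEKS["post"]
            for g in groups:
                sub = data[data["timepoint"] == "pre"].copy()
                if g is not None:
                    col = "modules_completed" if cov == "completion" else cov
                    sub = sub[sub[col] == g]
                sub = sub.assign(time=t)
                pred = self.gee_results.predict(sub)
                mean_shifted = float(np.mean(pred))
                label = (LEVEL_LABELS.get(cov, {}).get(g, f"{cov}={g}")
                         if g is not None else "sample")
                rows.append({
                    "timepoint": tp, "group": label,
                    "mean_score": mean_shifted - 1.0
                    + self.model.scale_spec.analysis_offset,
                })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Proportional symptom change model — {self.model.scale_spec.name}",
            f"  formula: {self.model.formula}  "
            f"(gamma family, log link, {self.model.spec.working_correlation} "
            "working correlation, robust SE)",
            f"  n obs = {int(self.gee_results.nobs)}",
            f"  exp(beta_time) = {self.exp_beta_time:.3f}  "
            f"-> sample change rate {self.sample_change_rate:.1f}%",
        ]
        if self.model.covariate is not None:
            lines.append(f"  moderation P (joint Wald) = "
                         f"{self.interaction_pvalue():.3g}")
            lines.append("")
            lines.append(f"  {'level':<28}{'ratio':>8}{'rate %':>9}{'95% CI':>18}")
            for lvl, row in self.subgroup_change_rates().iterrows():
                lines.append(
                    f"  {lvl:<28}{row['ratio']:>8.3f}{row['rate']:>9.1f}"
                    f"{'(' + format(row['rate_lower'], '.1f') + ', ' + format(row['rate_upper'], '.1f') + ')':>18}")
        return "\n".join(lines)


# ---------------------------------------------------------------- functions
def fit_change_model(cohort: Cohort, scale: str, covariate: str | None = None,
                     spec: ChangeModelSpec | None = None) -> SymptomChangeResults:
    """Fit the proportional-change GEE (module-level convenience)."""
    return SymptomChangeModel(cohort, scale, covariate, spec).fit()


def stability_icc(cohort: Cohort, scale: str, timepoint_a: str = "pre",
                  timepoint_b: str = "mid") -> StabilityEstimate:
    """Two-way consistency intraclass correlation between two timepoints.

    Uses participants observed at both timepoints; ICC(3,1) in the
    Shrout-Fleiss taxonomy.
    """
    wide = cohort.scores_wide(scale)[[timepoint_a, timepoint_b]].dropna()
    if len(wide) < 3:
        raise ValueError("need at least 3 complete pairs for an ICC")
    import pingouin as pg

    long = wide.reset_index().melt(id_vars="id", var_name="time",
                                   value_name="score")
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = pg.intraclass_corr(long, targets="id", raters="time",
                                 ratings="score")
    mask = icc["Type"].isin(["ICC3", "ICC(C,1)"])
    row = icc[mask].iloc[0]
    ci_col = "CI95%" if "CI95%" in icc.columns else "CI95"
    return StabilityEstimate(scale, float(row["ICC"]),
                             (float(row[ci_col][0]), float(row[ci_col][1])),
                             len(wide))
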