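"""Logistic models of posttreatment missing-case status.

The binary outcome is ``missing`` (1 = no posttreatment assessment).
Predictors are referred to by short names (``completion``, ``age``,
``gender``, ``employment``, ``relationship``, ``education``, ``comorbid``,
``phq9_pre``, ``gad7_pre``, ``k10_pre``) which expand to patsy terms;
module completion is categorical with full completers (5 of 5) as the
reference, and baseline scores enter on the offset-adjusted scale.

The model surface follows statsmodels conventions: build a
:class:`MissingnessModel` from a cohort, call :meth:`~MissingnessModel.fit`,
and read estimates, odds ratios, pseudo-R2 and classification metrics off
the returned :class:`MissingnessResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats

import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort import Cohort

__all__ = [
    "MissingnessModel", "MissingnessResults", "ClassificationMetrics",
    "RiskEstimate", "WaldTest", "fit_univariate", "fit_multivariate",
    "nagelkerke_r2", "odds_to_probability", "probability_to_odds_ratio",
    "relative_risk_increment", "auroc_rank", "delong_ci",
    "test_missingness_interaction",
]

#: Formula fragments per predictor short name.
PREDICTOR_TERMS = {
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

#: Predictors treated as categorical when building risk tables.
CATEGORICAL = {"completion", "gender", "employment", "relationship",
               "education", "comorbid"}

#: Human-readable level labels for risk tables.
LEVEL_LABELS = {
    "completion": {1: "completed 1 of 5", 2: "completed 2 of 5",
                   3: "completed 3 of 5", 4: "completed 4 of 5",
                   5: "completed all modules"},
    "gender": {1: "female", 0: "male"},
    "employment": {1: "employed", 0: "not employed"},
    "relationship": {1: "in a relationship", 0: "not in a relationship"},
    "education": {1: "tertiary education", 0: "no tertiary education"},
    "comorbid": {1: "comorbid", 0: "not comorbid"},
}


class SingleClassOutcomeError(ValueError):
    """Both outcome classes must be present to fit a dropout model."""


class NoContrastError(ValueError):
    """A predictor is constant across participants."""


# ----------------------------------------------------------------- helpers
def nagelkerke_r2(null_loglik: float, fitted_loglik: float, n: int) -> float:
    """Nagelkerke pseudo-R2: Cox-Snell rescaled by its attainable maximum.

    ``R2 = [1 - exp(2 (L0 - L1) / n)] / [1 - exp(2 L0 / n)]`` with L0/L1 the
    null and fitted log-likelihoods.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if fitted_loglik < null_loglik - 1e-8:
        raise ValueError("fitted log-likelihood below null log-likelihood")
    cox_snell = 1.0 - np.exp(2.0 * (null_loglik - fitted_loglik) / n)
    max_cs = 1.0 - np.exp(2.0 * null_loglik / n)
    if max_cs <= 0:
        return 0.0
    return float(min(max(cox_snell / max_cs, 0.0), 1.0))


def odds_to_probability(odds_ratio: float, reference_probability: float) -> float:
    """Probability implied by an odds ratio applied to a reference probability.

    ``p = q*OR / (1 + q*OR)`` with ``q`` the reference odds.
    """
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be > 0")
    if not 0 < reference_probability < 1:
        raise ValueError("reference_probability must be in (0, 1)")
    q = reference_probability / (1.0 - reference_probability)
    return q * odds_ratio / (1.0 + q * odds_ratio)


def probability_to_odds_ratio(probability: float, reference_probability: float) -> float:
    """Inverse of :func:`odds_to_probability`."""
    if not 0 < probability < 1:
        raise ValueError("probability must be in (0, 1)")
    if not 0 < reference_probability < 1:
        raise ValueError("reference_probability must be in (0, 1)")
    q = reference_probability / (1.0 - reference_probability)
    return (probability / (1.0 - probability)) / q


def relative_risk_increment(subgroup_probability: float,
                            sample_probability: float) -> float:
    """Percent change of a subgroup's missingness probability relative to the
    sample average: ``100 * (p_sub - p_avg) / p_avg``."""
    for p in (subgroup_probability, sample_probability):
        if not 0 < p < 1:
            raise ValueError("probabilities must be in (0, 1)")
    return 100.0 * (subgroup_probability - sample_probability) / sample_probability


def auroc_rank(scores, labels) -> float:
    """AUROC via the rank (Mann-Whitney) formulation.

    Probability that a randomly chosen positive (missing) case scores above a
    randomly chosen negative, ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise SingleClassOutcomeError("need both classes for AUROC")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def delong_ci(scores, labels, alpha: float = 0.05) -> tuple[float, float, float]:
    """AUROC with its DeLong (placement-value) confidence interval."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    n1, n0 = len(pos), len(neg)
    auc = auroc_rank(scores, labels)
    # placement values: for each positive, fraction of negatives it beats
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n0 for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / n1 for q in neg])
    var = np.var(v10, ddof=1) / n1 + np.var(v01, ddof=1) / n0
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return auc, max(auc - half, 0.0), min(auc + half, 1.0)


def _firth_logit(y: np.ndarray, X: np.ndarray, maxiter: int = 100,
                 tol: float = 1e-8):
    """Firth-penalized logistic regression (Jeffreys-prior score adjustment).

    Keeps estimates finite under (quasi-)separation.  Returns (params, cov).
    """
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(maxiter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        XtW = X.T * w
        info = XtW @ X
        cov = np.linalg.pinv(info)
        # hat diagonal of W^1/2 X (X'WX)^-1 X' W^1/2
        h = np.einsum("ij,jk,ik->i", X * w[:, None], cov, X)
        score = X.T @ (y - p + h * (0.5 - p))
        step = cov @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1 - p)
    cov = np.linalg.pinv((X.T * w) @ X)
    return beta, cov


# ------------------------------------------------------------- dataclasses
@dataclass
class ClassificationMetrics:
    """Confusion-matrix summary of a fitted dropout model at a threshold."""

    sensitivity: float          # true-positive rate, % (positive = missing)
    specificity: float          # true-negative rate, %
    accuracy: float             # overall, %
    auroc: float
    auroc_ci: tuple[float, float]
    threshold: float
    threshold_rule: str
    confusion: tuple[int, int, int, int] = (0, 0, 0, 0)  # tp, fn, tn, fp
    degenerate: bool = False    # all predictions in one class at threshold


@dataclass
class RiskEstimate:
    """Missingness probability for a subgroup or per predictor unit."""

    label: str
    probability_pct: float
    ci_pct: tuple[float, float]
    rri_pct: float              # relative to the sample-average probability


@dataclass
class WaldTest:
    statistic: float
    df: int
    pvalue: float
    term: str = ""
    flagged: bool = False
    note: str = ""


# ------------------------------------------------------------------- model
class MissingnessModel:
    """Logistic regression of posttreatment missing-case status.

    Parameters
    ----------
    cohort : Cohort
        Source data; the design frame is built internally.
    predictors : list of str
        Short predictor names (see :data:`PREDICTOR_TERMS`), or raw patsy
        terms for anything not in the registry.
    comorbid_reference : {"none", "comorbid"}
        Which comorbidity level is the reference category; with
        ``"comorbid"`` the indicator is flipped so the odds ratio describes
        the non-comorbid group.
    """

    def __init__(self, cohort: Cohort, predictors: list[str],
                 comorbid_reference: str = "none",
                 extra_terms: list[str] | None = None):
        if not predictors and not extra_terms:
            raise ValueError("at least one predictor is required")
        self.cohort = cohort
        self.predictors = list(predictors)
        self.comorbid_reference = comorbid_reference
        data = cohort.design_frame()
        if comorbid_reference == "comorbid":
            data = data.assign(comorbid=1 - data["comorbid"])
        elif comorbid_reference != "none":
            raise ValueError("comorbid_reference must be 'none' or 'comorbid'")
        y = data["missing"].values.astype(float)
        if len(np.unique(y)) < 2:
            raise SingleClassOutcomeError("outcome has a single class")
        for name in self.predictors:
            col = {"completion": "modules_completed"}.get(name, name)
            if col in data.columns and data[col].nunique() < 2:
                raise NoContrastError(f"predictor {name!r} is constant")
        terms = [PREDICTOR_TERMS.get(name, name) for name in self.predictors]
        terms += list(extra_terms or [])
        self.formula = "missing ~ " + " + ".join(terms)
        self.data = data
        ydm, X = patsy.dmatrices(self.formula, data, return_type="dataframe")
        self.endog = ydm.values.ravel()
        self.exog = X
        self.design_info = X.design_info

    # mapping from predictor short name -> design columns (minus intercept)
    def term_columns(self, name: str) -> list[str]:
        frag = PREDICTOR_TERMS.get(name, name)
        cols = []
        for term, sl in self.design_info.term_name_slices.items():
            if term == frag:
                cols.extend(self.exog.columns[sl])
        if not cols:  # fall back: substring match (interaction terms)
            cols = [c for c in self.exog.columns if frag in c and c != "Intercept"]
        return cols

    def fit(self, method: str = "auto", maxiter: int = 200) -> "MissingnessResults":
        """Fit by maximum likelihood; fall back to a Firth-penalized fit when
        separation leaves the MLE unbounded (``method="auto"``)."""
        X = self.exog.values
        y = self.endog
        separation = False
        used = "mle"
        params = cov = None
        if method in ("auto", "mle"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.Logit(y, X).fit(disp=0, maxiter=maxiter)
                params, cov = res.params, res.cov_params()
                if not res.mle_retvals.get("converged", True) or \
                        np.max(np.abs(params)) > 15:
                    separation = True
            except (PerfectSeparationError, np.linalg.LinAlgError):
                separation = True
            if separation and method == "mle":
                raise PerfectSeparationError(
                    "separation detected; refit with method='firth'")
        if method == "firth" or (separation and method == "auto"):
            params, cov = _firth_logit(y, X)
            used = "firth"
        eta = X @ params
        fitted = 1.0 / (1.0 + np.exp(-eta))
        eps = 1e-12
        llf = float(np.sum(y * np.log(fitted + eps)
                           + (1 - y) * np.log(1 - fitted + eps)))
        pbar = y.mean()
        llnull = float(len(y) * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar)))
        return MissingnessResults(
            model=self, params=pd.Series(params, index=self.exog.columns),
            cov=pd.DataFrame(np.asarray(cov), index=self.exog.columns,
                             columns=self.exog.columns),
            llf=llf, llnull=llnull, method=used, separation=separation,
            fittedvalues=pd.Series(fitted, index=self.data["id"].values),
        )


@dataclass
class MissingnessResults:
    """Fitted dropout model: coefficients, odds ratios, pseudo-R2, metrics."""

    model: MissingnessModel
    params: pd.Series
    cov: pd.DataFrame
    llf: float
    llnull: float
    method: str
    separation: bool
    fittedvalues: pd.Series
    alpha: float = 0.05

    # ------------------------------------------------------------ estimates
    @property
    def nobs(self) -> int:
        return len(self.fittedvalues)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    @property
    def wald_chi2(self) -> pd.Series:
        return (self.params / self.bse) ** 2

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(stats.chi2.sf(self.wald_chi2, 1), index=self.params.index)

    @property
    def nagelkerke_r2(self) -> float:
        return nagelkerke_r2(self.llnull, self.llf, self.nobs)

    def conf_int(self) -> pd.DataFrame:
        z = stats.norm.ppf(1 - self.alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse,
             "upper": self.params + z * self.bse})

    def odds_ratios(self) -> pd.DataFrame:
        """Per-term odds ratios with Wald confidence intervals."""
        ci = self.conf_int()
        out = pd.DataFrame({
            "odds_ratio": np.exp(self.params),
            "lower": np.exp(ci["lower"]),
            "upper": np.exp(ci["upper"]),
            "wald_chi2": self.wald_chi2,
            "pvalue": self.pvalues,
        })
        return out.drop(index="Intercept", errors="ignore")

    def term_wald_test(self, name: str) -> WaldTest:
        """Joint Wald chi-square for all design columns of one predictor."""
        cols = self.model.term_columns(name)
        if not cols:
            raise KeyError(f"term {name!r} not in model")
        c = self.params[cols].values
        V = self.cov.loc[cols, cols].values
        try:
            stat = float(c @ np.linalg.solve(V, c))
            flagged = False
            note = ""
        except np.linalg.LinAlgError:
            stat, flagged, note = float("nan"), True, "singular covariance"
        df = len(cols)
        return WaldTest(stat, df, float(stats.chi2.sf(stat, df)), term=name,
                        flagged=flagged, note=note)

    # -------------------------------------------------------- classification
    def classification_metrics(self, threshold_rule: str = "prevalence",
                               ) -> ClassificationMetrics:
        """Confusion metrics and AUROC (rank formulation; DeLong CI).

        ``threshold_rule='prevalence'`` classifies as missing when the
        predicted probability reaches the sample missingness rate — weak
        predictors then still split the sample; ``'fixed'`` uses 0.5.
        """
        y = self.model.endog.astype(bool)
        p = self.fittedvalues.values
        if threshold_rule == "prevalence":
            thr = float(y.mean())
        elif threshold_rule == "fixed":
            thr = 0.5
        else:
            raise ValueError("threshold_rule must be 'prevalence' or 'fixed'")
        pred = p >= thr
        tp = int(np.sum(pred & y)); fn = int(np.sum(~pred & y))
        tn = int(np.sum(~pred & ~y)); fp = int(np.sum(pred & ~y))
        sens = 100.0 * tp / (tp + fn) if tp + fn else 0.0
        spec = 100.0 * tn / (tn + fp) if tn + fp else 0.0
        acc = 100.0 * (tp + tn) / len(y)
        auc, lo, hi = delong_ci(p, y, alpha=self.alpha)
        degenerate = (tp + fp == 0) or (tn + fn == 0)
        if degenerate:
            warnings.warn("all predictions fall in one class at this threshold",
                          stacklevel=2)
        return ClassificationMetrics(sens, spec, acc, auc, (lo, hi), thr,
                                     threshold_rule, (tp, fn, tn, fp), degenerate)

    # ---------------------------------------------------------------- risks
    def risk_estimates(self) -> list[RiskEstimate]:
        """Per-level probabilities (categorical) or per-unit relative change
        (continuous) for each predictor, relative to the sample average."""
        out = []
        sample_p = float(self.model.endog.mean())
        data = self.model.data
        for name in self.model.predictors:
            if name in CATEGORICAL:
                col = "modules_completed" if name == "completion" else name
                for level in sorted(data[col].unique(), reverse=True):
                    eta_cols, x = self._level_design(name, col, level)
                    eta = float(x @ self.params.values)
                    se = float(np.sqrt(x @ self.cov.values @ x))
                    z = stats.norm.ppf(1 - self.alpha / 2)
                    p = 1 / (1 + np.exp(-eta))
                    lo = 1 / (1 + np.exp(-(eta - z * se)))
                    hi = 1 / (1 + np.exp(-(eta + z * se)))
                    label = LEVEL_LABELS.get(name, {}).get(level, f"{name}={level}")
                    out.append(RiskEstimate(
                        label, 100 * p, (100 * lo, 100 * hi),
                        relative_risk_increment(p, sample_p)))
            else:
                xbar = float(data[name].mean())
                p0 = self._prob_at(name, xbar)
                p1 = self._prob_at(name, xbar + 1.0)
                rri = 100.0 * (p1 - p0) / p0
                # CI by mapping the coefficient CI through the same transform
                cols = self.model.term_columns(name)
                ci = self.conf_int().loc[cols[0]]
                rlo, rhi = sorted(
                    100.0 * (self._prob_at(name, xbar + 1.0, shift)
                             - p0) / p0
                    for shift in (ci["lower"] - self.params[cols[0]],
                                  ci["upper"] - self.params[cols[0]]))
                out.append(RiskEstimate(f"{name} (per unit)", 100 * p0,
                                        (rlo, rhi), rri))
        return out

    def _level_design(self, name: str, col: str, level):
        """Design row for one categorical level at the model's reference for
        everything else (univariate use)."""
        x = np.zeros(len(self.params))
        x[list(self.params.index).index("Intercept")] = 1.0
        cols = self.model.term_columns(name)
        for c in cols:
            if f"[T.{level}]" in c or f"[T.{float(level)}]" in c:
                x[list(self.params.index).index(c)] = 1.0
        return cols, x

    def _prob_at(self, name: str, value: float, coef_shift: float = 0.0) -> float:
        cols = self.model.term_columns(name)
        x = self.params.copy()
        eta = x["Intercept"] + (x[cols[0]] + coef_shift) * value
        return float(1 / (1 + np.exp(-eta)))

    # -------------------------------------------------------------- summary
    def summary(self) -> str:
        lines = [
            "Posttreatment missing-case logistic model",
            f"  formula: {self.model.formula}",
            f"  n={self.nobs}  method={self.method}"
            + ("  [separation: Firth penalty]" if self.separation else ""),
            f"  log-likelihood {self.llf:.1f} (null {self.llnull:.1f})",
            f"  Nagelkerke R2 = {100 * self.nagelkerke_r2:.1f}%",
            "",
            f"  {'term':<45}{'OR':>10}{'95% CI':>22}{'Wald chi2':>11}{'P':>11}",
        ]
        for term, row in self.odds_ratios().iterrows():
            lines.append(
                f"  {term:<45}{row['odds_ratio']:>10.3f}"
                f"{'(' + format(row['lower'], '.3f') + ', ' + format(row['upper'], '.3f') + ')':>22}"
                f"{row['wald_chi2']:>11.1f}  {row['pvalue']:>9.2g}")
        return "\n".join(lines)


# ------------------------------------------------------------ conveniences
def fit_univariate(cohort: Cohort, predictor: str, **kwargs):
    """Single-predictor dropout model.

    Returns ``(results, classification_metrics, risk_estimates)``.
    """
    res = MissingnessModel(cohort, [predictor], **kwargs).fit()
    return res, res.classification_metrics(), res.risk_estimates()


def _wald_p(cohort: Cohort, current: list[str], candidate: str | None,
            comorbid_reference: str) -> tuple[float, "MissingnessResults"]:
    terms = current + ([candidate] if candidate else [])
    res = MissingnessModel(cohort, terms,
                           comorbid_reference=comorbid_reference).fit()
    if candidate is None:
        return np.nan, res
    return res.term_wald_test(candidate).pvalue, res


def fit_multivariate(cohort: Cohort, candidates: list[str],
                     selection_rule: str = "stepwise", p_enter: float = 0.01,
                     p_remove: float = 0.01, comorbid_reference: str = "none"):
    """Multivariate dropout model with Wald-based variable selection.

    ``selection_rule`` is ``"stepwise"``, ``"forward"``, ``"backward"`` or
    ``"all"`` (a dict of the three, side by side).  Entry and removal use the
    conservative P = .01 threshold; candidates are scanned in their given
    order, ties broken by that order.
    """
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    if selection_rule == "all":
        return {rule: fit_multivariate(cohort, candidates, rule, p_enter,
                                       p_remove, comorbid_reference)
                for rule in ("stepwise", "forward", "backward")}
    if selection_rule not in ("stepwise", "forward", "backward"):
        raise ValueError(f"unknown selection rule {selection_rule!r}")

    def forward_pass(selected):
        best = (None, p_enter)
        for cand in candidates:
            if cand in selected:
                continue
            p, _ = _wald_p(cohort, selected, cand, comorbid_reference)
            if p < best[1]:
                best = (cand, p)
        return best[0]

    def backward_pass(selected):
        if not selected:
            return None
        res = MissingnessModel(cohort, selected,
                               comorbid_reference=comorbid_reference).fit()
        worst = (None, p_remove)
        for term in selected:
            p = res.term_wald_test(term).pvalue
            if p >= worst[1]:
                worst = (term, p)
        return worst[0]

    if selection_rule == "backward":
        selected = list(candidates)
        while True:
            drop = backward_pass(selected)
            if drop is None:
                break
            selected.remove(drop)
    else:
        selected: list[str] = []
        while True:
            add = forward_pass(selected)
            if add is None:
                break
            selected.append(add)
            if selection_rule == "stepwise":
                while True:
                    drop = backward_pass(selected)
                    if drop is None or drop == add:
                        break
                    selected.remove(drop)
    if not selected:
        raise ValueError("no candidate met the entry criterion")
    res = MissingnessModel(cohort, selected,
                           comorbid_reference=comorbid_reference).fit()
    res.selected_predictors = selected
    res.selection_rule = selection_rule
    return res


def test_missingness_interaction(cohort: Cohort, predictor_a: str,
                                 predictor_b: str,
                                 comorbid_reference: str = "none") -> WaldTest:
    """Joint Wald test of the a-by-b product term added to the additive model."""
    term_a = PREDICTOR_TERMS.get(predictor_a, predictor_a)
    term_b = PREDICTOR_TERMS.get(predictor_b, predictor_b)
    data = cohort.design_frame()
    for name in (predictor_a, predictor_b):
        col = {"completion": "modules_completed"}.get(name, name)
        if col in data.columns and data[col].nunique() < 2:
            raise NoContrastError(f"predictor {name!r} is constant")
    model = MissingnessModel(
        cohort, [predictor_a, predictor_b],
        comorbid_reference=comorbid_reference,
        extra_terms=[f"{term_a}:{term_b}"])
    res = model.fit()
    inter_cols = [c for c in res.params.index if ":" in c]
    c = res.params[inter_cols].values
    V = res.cov.loc[inter_cols, inter_cols].values
    try:
        statistic = float(c @ np.linalg.solve(V, c))
        flagged, note = False, ""
    except np.linalg.LinAlgError:
        statistic, flagged, note = float("nan"), True, "collinear product term"
    df = len(inter_cols)
    pvalue = float(stats.chi2.sf(statistic, df)) if np.isfinite(statistic) else float("nan")
    return WaldTest(statistic, df, pvalue,
                    term=f"{predictor_a}:{predictor_b}", flagged=flagged,
                    note=note)
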