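"""End-to-end pipeline: simulate or load a cohort, fit every stage, and
write table/figure analogues plus a machine-readable results document.

Outputs (in the run directory):

* ``missingness_univariate.csv`` — one row per predictor level (odds
  ratios, pseudo-R2, classification metrics);
* ``missingness_multivariate.csv`` — the selected model per rule;
* ``change_<scale>.csv`` — moderation tables (exp(beta), P, rate, CI);
* ``replacement_<scale>.csv`` — replacement-model comparison tables;
* ``replication.csv`` / ``randomization.csv`` — cross-validation outputs;
* ``figure_completion.csv`` / ``figure_baseline.csv`` — observation
  probability and predicted-outcome trend curves;
* ``power_*.csv`` — optional Monte-Carlo power curves;
* ``results.json`` — everything above at full precision, plus the seed and
  a hash of the configuration.

Report tables round percentages to integers, means to one decimal and odds
ratios/coefficients to three decimals; ``results.json`` keeps full
precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .change import SymptomChangeModel, stability_icc
from .cohort import Cohort
from .config import SimConfig
from .crossval import randomization_check, replicate_univariate, split_cohort
from .missingness import MissingnessModel, fit_multivariate
from .power import (PowerConfig, extract_pilot_parameters,
                    power_curve_change, power_curve_missingness)
from .replacement import MIConfig, ReplacementAnalysis
from .scales import SCALES
from .simulate import simulate

logger = logging.getLogger("misscase")

DEFAULT_PREDICTORS = ("age", "gender", "employment", "relationship",
                      "education", "gad7_pre", "phq9_pre", "k10_pre",
                      "comorbid", "completion")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "simulate"                  # "simulate" | "files"
    sim: SimConfig = field(default_factory=SimConfig)
    input_dir: str | None = None            # for mode="files"
    scales: tuple = ("phq9", "gad7", "k10")
    predictors: tuple = DEFAULT_PREDICTORS
    change_covariates: tuple = ("completion", "own_baseline", "relationship")
    replacement_covariates: tuple = (
        "age", "gender", "own_baseline", "completion")
    include_mlm: bool = True
    mi_m: int = 20
    do_crossval: bool = True
    do_power: bool = False
    power_replications: int = 100
    out_dir: str = "misscase_run"
    seed: int = 0
    verbosity: str = "INFO"

    def validate(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ValueError("mode must be 'simulate' or 'files'")
        if self.mode == "files":
            if not self.input_dir or not Path(self.input_dir).exists():
                raise FileNotFoundError(
                    f"input directory {self.input_dir!r} does not exist")
        unknown = set(self.scales) - set(SCALES)
        if unknown:
            raise ValueError(f"unknown scales {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        for key in ("scales", "predictors", "change_covariates",
                    "replacement_covariates"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = SimConfig.from_dict(d["sim"])
        for key in ("scales", "predictors", "change_covariates",
                    "replacement_covariates"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResults:
    """In-memory bundle of every fitted stage of one run."""

    cohort: Cohort
    config: RunConfig
    missingness: dict = field(default_factory=dict)      # predictor -> results
    multivariate: object = None
    change: dict = field(default_factory=dict)           # (scale, cov) -> results
    replacement_tables: dict = field(default_factory=dict)
    replication: pd.DataFrame | None = None
    randomization: pd.DataFrame | None = None
    power: dict = field(default_factory=dict)
    stability: dict = field(default_factory=dict)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="records"))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in sorted(obj.items(),
                                                        key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(run_config: RunConfig) -> PipelineResults:
    """Execute every stage and write all outputs to the run directory."""
    rc = run_config
    rc.validate()
    out = Path(rc.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=getattr(logging, rc.verbosity.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    chash = rc.config_hash()
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, rc.verbosity.upper(), logging.INFO))
    logger.info("run config hash %s seed %s", chash, rc.seed)
    results_doc: dict = {"seed": rc.seed, "config_hash": chash,
                         "config": rc.to_dict()}
    timings: dict = {}

    def write(df, path, **kw):
        _write_table(df, path, config_hash=chash, **kw)

    def stage(name):
        t0 = time.time()
        logger.info("stage %s start", name)

        def done():
            timings[name] = round(time.time() - t0, 3)
            logger.info("stage %s done in %.2fs", name, timings[name])
        return done

    try:
        done = stage("input")
        if rc.mode == "simulate":
            cohort = simulate(rc.sim, seed=rc.seed)
        else:
            cohort = Cohort.from_csv(rc.input_dir)
        done()
        res = PipelineResults(cohort=cohort, config=rc)

        # ---------------------------------------------------- missingness
        done = stage("missingness")
        uni_rows = []
        sample_p = float(cohort.missing_post.mean())
        uni_rows.append({
            "predictor": "sample average", "level": "", "pvalue": np.nan,
            "odds_ratio": np.nan, "or_lower": np.nan, "or_upper": np.nan,
            "nagelkerke_r2_pct": np.nan,
            "probability_pct": 100 * sample_p,
            "prob_lower": np.nan, "prob_upper": np.nan, "rri_pct": np.nan,
            "sensitivity_pct": np.nan, "specificity_pct": np.nan,
            "accuracy_pct": np.nan, "auroc": np.nan,
            "auroc_lower": np.nan, "auroc_upper": np.nan,
        })
        for pred in rc.predictors:
            fit = MissingnessModel(cohort, [pred]).fit()
            res.missingness[pred] = fit
            cm = fit.classification_metrics()
            ors = fit.odds_ratios()
            first = ors.iloc[0]
            risks = fit.risk_estimates()
            for i, risk in enumerate(risks):
                uni_rows.append({
                    "predictor": pred, "level": risk.label,
                    "pvalue": first["pvalue"] if i == 0 else np.nan,
                    "odds_ratio": first["odds_ratio"] if i == 0 else np.nan,
                    "or_lower": first["lower"] if i == 0 else np.nan,
                    "or_upper": first["upper"] if i == 0 else np.nan,
                    "nagelkerke_r2_pct": 100 * fit.nagelkerke_r2 if i == 0 else np.nan,
                    "probability_pct": risk.probability_pct,
                    "prob_lower": risk.ci_pct[0], "prob_upper": risk.ci_pct[1],
                    "rri_pct": risk.rri_pct,
                    "sensitivity_pct": cm.sensitivity if i == 0 else np.nan,
                    "specificity_pct": cm.specificity if i == 0 else np.nan,
                    "accuracy_pct": cm.accuracy if i == 0 else np.nan,
                    "auroc": cm.auroc if i == 0 else np.nan,
                    "auroc_lower": cm.auroc_ci[0] if i == 0 else np.nan,
                    "auroc_upper": cm.auroc_ci[1] if i == 0 else np.nan,
                })
        uni = pd.DataFrame(uni_rows)
        write(uni, out / "missingness_univariate.csv",
                     pct_cols=["probability_pct", "prob_lower", "prob_upper",
                               "sensitivity_pct", "specificity_pct",
                               "accuracy_pct"],
                     mean_cols=["rri_pct", "nagelkerke_r2_pct"],
                     coef_cols=["odds_ratio", "or_lower", "or_upper",
                                "auroc", "auroc_lower", "auroc_upper"])
        results_doc["missingness_univariate"] = uni
        try:
            multi = fit_multivariate(cohort, list(rc.predictors),
                                     selection_rule="stepwise")
            res.multivariate = multi
            mdf = multi.odds_ratios().reset_index(names="term")
            mdf["nagelkerke_r2_pct"] = 100 * multi.nagelkerke_r2
            mdf["selected"] = ", ".join(multi.selected_predictors)
            write(mdf, out / "missingness_multivariate.csv",
                         coef_cols=["odds_ratio", "lower", "upper"])
            results_doc["missingness_multivariate"] = mdf
        except ValueError as err:
            logger.warning("multivariate selection skipped: %s", err)
        done()

        # --------------------------------------------------------- change
        done = stage("change")
        for scale in rc.scales:
            rows = []
            time_only = SymptomChangeModel(cohort, scale).fit()
            res.change[(scale, None)] = time_only
            rows.append({
                "covariate": "sample average", "level": "",
                "pvalue": np.nan, "exp_beta": time_only.exp_beta_time,
                "rate_pct": time_only.sample_change_rate,
                "rate_lower": np.nan, "rate_upper": np.nan,
            })
            covs = tuple(c if c != "own_baseline" else f"{scale}_pre"
                         for c in rc.change_covariates)
            for cov in covs:
                fitted = SymptomChangeModel(cohort, scale, cov).fit()
                res.change[(scale, cov)] = fitted
                inter = fitted.interaction_multipliers()
                p_joint = fitted.interaction_pvalue()
                table = fitted.subgroup_change_rates()
                for i, (lvl, row) in enumerate(table.iterrows()):
                    rows.append({
                        "covariate": cov, "level": lvl,
                        "pvalue": p_joint if i == 0 else np.nan,
                        "exp_beta": row["ratio"],
                        "rate_pct": row["rate"],
                        "rate_lower": row["rate_lower"],
                        "rate_upper": row["rate_upper"],
                    })
            df = pd.DataFrame(rows)
            write(df, out / f"change_{scale}.csv",
                         pct_cols=["rate_pct", "rate_lower", "rate_upper"],
                         coef_cols=["exp_beta"])
            results_doc[f"change_{scale}"] = df
            res.stability[scale] = stability_icc(cohort, scale)
        done()

        # ---------------------------------------------------- replacement
        done = stage("replacement")
        for scale in rc.scales:
            ra = ReplacementAnalysis(cohort, scale, seed=rc.seed)
            estimates = [ra.mcar()]
            covs = tuple(c if c != "own_baseline" else f"{scale}_pre"
                         for c in rc.replacement_covariates)
            for cov in covs:
                estimates.append(ra.mar([cov]))
            estimates.append(ra.mar(["completion", f"{scale}_pre"]))
            if rc.include_mlm:
                estimates.append(ra.mlm(("completion",)))
            estimates.append(ra.mi(MIConfig(
                m=rc.mi_m, covariates=("completion", f"{scale}_pre"),
                seed=rc.seed)))
            estimates.append(ra.locf())
            estimates.append(ra.bocf())
            rows = [{
                "method": e.method, "mean": e.mean,
                "ci_lower": e.ci[0], "ci_upper": e.ci[1],
                "relative_pct": e.relative_pct,
                "relative_lower": e.relative_ci[0],
                "relative_upper": e.relative_ci[1],
                "verdict": e.verdict, "cohort_mean": e.cohort_mean,
            } for e in estimates]
            df = pd.DataFrame(rows)
            res.replacement_tables[scale] = df
            write(df, out / f"replacement_{scale}.csv",
                         mean_cols=["mean", "ci_lower", "ci_upper",
                                    "cohort_mean"],
                         pct_cols=["relative_pct", "relative_lower",
                                   "relative_upper"])
            results_doc[f"replacement_{scale}"] = df
        done()

        # ------------------------------------------------------- crossval
        if rc.do_crossval:
            done = stage("crossval")
            plan = split_cohort(cohort, k=5, seed=rc.seed)
            res.randomization = randomization_check(cohort, plan)
            res.replication = replicate_univariate(cohort, plan,
                                                   ("completion",))
            write(plan.to_frame(), out / "split_plan.csv")
            write(res.randomization.reset_index(),
                         out / "randomization.csv", coef_cols=["chi2", "pvalue"])
            write(res.replication, out / "replication.csv",
                         pct_cols=["probability_pct", "ci_lower", "ci_upper"],
                         mean_cols=["rri_pct"])
            results_doc["randomization"] = res.randomization.reset_index()
            results_doc["replication"] = res.replication
            done()

        # ---------------------------------------------------------- power
        if rc.do_power:
            done = stage("power")
            plan = split_cohort(cohort, k=5, seed=rc.seed)
            pilot_cohort = cohort.subset(plan.subsample_ids(1))
            pilot = extract_pilot_parameters(pilot_cohort, rc.scales[0])
            curve_c = power_curve_change(PowerConfig(
                n=int((~pilot_cohort.missing_post).sum()),
                effects=(0.0, 3.0, 4.5, 6.0, 7.5),
                replications=rc.power_replications, pilot=pilot,
                seed=rc.seed))
            curve_m = power_curve_missingness(PowerConfig(
                n=pilot_cohort.n,
                effects=(0.0, 1.8, 2.7, 3.6, 4.5, 5.4),
                replications=rc.power_replications,
                reference_rate=float(cohort.missing_post.mean()),
                seed=rc.seed))
            res.power = {"change": curve_c, "missingness": curve_m}
            for name, curve in res.power.items():
                df = curve.to_frame()
                write(df, out / f"power_{name}.csv")
                results_doc[f"power_{name}"] = {
                    "curve": df,
                    "minimal_detectable_effect": curve.minimal_detectable_effect,
                }
            done()

        # -------------------------------------------------------- figures
        done = stage("figures")
        fig = export_figure_data(res)
        for name, df in fig.items():
            write(df, out / f"figure_{name}.csv")
            results_doc[f"figure_{name}"] = df
        done()

        results_doc["stability_icc"] = {
            s: {"icc": e.icc, "ci": list(e.ci)} for s, e in res.stability.items()}
        logger.info("stage timings: %s", timings)
        (out / "results.json").write_text(
            json.dumps(_jsonable(results_doc), indent=2, sort_keys=True))
        (out / "config.json").write_text(
            json.dumps(_jsonable(rc.to_dict()), indent=2, sort_keys=True))
        logger.info("pipeline complete: %s", out)
        return res
    except Exception:
        logger.exception("pipeline failed; partial outputs kept in %s", out)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def export_figure_data(results: PipelineResults) -> dict[str, pd.DataFrame]:
    """Plot-ready observation-probability and outcome-trend curves.

    ``completion``: per module-completion level, the probability of being
    observed at posttreatment (1 - missingness probability) and the
    model-predicted posttreatment score of the first analysed scale.
    ``baseline``: the same pair over the observed baseline-severity range.
    """
    scale = results.config.scales[0]
    own_pre = f"{scale}_pre"
    out = {}
    m_fit = results.missingness.get("completion")
    c_fit = results.change.get((scale, "completion"))
    if m_fit is None or c_fit is None:
        raise KeyError("completion fits unavailable for figure export")
    rows = []
    risks = {r.label: r for r in m_fit.risk_estimates()}
    means = c_fit.marginal_means()
    post = means[means["timepoint"] == "post"].set_index("group")
    for label, risk in risks.items():
        rows.append({
            "level": label,
            "observed_prob": 1 - risk.probability_pct / 100,
            "observed_lower": 1 - risk.ci_pct[1] / 100,
            "observed_upper": 1 - risk.ci_pct[0] / 100,
            "predicted_post": post.loc[label, "mean_score"]
            if label in post.index else np.nan,
        })
    out["completion"] = pd.DataFrame(rows)

    m_fit = results.missingness.get(own_pre)
    c_fit = results.change.get((scale, own_pre))
    if m_fit is not None and c_fit is not None:
        d = results.cohort.design_frame()
        grid = np.arange(int(d[own_pre].min()), int(d[own_pre].max()) + 1)
        b = m_fit.params
        eta = b["Intercept"] + b[m_fit.model.term_columns(own_pre)[0]] * grid
        p_missing = 1 / (1 + np.exp(-eta))
        cb = c_fit.params
        inter = [c for c in cb.index if c.startswith("time:")][0]
        main = [c for c in cb.index
                if c not in ("Intercept", "time") and not c.startswith("time:")][0]
        post_pred = np.exp(cb["Intercept"] + cb[main] * grid
                           + cb["time"] + cb[inter] * grid) - 1.0 \
            + c_fit.model.scale_spec.analysis_offset
        out["baseline"] = pd.DataFrame({
            "baseline_score": grid,
            "observed_prob": 1 - p_missing,
            "predicted_post": post_pred,
        })
    return out


def _write_table(df: pd.DataFrame, path: Path, pct_cols=(), mean_cols=(),
                 coef_cols=(), config_hash: str | None = None) -> None:
    """Write with the report rounding conventions; each file carries the
    config hash as a leading comment line."""
    df = df.copy()
    for col in pct_cols:
        if col in df:
            df[col] = df[col].round(0)
    for col in mean_cols:
        if col in df:
            df[col] = df[col].round(1)
    for col in coef_cols:
        if col in df:
            df[col] = df[col].round(3)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, index=False)
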