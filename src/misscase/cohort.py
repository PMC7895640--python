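"""Cohort container: participants plus a participant-by-scale-by-time grid.

A :class:`Cohort` bundles two tidy tables:

``participants``
    one row per participant: ``id, age, gender, employment, relationship,
    education, modules_completed`` (binary covariates coded 0/1; gender 1 =
    female; modules_completed in 1..5).

``measurements``
    long format: ``id, scale, timepoint, score`` with timepoints ``pre``
    (week 0), ``mid`` (week 4) and ``post`` (week 8).  A missing
    posttreatment assessment is represented by the *absence* of the post
    rows, never by a sentinel score, and is a participant-level event: either
    all three scales are observed at post or none is.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .scales import SCALES, get_scale, offset_scale

TIMEPOINTS = ("pre", "mid", "post")
WEEKS = {"pre": 0, "mid": 4, "post": 8}

PARTICIPANT_COLUMNS = [
    "id", "age", "gender", "employment", "relationship", "education",
    "modules_completed",
]
MEASUREMENT_COLUMNS = ["id", "scale", "timepoint", "score"]

#: Clinical comorbidity thresholds: anxiety and depression jointly elevated.
COMORBID_GAD7_THRESHOLD = 8
COMORBID_PHQ9_THRESHOLD = 10


class CohortValidationError(ValueError):
    """The cohort tables violate the schema or an invariant."""


@dataclass
class Cohort:
    participants: pd.DataFrame
    measurements: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.participants = self.participants.reset_index(drop=True)
        self.measurements = self.measurements.reset_index(drop=True)
        self.validate()

    # ------------------------------------------------------------------ basics
    @property
    def n(self) -> int:
        return len(self.participants)

    def validate(self) -> None:
        for col in PARTICIPANT_COLUMNS:
            if col not in self.participants.columns:
                raise CohortValidationError(f"participants missing column {col!r}")
        for col in MEASUREMENT_COLUMNS:
            if col not in self.measurements.columns:
                raise CohortValidationError(f"measurements missing column {col!r}")
        ids = self.participants["id"]
        if ids.duplicated().any():
            raise CohortValidationError("duplicate participant ids")
        mc = self.participants["modules_completed"]
        if ((mc < 1) | (mc > 5)).any():
            raise CohortValidationError("modules_completed outside 1..5")
        m = self.measurements
        bad_tp = ~m["timepoint"].isin(TIMEPOINTS)
        if bad_tp.any():
            row = int(m.index[bad_tp][0])
            raise CohortValidationError(
                f"measurements row {row}, column 'timepoint': "
                f"invalid value {m.loc[row, 'timepoint']!r}"
            )
        bad_scale = ~m["scale"].isin(SCALES)
        if bad_scale.any():
            row = int(m.index[bad_scale][0])
            raise CohortValidationError(
                f"measurements row {row}, column 'scale': "
                f"invalid value {m.loc[row, 'scale']!r}"
            )
        if m["score"].isna().any():
            row = int(m.index[m["score"].isna()][0])
            raise CohortValidationError(
                f"measurements row {row}, column 'score': missing value "
                "(absent assessments must be dropped rows, not blanks)"
            )
        for key, spec in SCALES.items():
            sc = m.loc[m["scale"] == key, "score"]
            out = (sc < spec.minimum) | (sc > spec.maximum)
            if out.any():
                row = int(sc.index[out][0])
                raise CohortValidationError(
                    f"measurements row {row}, column 'score': {spec.name} score "
                    f"{m.loc[row, 'score']} outside [{spec.minimum}, {spec.maximum}]"
                )
        # pre must be observed for every participant on every scale
        pre = m[m["timepoint"] == "pre"]
        have_pre = pre.groupby("id")["scale"].nunique()
        missing_pre = set(ids) - set(have_pre[have_pre == len(SCALES)].index)
        if missing_pre:
            raise CohortValidationError(
                f"participants without complete pretreatment scores: "
                f"{sorted(missing_pre)[:5]}"
            )
        # posttreatment missingness must be joint across scales
        post = m[m["timepoint"] == "post"]
        nsc = post.groupby("id")["scale"].nunique()
        partial = nsc[(nsc > 0) & (nsc < len(SCALES))]
        if len(partial):
            raise CohortValidationError(
                f"partial posttreatment observation for ids {list(partial.index)[:5]}; "
                "missingness must be a participant-level event"
            )

    # -------------------------------------------------------------- accessors
    def scores_wide(self, scale: str) -> pd.DataFrame:
        """id-indexed frame with columns pre/mid/post (NaN where absent)."""
        m = self.measurements[self.measurements["scale"] == scale.lower()]
        wide = m.pivot(index="id", columns="timepoint", values="score")
        wide = wide.reindex(self.participants["id"])
        for tp in TIMEPOINTS:
            if tp not in wide.columns:
                wide[tp] = np.nan
        return wide[list(TIMEPOINTS)]

    def baseline(self, scale: str) -> pd.Series:
        """Raw pretreatment scores, indexed by participant id."""
        return self.scores_wide(scale)["pre"]

    @property
    def missing_post(self) -> pd.Series:
        """True for participants with no posttreatment assessment."""
        post_ids = set(
            self.measurements.loc[
                self.measurements["timepoint"] == "post", "id"
            ].unique()
        )
        s = ~self.participants["id"].isin(post_ids)
        s.index = self.participants["id"].values
        return s

    @property
    def comorbid(self) -> pd.Series:
        """Baseline comorbidity: GAD-7 >= 8 and PHQ-9 >= 10 (0/1 by id)."""
        gad = self.baseline("gad7")
        phq = self.baseline("phq9")
        return (
            (gad >= COMORBID_GAD7_THRESHOLD) & (phq >= COMORBID_PHQ9_THRESHOLD)
        ).astype(int)

    def design_frame(self) -> pd.DataFrame:
        """Per-participant covariate frame used by the dropout models.

        Columns: demographics, ``modules_completed``, ``comorbid``, the
        offset-adjusted baseline score of each scale (``phq9_pre`` etc.), and
        the binary outcome ``missing`` (1 = no posttreatment assessment).
        """
        df = self.participants.set_index("id").copy()
        df["comorbid"] = self.comorbid
        for key in SCALES:
            spec = get_scale(key)
            df[f"{key}_pre"] = offset_scale(self.baseline(key).values, spec)
        df["missing"] = self.missing_post.astype(int)
        return df.reset_index()

    # --------------------------------------------------------------------- io
    def to_csv(self, directory: str | Path) -> tuple[Path, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        ppath = directory / "participants.csv"
        mpath = directory / "measurements.csv"
        self.participants[PARTICIPANT_COLUMNS].to_csv(ppath, index=False)
        self.measurements[MEASUREMENT_COLUMNS].to_csv(mpath, index=False)
        return ppath, mpath

    @classmethod
    def from_csv(cls, directory: str | Path) -> "Cohort":
        directory = Path(directory)
        participants = pd.read_csv(directory / "participants.csv")
        measurements = pd.read_csv(directory / "measurements.csv")
        return cls(participants, measurements)

    def subset(self, ids) -> "Cohort":
        """Cohort restricted to the given participant ids (order preserved)."""
        ids = pd.Index(ids)
        p = self.participants[self.participants["id"].isin(ids)]
        m = self.measurements[self.measurements["id"].isin(ids)]
        return Cohort(p, m, meta=dict(self.meta))

    def __repr__(self) -> str:  # pragma: no cover
        nmiss = int(self.missing_post.sum())
        return (
            f"<Cohort n={self.n}, missing post={nmiss} "
            f"({100 * nmiss / max(self.n, 1):.1f}%)>"
        )
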