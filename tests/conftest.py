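import numpy as np
import pandas as pd
import pytest

from misscase import Cohort, SimConfig, simulate


def build_cohort(records):
    """Hand-built cohort from a list of participant dicts.

    Each record: ``id``, optional demographics/modules, and per-scale score
    triples ``phq9=(pre, mid, post)`` (post None = missing; mid None = no
    mid assessment).  Unspecified scales copy the PHQ-9 pattern, clipped to
    their own range.
    """
    defaults = dict(age=35.0, gender=1, employment=1, relationship=1,
                    education=0, modules_completed=5)
    participants, measurements = [], []
    for rec in records:
        row = dict(defaults)
        row["id"] = rec["id"]
        for key in defaults:
            if key in rec:
                row[key] = rec[key]
        participants.append(row)
        phq = rec.get("phq9", (10, 8, 6))
        for scale, lo, hi, off in (("phq9", 0, 27, 0), ("gad7", 0, 21, 0),
                                   ("k10", 10, 50, 10)):
            triple = rec.get(scale)
            if triple is None:
                triple = tuple(
                    None if v is None else min(max(v + off, lo), hi)
                    for v in phq)
            for tp, val in zip(("pre", "mid", "post"), triple):
                if val is not None:
                    measurements.append({"id": rec["id"], "scale": scale,
                                         "timepoint": tp, "score": float(val)})
    return Cohort(pd.DataFrame(participants), pd.DataFrame(measurements))


@pytest.fixture(scope="session")
def study_cohort():
    """Full-scale cohort under the default study conditions (n=6701)."""
    return simulate(SimConfig(), seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort for the slower model fits."""
    return simulate(SimConfig(n=1500), seed=7)


@pytest.fixture(scope="session")
def cohort_factory():
    return build_cohort
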