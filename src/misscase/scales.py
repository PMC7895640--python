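"""Symptom-scale definitions and score-offset handling.

Three bounded self-report scales are supported out of the box:

* PHQ-9 (depression), total score 0-27
* GAD-7 (generalized anxiety), total score 0-21
* K-10 (psychological distress), total score 10-50

The K-10 is analysed on a 0-40 range: its constant offset of 10 points is
subtracted before modelling and added back for reporting.  Because the
longitudinal models use a log link, offset-adjusted scores are additionally
shifted by +1 before fitting (``shifted = score - analysis_offset + 1``), so
zero scores remain inside the log/gamma domain; the shift is undone after
prediction.
"""

from __future__ import annotations

from dataclasses import dataclass


class ScaleError(ValueError):
    """A score was outside the scale's bounds, or the scale is unknown."""


@dataclass(frozen=True)
class ScaleSpec:
    """Bounds and offset convention for one symptom scale.

    Parameters
    ----------
    name : str
        Display label, e.g. ``"PHQ-9"``.
    minimum, maximum : int
        Inclusive total-score bounds.
    analysis_offset : int
        Points subtracted before modelling (10 for the K-10, else 0), so
        offset-adjusted scores lie in ``[0, maximum - minimum]``.
    """

    name: str
    minimum: int
    maximum: int
    analysis_offset: int = 0

    def __post_init__(self) -> None:
        if self.minimum >= self.maximum:
            raise ScaleError(f"{self.name}: minimum must be < maximum")
        if self.analysis_offset < 0:
            raise ScaleError(f"{self.name}: analysis_offset must be >= 0")

    @property
    def span(self) -> int:
        return self.maximum - self.minimum


PHQ9 = ScaleSpec("PHQ-9", 0, 27)
GAD7 = ScaleSpec("GAD-7", 0, 21)
K10 = ScaleSpec("K-10", 10, 50, analysis_offset=10)

#: Registry keyed by the identifiers used in measurement files.
SCALES: dict[str, ScaleSpec] = {"phq9": PHQ9, "gad7": GAD7, "k10": K10}


def get_scale(key: str) -> ScaleSpec:
    try:
        return SCALES[key.lower()]
    except KeyError:
        raise ScaleError(f"unknown scale {key!r}; known: {sorted(SCALES)}") from None


def offset_scale(score, spec: ScaleSpec):
    """Map a raw total score onto the analysis range (subtract the offset).

    Accepts scalars or numpy arrays; raises :class:`ScaleError` if any score
    is outside ``[spec.minimum, spec.maximum]``.
    """
    import numpy as np

    arr = np.asarray(score)
    if np.any(arr < spec.minimum) or np.any(arr > spec.maximum):
        raise ScaleError(
            f"{spec.name}: score outside [{spec.minimum}, {spec.maximum}]"
        )
    out = arr - spec.analysis_offset
    return out.item() if np.isscalar(score) or arr.ndim == 0 else out


def restore_scale(offset_score, spec: ScaleSpec):
    """Inverse of :func:`offset_scale`: add the analysis offset back."""
    import numpy as np

    arr = np.asarray(offset_score)
    out = arr + spec.analysis_offset
    if np.any(out < spec.minimum) or np.any(out > spec.maximum):
        raise ScaleError(f"{spec.name}: restored score outside bounds")
    return out.item() if np.isscalar(offset_score) or arr.ndim == 0 else out
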