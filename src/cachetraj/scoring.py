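"""Consensus-criteria cachexia scoring.

Implements the 2011 consensus (Fearon) weight-based criteria as used for a
single baseline assessment and, pointwise, for longitudinal severity
sequences:

* percent weight change is measured against the patient's **maximum weight
  in the 6 months before diagnosis** (the reference weight);
* with BMI >= 20: loss > 5% -> cachexia (2), 1-5% -> pre-cachexia (1),
  < 1% -> no cachexia (0);
* with BMI < 20 the cachexia threshold tightens to loss > 2%.  The
  pre-cachexia band for underweight patients is not specified by the
  criteria text; this implementation mirrors the 1% lower bound, so
  1-2% loss maps to pre-cachexia.

Boundary convention: the printed inequalities are strict, so exactly 5%
loss (or exactly 2% at BMI < 20) is pre-cachexia and exactly 1% loss is
pre-cachexia.

Baseline percent-change outliers are flagged cohort-wide with Tukey fences
(Q1 - 1.5 IQR, Q3 + 1.5 IQR; linear-interpolation quantiles).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .cohort import ExclusionError, PatientSeries

__all__ = [
    "CachexiaCategory", "BaselineAssessment", "SeveritySequence",
    "baseline_percent_change", "classify_consensus", "remove_outliers",
    "encode_sequence",
]


class CachexiaCategory(IntEnum):
    """Ordinal cachexia severity (higher = more severe)."""

    NO_CACHEXIA = 0
    PRE_CACHEXIA = 1
    CACHEXIA = 2


@dataclass
class BaselineAssessment:
    """Single consensus-criteria assessment anchored at diagnosis."""

    patient_id: str
    reference_weight: float   # max pre-diagnosis weight (kg)
    anchor_weight: float      # weight closest in time to diagnosis (kg)
    pct_change: float         # signed percent; negative = loss
    baseline_bmi: float
    category: CachexiaCategory | None = None
    outlier_flag: bool = False


@dataclass
class SeveritySequence:
    """Chronological ordinal severity categories for one patient."""

    patient_id: str
    times: np.ndarray   # day offsets >= 0, ascending
    values: np.ndarray  # categories in {0, 1, 2}, same length

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=int)
        self.values = np.asarray(self.values, dtype=np.int8)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly ascending")

    def __len__(self) -> int:
        return len(self.values)


def classify_consensus(pct_change: float, bmi: float) -> CachexiaCategory:
    """Map a signed percent weight change and BMI to a severity category.

    Parameters
    ----------
    pct_change : float
        Signed percent change from the reference weight; negative = loss.
    bmi : float
        BMI (kg/m^2) at the assessed measurement; must be positive.
    """
    if not (math.isfinite(pct_change) and math.isfinite(bmi)):
        raise ValueError("pct_change and bmi must be finite")
    if bmi <= 0:
        raise ValueError("bmi must be positive")
    loss = -pct_change
    cachexia_threshold = 5.0 if bmi >= 20.0 else 2.0
    if loss > cachexia_threshold:
        return CachexiaCategory.CACHEXIA
    if loss >= 1.0:
        return CachexiaCategory.PRE_CACHEXIA
    return CachexiaCategory.NO_CACHEXIA


def baseline_percent_change(series: PatientSeries,
                            baseline_window_days: int = 183) -> BaselineAssessment:
    """Compute the baseline percent weight change for one patient.

    The reference weight is the maximum weight within ``baseline_window_days``
    before diagnosis; the anchor is the measurement closest in time to
    diagnosis (ties resolved toward the earlier, pre-diagnosis record).
    Returns an assessment with ``category`` unset; classify with
    :func:`classify_consensus` using ``pct_change`` and ``baseline_bmi``.

    Raises
    ------
    ExclusionError
        reason ``"no baseline"`` if there is no pre-diagnosis measurement in
        the window, or ``"no post-diagnosis measurement"``.
    """
    in_window = (series.pre_times >= -baseline_window_days) & (series.pre_times < 0)
    if not np.any(in_window):
        raise ExclusionError("no baseline",
                             f"patient {series.patient_id}: no pre-diagnosis weight "
                             f"within {baseline_window_days} days")
    if series.n_post < 1:
        raise ExclusionError("no post-diagnosis measurement",
                             f"patient {series.patient_id}: no measurement on/after "
                             "diagnosis")
    reference = float(np.max(series.pre_weights[in_window]))

    all_times = np.concatenate([series.pre_times, series.post_times])
    all_weights = np.concatenate([series.pre_weights, series.post_weights])
    all_bmis = np.concatenate([series.pre_bmis, series.post_bmis])
    dist = np.abs(all_times)
    # stable argmin on |t| prefers the earlier (pre-diagnosis) record on ties
    # because pre-diagnosis times sort first in the concatenation
    idx = int(np.argmin(dist))
    anchor = float(all_weights[idx])
    pct = 100.0 * (anchor - reference) / reference
    return BaselineAssessment(
        patient_id=series.patient_id,
        reference_weight=reference,
        anchor_weight=anchor,
        pct_change=pct,
        baseline_bmi=float(all_bmis[idx]),
    )


def remove_outliers(assessments: list[BaselineAssessment]) -> list[BaselineAssessment]:
    """Flag cohort-level percent-change outliers with Tukey fences (in place).

    Values above ``Q3 + 1.5 IQR`` or below ``Q1 - 1.5 IQR`` over all baseline
    percent changes get ``outlier_flag = True``.  With fewer than 4 values no
    flags are set and a warning is emitted.
    """
    values = np.array([a.pct_change for a in assessments], dtype=float)
    if len(values) < 4:
        warnings.warn("fewer than 4 baseline values; outlier fences not applied",
                      stacklevel=2)
        return assessments
    q1, q3 = np.percentile(values, [25, 75])  # linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    for a in assessments:
        a.outlier_flag = bool(a.pct_change > hi or a.pct_change < lo)
    return assessments


def encode_sequence(series: PatientSeries, reference_weight: float) -> SeveritySequence:
    """Encode post-diagnosis measurements as an ordinal severity sequence.

    Every post-diagnosis weight is expressed as percent change against the
    fixed pre-diagnosis reference weight and classified with that
    measurement's BMI, yielding one category per measurement aligned with
    the measurement times.

    Raises
    ------
    ExclusionError
        reason ``"fewer than 2 post-diagnosis measurements"`` (the cohort
        inclusion rule for longitudinal analysis).
    """
    if series.n_post < 2:
        raise ExclusionError("fewer than 2 post-diagnosis measurements",
                             f"patient {series.patient_id}: {series.n_post} "
                             "post-diagnosis measurements")
    if reference_weight <= 0:
        raise ValueError("reference_weight must be positive")
    pct = 100.0 * (series.post_weights - reference_weight) / reference_weight
    cats = [classify_consensus(p, b) for p, b in zip(pct, series.post_bmis)]
    return SeveritySequence(series.patient_id, series.post_times,
                            np.array(cats, dtype=np.int8))
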