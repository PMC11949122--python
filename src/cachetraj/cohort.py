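"""Per-patient longitudinal weight/BMI series and cohort file IO.

A cohort is exchanged as two delimited text files:

``measurements``
    columns ``patient_id, time_days, weight_kg, bmi`` — one row per dated
    weight measurement, with ``time_days`` relative to the cancer diagnosis
    (negative = pre-diagnosis).
``outcomes``
    columns ``patient_id, endpoint, time_days, event`` — one row per
    time-to-event channel (``overall``, ``disability_free``,
    ``hospitalization_free``).

Times are integer days relative to diagnosis throughout; conversion to
years (365.25 d/yr) happens only at reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
ENDPOINTS = ("overall", "disability_free", "hospitalization_free")

MEASUREMENT_COLUMNS = ["patient_id", "time_days", "weight_kg", "bmi"]
OUTCOME_COLUMNS = ["patient_id", "endpoint", "time_days", "event"]


class ExclusionError(Exception):
    """A patient fails an analytic inclusion gate (distinct from a bug).

    Carries a short machine-readable ``reason`` so exclusion logs can mirror
    the cohort inclusion flow.
    """

    def __init__(self, reason: str, message: str | None = None):
        self.reason = reason
        super().__init__(message or reason)


class SchemaError(ValueError):
    """Input file violates the documented schema; lists offending lines."""


@dataclass
class PatientSeries:
    """Dated weight/BMI measurements for one patient, split at diagnosis.

    Attributes
    ----------
    patient_id : str
    pre_times, pre_weights, pre_bmis : ndarray
        Measurements strictly before diagnosis (``time < 0``), ascending.
    post_times, post_weights, post_bmis : ndarray
        Measurements on/after diagnosis (``time >= 0``), strictly ascending.
    event_channels : dict
        endpoint name -> ``(time_days, event)`` with event 1 = observed.
    true_archetype : str or None
        Latent trajectory label; populated only for simulated cohorts.
    covariates : dict
        Optional dichotomous covariates (name -> 0/1).
    """

    patient_id: str
    pre_times: np.ndarray
    pre_weights: np.ndarray
    pre_bmis: np.ndarray
    post_times: np.ndarray
    post_weights: np.ndarray
    post_bmis: np.ndarray
    event_channels: dict = field(default_factory=dict)
    true_archetype: str | None = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("pre", "post"):
            t = np.asarray(getattr(self, f"{name}_times"), dtype=int)
            w = np.asarray(getattr(self, f"{name}_weights"), dtype=float)
            b = np.asarray(getattr(self, f"{name}_bmis"), dtype=float)
            if not (len(t) == len(w) == len(b)):
                raise ValueError(f"{name}-diagnosis arrays have unequal lengths")
            if np.any(w <= 0):
                raise ValueError(f"non-positive weight in {name}-diagnosis series "
                                 f"for patient {self.patient_id}")
            order = np.argsort(t, kind="stable")
            setattr(self, f"{name}_times", t[order])
            setattr(self, f"{name}_weights", w[order])
            setattr(self, f"{name}_bmis", b[order])
        if len(self.post_times) > 1 and np.any(np.diff(self.post_times) <= 0):
            raise ValueError(f"duplicate post-diagnosis timestamps for patient "
                             f"{self.patient_id}")
        for ep, (t, e) in self.event_channels.items():
            if t < 0:
                raise ValueError(f"negative event time for {ep}")
            if e not in (0, 1):
                raise ValueError(f"event indicator must be 0/1 for {ep}")

    @property
    def n_post(self) -> int:
        return len(self.post_times)

    def followup_days(self) -> int:
        """Overall-survival channel time (death or loss to follow-up)."""
        return int(self.event_channels["overall"][0])


def cohort_to_frames(patients: list[PatientSeries]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten a cohort into (measurements, outcomes) data frames."""
    meas_rows, out_rows = [], []
    for p in patients:
        for t, w, b in zip(p.pre_times, p.pre_weights, p.pre_bmis):
            meas_rows.append((p.patient_id, int(t), float(w), float(b)))
        for t, w, b in zip(p.post_times, p.post_weights, p.post_bmis):
            meas_rows.append((p.patient_id, int(t), float(w), float(b)))
        for ep, (t, e) in p.event_channels.items():
            out_rows.append((p.patient_id, ep, int(t), int(e)))
    meas = pd.DataFrame(meas_rows, columns=MEASUREMENT_COLUMNS)
    out = pd.DataFrame(out_rows, columns=OUTCOME_COLUMNS)
    return meas, out


def write_cohort(patients: list[PatientSeries], measurements_path, outcomes_path,
                 truth_path=None) -> None:
    """Serialize a cohort to the two delimited files (plus optional truth table).

    The truth table (patient_id, true_archetype) only exists for simulated
    cohorts and is written separately so analysis inputs stay blind to it.
    """
    meas, out = cohort_to_frames(patients)
    meas.to_csv(measurements_path, index=False)
    out.to_csv(outcomes_path, index=False)
    if truth_path is not None:
        truth = pd.DataFrame(
            [(p.patient_id, p.true_archetype) for p in patients],
            columns=["patient_id", "true_archetype"],
        )
        truth.to_csv(truth_path, index=False)


def _validate_frame(df: pd.DataFrame, columns: list[str], path) -> list[str]:
    problems = []
    missing = [c for c in columns if c not in df.columns]
    if missing:
        problems.append(f"{path}: missing columns {missing}")
        return problems
    return problems


def read_cohort(measurements_path, outcomes_path, truth_path=None) -> list[PatientSeries]:
    """Read and validate a cohort from delimited text.

    Malformed rows are reported with 1-based line numbers (header = line 1)
    and raise :class:`SchemaError` listing every offending line.  Duplicate
    ``(patient_id, time_days)`` measurement rows are resolved by keeping the
    last record, with the collapse count logged.
    """
    meas = pd.read_csv(measurements_path)
    out = pd.read_csv(outcomes_path)
    problems = _validate_frame(meas, MEASUREMENT_COLUMNS, measurements_path)
    problems += _validate_frame(out, OUTCOME_COLUMNS, outcomes_path)
    if problems:
        raise SchemaError("; ".join(problems))

    for col in ("time_days", "weight_kg", "bmi"):
        bad = pd.to_numeric(meas[col], errors="coerce").isna() & meas[col].notna()
        vals = pd.to_numeric(meas[col], errors="coerce")
        for idx in meas.index[bad | vals.isna()]:
            problems.append(f"{measurements_path} line {idx + 2}: non-numeric {col!r}")
        meas[col] = vals
    nonpos = meas.index[meas["weight_kg"] <= 0]
    for idx in nonpos:
        problems.append(f"{measurements_path} line {idx + 2}: non-positive weight_kg")
    bad_ep = out.index[~out["endpoint"].isin(ENDPOINTS)]
    for idx in bad_ep:
        problems.append(f"{outcomes_path} line {idx + 2}: unknown endpoint "
                        f"{out.loc[idx, 'endpoint']!r}")
    bad_ev = out.index[~out["event"].isin([0, 1])]
    for idx in bad_ev:
        problems.append(f"{outcomes_path} line {idx + 2}: event must be 0/1")
    if problems:
        raise SchemaError("; ".join(problems))

    n_before = len(meas)
    meas = meas.drop_duplicates(subset=["patient_id", "time_days"], keep="last")
    n_dup = n_before - len(meas)
    if n_dup:
        logger.info("collapsed %d duplicated (patient_id, time_days) rows "
                    "(kept last record)", n_dup)

    truth = None
    if truth_path is not None:
        tdf = pd.read_csv(truth_path)
        truth = dict(zip(tdf["patient_id"].astype(str), tdf["true_archetype"]))

    patients = []
    out_by_pid = {pid: g for pid, g in out.groupby(out["patient_id"].astype(str))}
    for pid, g in meas.groupby(meas["patient_id"].astype(str), sort=True):
        g = g.sort_values("time_days")
        pre = g[g["time_days"] < 0]
        post = g[g["time_days"] >= 0]
        channels = {}
        if pid in out_by_pid:
            for _, row in out_by_pid[pid].iterrows():
                channels[row["endpoint"]] = (int(row["time_days"]), int(row["event"]))
        patients.append(PatientSeries(
            patient_id=pid,
            pre_times=pre["time_days"].to_numpy(int),
            pre_weights=pre["weight_kg"].to_numpy(float),
            pre_bmis=pre["bmi"].to_numpy(float),
            post_times=post["time_days"].to_numpy(int),
            post_weights=post["weight_kg"].to_numpy(float),
            post_bmis=post["bmi"].to_numpy(float),
            event_channels=channels,
            true_archetype=None if truth is None else truth.get(pid),
        ))
    return patients
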