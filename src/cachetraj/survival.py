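"""Survival stratification metrics: KM, log-rank, Cox, IPCW time-dependent AUC.

Kaplan-Meier estimation, the log-rank test and Cox proportional-hazards
fits (Efron tie handling) are delegated to ``lifelines``.  The
inverse-probability-of-censoring-weighted (IPCW) cumulative/dynamic AUC is
implemented here:

    cases    i : T_i <= t and event, weight w_i = 1 / G(T_i^-)
    controls j : T_j > t,            weight v_j = 1 / G(t)

    AUC(t) = sum_ij w_i v_j [ 1(m_i > m_j) + 1/2 1(m_i = m_j) ]
             / ( sum_i w_i * sum_j v_j )

where G is the Kaplan-Meier estimator of the censoring distribution and m
the marker (binary markers are handled by the tie term).  G is evaluated
with a left limit at case event times, the standard convention avoiding a
zero weight at the jump of G.  With no censoring G == 1 and the estimator
reduces exactly to the plain case/control concordance.

Confidence bands and marker comparisons use seeded patient-level percentile
bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .cohort import DAYS_PER_YEAR

__all__ = ["KMCurve", "AUCSeries", "km_estimate", "logrank_test", "cox_fit",
           "censor_survival", "ipcw_auc", "auc_series", "compare_markers",
           "DAYS_PER_MONTH"]

DAYS_PER_MONTH = DAYS_PER_YEAR / 12.0


@dataclass
class KMCurve:
    """Right-continuous product-limit step function."""

    times: np.ndarray       # jump locations, ascending, starting at 0
    survival: np.ndarray    # S(times[k]), right-continuous
    median: float           # first t with S(t) <= 0.5; nan if never reached

    def at(self, t, left: bool = False) -> np.ndarray:
        """Evaluate S(t) (or the left limit S(t-) with ``left=True``)."""
        side = "left" if left else "right"
        idx = np.searchsorted(self.times, np.asarray(t), side=side) - 1
        idx = np.clip(idx, 0, len(self.times) - 1)
        out = self.survival[idx]
        return out if np.ndim(t) else float(out)


@dataclass
class AUCSeries:
    """IPCW AUC over a monthly horizon grid with bootstrap bands."""

    endpoint: str
    marker: str
    horizons_months: np.ndarray
    auc: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_boot: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "endpoint": self.endpoint, "marker": self.marker,
            "horizon_months": self.horizons_months, "auc": self.auc,
            "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
        })


def _km(times, events) -> KMCurve:
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, float), np.asarray(events, int))
    sf = kmf.survival_function_
    t = sf.index.to_numpy(float)
    s = sf.iloc[:, 0].to_numpy(float)
    if t[0] != 0.0:
        t = np.insert(t, 0, 0.0)
        s = np.insert(s, 0, 1.0)
    med = kmf.median_survival_time_
    return KMCurve(times=t, survival=s,
                   median=float(med) if np.isfinite(med) else float("nan"))


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimate of the event-time survival function."""
    if len(np.asarray(times)) == 0:
        raise ValueError("need at least one record")
    return _km(times, events)


def censor_survival(times, events) -> KMCurve:
    """KM estimate of the censoring distribution (event indicator inverted)."""
    events = np.asarray(events, int)
    return _km(times, 1 - events)


def logrank_test(times, events, groups):
    """Unweighted log-rank test across >= 2 groups.

    Returns ``(chi2, df, p)`` with df = number of groups - 1.
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("log-rank requires at least 2 non-empty groups")
    res = multivariate_logrank_test(np.asarray(times, float), groups,
                                    np.asarray(events, int))
    df = len(uniq) - 1
    return float(res.test_statistic), df, float(res.p_value)


@dataclass
class CoxResult:
    summary: pd.DataFrame       # coef, HR, CI bounds, p per covariate
    concordance: float
    n_events: int
    model: CoxPHFitter = field(repr=False, default=None)

    def hazard_ratio(self, name: str) -> float:
        return float(self.summary.loc[name, "hazard_ratio"])


def cox_fit(df: pd.DataFrame, duration_col: str = "time",
            event_col: str = "event", covariates: list[str] | None = None) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties) with Harrell concordance.

    ``df`` holds one row per patient with duration, event and dichotomized
    covariate columns.  Warns when events < 10 x covariates.  Non-convergence
    surfaces as a ``ConvergenceError`` from lifelines with its diagnostics.
    """
    covariates = covariates or [c for c in df.columns
                                if c not in (duration_col, event_col)]
    n_events = int(df[event_col].sum())
    if n_events < 10 * len(covariates):
        warnings.warn(f"only {n_events} events for {len(covariates)} covariates "
                      "(< 10 per covariate)", stacklevel=2)
    cph = CoxPHFitter()
    cph.fit(df[[duration_col, event_col] + covariates], duration_col=duration_col,
            event_col=event_col)
    s = cph.summary
    summary = pd.DataFrame({
        "coef": s["coef"],
        "hazard_ratio": s["exp(coef)"],
        "hr_ci_lower": s["exp(coef) lower 95%"],
        "hr_ci_upper": s["exp(coef) upper 95%"],
        "p": s["p"],
    })
    return CoxResult(summary=summary, concordance=float(cph.concordance_index_),
                     n_events=n_events, model=cph)


def ipcw_auc(times, events, marker, horizon, censor_km: KMCurve | None = None) -> float:
    """IPCW cumulative/dynamic AUC of a marker at one horizon.

    Returns ``nan`` when there is no case (event by ``horizon``) or no
    control (followed beyond ``horizon``).
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    marker = np.asarray(marker, float)
    case = (times <= horizon) & (events == 1)
    ctrl = times > horizon
    if not case.any() or not ctrl.any():
        return float("nan")
    if censor_km is None:
        censor_km = censor_survival(times, events)
    g_case = censor_km.at(times[case], left=True)
    g_ctrl = censor_km.at(horizon)
    # G can only hit 0 beyond the last observed censoring time; clip to the
    # smallest positive estimate so weights stay finite
    g_floor = censor_km.survival[censor_km.survival > 0].min()
    w_case = 1.0 / np.maximum(g_case, g_floor)
    v_ctrl = 1.0 / max(g_ctrl, g_floor)

    m_ctrl = np.sort(marker[ctrl])
    lo = np.searchsorted(m_ctrl, marker[case], side="left")
    hi = np.searchsorted(m_ctrl, marker[case], side="right")
    wins = lo + 0.5 * (hi - lo)          # controls beaten + half the ties
    num = float((w_case * wins).sum()) * v_ctrl
    den = float(w_case.sum()) * v_ctrl * len(m_ctrl)
    return num / den


def _monthly_horizons(median_os_days: float) -> np.ndarray:
    m = int(np.floor(median_os_days / DAYS_PER_MONTH))
    return np.arange(1, m + 1)


def auc_series(times, events, marker, median_os_days: float, endpoint: str = "overall",
               marker_name: str = "marker", n_boot: int = 500,
               seed: int | None = None) -> AUCSeries:
    """IPCW AUC at monthly horizons up to the median overall survival.

    Horizons run from month 1 to ``floor(median OS in months)``; undefined
    horizons (no case or no control) are carried as ``nan``.  Percentile
    bootstrap (patient-level resampling, ``n_boot`` replicates, seeded)
    yields 95% bands; ``n_boot=0`` skips them.
    """
    if not np.isfinite(median_os_days):
        raise ValueError("median overall survival is undefined")
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    marker = np.asarray(marker, float)
    horizons = _monthly_horizons(median_os_days)
    days = horizons * DAYS_PER_MONTH
    G = censor_survival(times, events)
    auc = np.array([ipcw_auc(times, events, marker, d, G) for d in days])
    lower = np.full_like(auc, np.nan)
    upper = np.full_like(auc, np.nan)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(times)
        boots = np.empty((n_boot, len(days)))
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            tb, eb, mb = times[idx], events[idx], marker[idx]
            Gb = censor_survival(tb, eb)
            boots[b] = [ipcw_auc(tb, eb, mb, d, Gb) for d in days]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            lower = np.nanpercentile(boots, 2.5, axis=0)
            upper = np.nanpercentile(boots, 97.5, axis=0)
    return AUCSeries(endpoint=endpoint, marker=marker_name,
                     horizons_months=horizons, auc=auc,
                     ci_lower=lower, ci_upper=upper, n_boot=n_boot)


def compare_markers(times, events, marker_a, marker_b, horizon,
                    n_boot: int = 500, seed: int | None = None):
    """Paired bootstrap comparison of two markers' IPCW AUC at one horizon.

    Returns ``(difference, p)`` where difference = AUC_a - AUC_b on the
    observed data and p is the two-sided percentile bootstrap p-value of the
    paired difference.  Rejects horizons where either AUC is undefined.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    marker_a = np.asarray(marker_a, float)
    marker_b = np.asarray(marker_b, float)
    a = ipcw_auc(times, events, marker_a, horizon)
    b = ipcw_auc(times, events, marker_b, horizon)
    if np.isnan(a) or np.isnan(b):
        raise ValueError("AUC undefined at this horizon for at least one marker")
    diff = a - b
    rng = np.random.default_rng(seed)
    n = len(times)
    diffs = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        tb, eb = times[idx], events[idx]
        Gb = censor_survival(tb, eb)
        da = ipcw_auc(tb, eb, marker_a[idx], horizon, Gb)
        db = ipcw_auc(tb, eb, marker_b[idx], horizon, Gb)
        if not (np.isnan(da) or np.isnan(db)):
            diffs.append(da - db)
    diffs = np.asarray(diffs)
    if len(diffs) == 0:
        return diff, float("nan")
    p = 2.0 * min((diffs <= 0).mean(), (diffs >= 0).mean())
    return diff, float(min(p, 1.0))
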