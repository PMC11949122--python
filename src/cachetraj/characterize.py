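"""Cluster characterization: weekly at-risk cachexia prevalence curves.

For each cluster and week since diagnosis, the prevalence is the number of
at-risk patients whose current severity category is full cachexia (2)
divided by the number of at-risk patients with a defined category.  A
patient is at risk in week ``w`` while their overall-survival channel time
(death or loss to follow-up) exceeds ``7*w`` days.  The current category is
the last observed category at or before the week start (last observation
carried forward); before a patient's first post-diagnosis measurement the
category is undefined and the patient is excluded from both numerator and
denominator.

``label_archetypes`` attaches the descriptive archetype names used for the
three canonical progression morphologies — sustained-high ("persistent"),
low-flat ("smouldering") and spike-then-decay ("rapid_recovery") — from
summary features of the curves.  It is a post-hoc naming convenience and
never feeds back into clustering.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .scoring import SeveritySequence

__all__ = ["prevalence_curves", "label_archetypes", "ARCHETYPE_NAMES"]

ARCHETYPE_NAMES = ("persistent", "smouldering", "rapid_recovery")


def prevalence_curves(sequences: list[SeveritySequence],
                      followup_days,
                      labels,
                      horizon_weeks: int = 156) -> pd.DataFrame:
    """Weekly at-risk cachexia prevalence per cluster.

    Parameters
    ----------
    sequences : list of SeveritySequence
    followup_days : array-like
        Overall-survival channel time per patient (death or censoring), days.
    labels : array-like
        Cluster label per patient (aligned with ``sequences``).
    horizon_weeks : int
        Number of weekly grid points from diagnosis (default 156 = 3 years).

    Returns
    -------
    DataFrame with columns ``cluster, week, at_risk, with_cachexia, fraction``;
    weeks where a cluster has no at-risk patient with a defined category are
    omitted.
    """
    followup_days = np.asarray(followup_days)
    labels = np.asarray(labels)
    if not (len(sequences) == len(followup_days) == len(labels)):
        raise ValueError("sequences, followup_days and labels must align")
    rows = []
    for cluster in np.unique(labels):
        members = np.flatnonzero(labels == cluster)
        n_before = len(rows)
        for w in range(horizon_weeks):
            day = 7 * w
            at_risk = 0
            with_cachexia = 0
            for i in members:
                if followup_days[i] <= day:
                    continue
                seq = sequences[i]
                pos = np.searchsorted(seq.times, day, side="right") - 1
                if pos < 0:   # before first measurement: category undefined
                    continue
                at_risk += 1
                if seq.values[pos] == 2:
                    with_cachexia += 1
            if at_risk > 0:
                rows.append((int(cluster), w, at_risk, with_cachexia,
                             with_cachexia / at_risk))
        if len(rows) == n_before:
            warnings.warn(f"cluster {cluster}: empty prevalence curve (no "
                          "at-risk patient with a defined category)",
                          stacklevel=2)
    return pd.DataFrame(rows, columns=["cluster", "week", "at_risk",
                                       "with_cachexia", "fraction"])


def _curve_features(curves: pd.DataFrame) -> pd.DataFrame:
    feats = []
    for cluster, g in curves.groupby("cluster"):
        frac = g.sort_values("week")["fraction"].to_numpy()
        peak = float(frac.max()) if len(frac) else 0.0
        late = frac[len(frac) - max(1, len(frac) // 3):]
        late_mean = float(late.mean()) if len(late) else 0.0
        feats.append((cluster, peak, late_mean, peak - late_mean))
    return pd.DataFrame(feats, columns=["cluster", "peak", "late_mean",
                                        "decline"]).set_index("cluster")


def label_archetypes(curves: pd.DataFrame) -> dict:
    """Assign archetype names to clusters from prevalence-curve features.

    Scores per archetype: ``smouldering`` favours the lowest peak,
    ``rapid_recovery`` the largest peak-to-late decline, ``persistent`` the
    highest late-window mean.  Labels are assigned greedily by the globally
    strongest (cluster, archetype) score, each label and cluster used at
    most once; with more than three clusters the extras stay unlabeled
    (``None``).  Emits a degeneracy warning when curves are
    indistinguishable.
    """
    feats = _curve_features(curves)
    if len(feats) < 2:
        raise ValueError("need at least 2 cluster curves to assign archetypes")
    scores = pd.DataFrame({
        "persistent": feats["late_mean"],
        "smouldering": 1.0 - feats["peak"],
        "rapid_recovery": feats["decline"],
    })
    if scores.nunique().max() == 1:
        warnings.warn("identical prevalence curves; archetype assignment is "
                      "degenerate", stacklevel=2)
    mapping = {c: None for c in feats.index}
    free_clusters = list(feats.index)
    free_labels = list(ARCHETYPE_NAMES)
    while free_clusters and free_labels:
        best = None
        for name in free_labels:            # fixed archetype order
            for c in free_clusters:         # then ascending cluster id
                s = scores.loc[c, name]
                if best is None or s > best[0]:
                    best = (s, name, c)
        _, name, c = best
        mapping[c] = name
        free_clusters.remove(c)
        free_labels.remove(name)
    return mapping
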