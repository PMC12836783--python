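"""Evaluation statistics comparing text-mined output to reference data.

Four views, matching how rule-based extraction is usually audited:

* a confusion matrix with class-wise precision/recall/F1 and the
  support-weighted F1 for baseline PS (percent scale);
* Kaplan-Meier survival curves with the median PFS and its 95% CI
  (log-log Greenwood band inversion) for each arm;
* Harrell's concordance index between the text-mined and reference PFS,
  with comparability decided on the reference arm (a pair is comparable
  when the shorter reference time ends in an event); ties in the
  text-mined times count half;
* per-patient discrepancy flags on the TM/reference time ratio (> 3 or
  < 1/3), the triage list for manual review of large disagreements.

The cohort-flow report accounts for every patient exactly once per arm
(resolved / unresolved / no-follow-up / unmatched), so numbers quoted from
any of the views can be traced back to a denominator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times

from .temporal import SurvivalRecord


@dataclass
class ConfusionMatrix:
    classes: list  # ordered labels present in truth ∪ prediction
    counts: np.ndarray  # true class x predicted class

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


@dataclass
class MetricsReport:
    """Class-wise precision/recall/F1 (percent) and the weighted F1."""

    per_class: dict  # label -> {"precision": %, "recall": %, "f1": %, "support": n}
    weighted_f1: float
    n_matched: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(self.per_class, orient="index")


def _as_series(table, value_col: str) -> pd.Series:
    if isinstance(table, pd.Series):
        return table
    df = pd.DataFrame(table)
    return df.set_index("patient_id")[value_col]


def ps_metrics(predicted, truth) -> tuple[ConfusionMatrix, MetricsReport]:
    """Score predicted baseline PS against the reference.

    Both tables need ``patient_id`` and ``score`` columns (or are Series
    indexed by patient).  Only patients present in both are scored;
    unmatched patients are counted by :func:`cohort_flow`, not here.
    Classes with zero predicted positives get precision 0 with a warning so
    the weighted F1 stays defined.
    """
    pred = _as_series(predicted, "score")
    ref = _as_series(truth, "score")
    shared = pred.index.intersection(ref.index)
    if len(shared) == 0:
        raise ValueError("no overlapping patients between prediction and reference")
    y_pred = pred.loc[shared].astype(int)
    y_true = ref.loc[shared].astype(int)
    classes = sorted(set(y_true) | set(y_pred))
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[idx[t], idx[p]] += 1
    per_class: dict = {}
    weighted = 0.0
    n = counts.sum()
    for c in classes:
        i = idx[c]
        tp = counts[i, i]
        support = counts[i, :].sum()
        pred_pos = counts[:, i].sum()
        if pred_pos == 0:
            warnings.warn(f"class {c}: no predicted positives; precision set to 0")
            precision = 0.0
        else:
            precision = tp / pred_pos
        recall = tp / support if support else 0.0
        f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
        per_class[c] = {
            "precision": 100.0 * precision,
            "recall": 100.0 * recall,
            "f1": 100.0 * f1,
            "support": int(support),
        }
        weighted += (support / n) * 100.0 * f1
    matrix = ConfusionMatrix(classes=classes, counts=counts)
    return matrix, MetricsReport(per_class=per_class, weighted_f1=weighted, n_matched=int(n))


@dataclass
class KMEstimate:
    """Product-limit survival estimate with median and its 95% CI."""

    times: np.ndarray
    survival: np.ndarray
    median: Optional[float]
    median_ci: tuple[Optional[float], Optional[float]]
    n: int
    n_events: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival})


def _records_to_arrays(records) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(records, pd.DataFrame):
        return records["time_months"].to_numpy(float), records["event"].to_numpy(bool)
    times = np.array([r.time_months for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    return times, events


def km_estimate(records) -> KMEstimate:
    """Kaplan-Meier product-limit estimate of a survival table.

    ``records`` is a sequence of :class:`~clinotext.temporal.SurvivalRecord`
    or a DataFrame with ``time_months``/``event``.  The median is the first
    time the step function drops to <= 0.5; its 95% CI inverts the
    pointwise log-log (Greenwood) confidence band at 0.5.  With an
    all-censored sample the median and CI are undefined (``None``), not an
    error.
    """
    times, events = _records_to_arrays(records)
    if len(times) == 0:
        raise ValueError("km_estimate needs at least one record")
    if np.any(times < 0):
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    grid = kmf.survival_function_.index.to_numpy(float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(float)
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    median_ci = (None if np.isinf(lo) else lo, None if np.isinf(hi) else hi)
    if median is None:
        median_ci = (None, None)
    return KMEstimate(
        times=grid, survival=surv, median=median, median_ci=median_ci,
        n=len(times), n_events=int(events.sum()),
    )


@dataclass
class ConcordanceResult:
    concordant: int
    discordant: int
    tied: int

    @property
    def comparable(self) -> int:
        return self.concordant + self.discordant + self.tied

    @property
    def c(self) -> Optional[float]:
        if self.comparable == 0:
            return None
        return (self.concordant + 0.5 * self.tied) / self.comparable


def _survival_frame(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        df = table
    else:
        df = pd.DataFrame(
            [{"patient_id": r.patient_id, "time_months": r.time_months, "event": r.event}
             for r in table]
        )
    return df.set_index("patient_id") if "patient_id" in df.columns else df


def concordance_index(tm, reference) -> ConcordanceResult:
    """Harrell's C of the text-mined PFS against the reference PFS.

    Evaluated over patients present in both tables.  A pair is comparable
    when the reference times are orderable under censoring: the patient
    with the shorter reference time had an event.  The pair is concordant
    when the text-mined times order the same way; equal text-mined times
    count 0.5.  Text-mined censored times enter as their recorded values.
    """
    tm_df, ref_df = _survival_frame(tm), _survival_frame(reference)
    shared = tm_df.index.intersection(ref_df.index)
    t_tm = tm_df.loc[shared, "time_months"].to_numpy(float)
    t_ref = ref_df.loc[shared, "time_months"].to_numpy(float)
    e_ref = ref_df.loc[shared, "event"].to_numpy(bool)
    conc = disc = tied = 0
    n = len(shared)
    for i in range(n):
        for j in range(i + 1, n):
            if t_ref[i] == t_ref[j]:
                continue  # not orderable
            short, long_ = (i, j) if t_ref[i] < t_ref[j] else (j, i)
            if not e_ref[short]:
                continue  # censored before the other's time: not comparable
            if t_tm[short] < t_tm[long_]:
                conc += 1
            elif t_tm[short] > t_tm[long_]:
                disc += 1
            else:
                tied += 1
    result = ConcordanceResult(conc, disc, tied)
    if result.comparable < 2:
        warnings.warn("fewer than 2 comparable pairs; C-index undefined")
    return result


@dataclass(frozen=True)
class DiscrepancyFlag:
    patient_id: str
    tm_time: float
    ref_time: float
    ratio: float  # nan when the reference time is 0
    flagged: bool


def flag_discrepancies(tm, reference, upper: float = 3.0) -> list[DiscrepancyFlag]:
    """Flag patients whose TM/reference PFS ratio exceeds ``upper`` or falls
    below ``1/upper``; output sorted by |log ratio| descending.

    Restricted to patients with a time in both arms.  A reference time of
    zero makes the ratio undefined; such rows are flagged for review.
    """
    tm_df, ref_df = _survival_frame(tm), _survival_frame(reference)
    shared = tm_df.index.intersection(ref_df.index)
    flags = []
    for pid in shared:
        t_tm = float(tm_df.loc[pid, "time_months"])
        t_ref = float(ref_df.loc[pid, "time_months"])
        if t_ref == 0:
            flags.append(DiscrepancyFlag(pid, t_tm, t_ref, float("nan"), True))
            continue
        ratio = t_tm / t_ref
        flags.append(DiscrepancyFlag(pid, t_tm, t_ref, ratio, ratio > upper or ratio < 1.0 / upper))
    def sort_key(f: DiscrepancyFlag):
        if math.isnan(f.ratio) or f.ratio <= 0:
            return math.inf
        return abs(math.log(f.ratio))
    return sorted(flags, key=sort_key, reverse=True)


def cohort_flow(statuses: Mapping[str, Mapping[str, str]]) -> pd.DataFrame:
    """Tabulate per-arm patient accounting.

    ``statuses`` maps arm name -> {patient_id -> category}, categories from
    {"resolved", "unresolved", "no_follow_up", "unmatched"}.  The returned
    frame has one row per arm with category counts and a total; categories
    partition each arm's cohort by construction.
    """
    categories = ("resolved", "unresolved", "no_follow_up", "unmatched")
    rows = []
    for arm, mapping in statuses.items():
        bad = {v for v in mapping.values()} - set(categories)
        if bad:
            raise ValueError(f"unknown cohort categories in arm {arm!r}: {sorted(bad)}")
        counts = {c: sum(1 for v in mapping.values() if v == c) for c in categories}
        counts["total"] = len(mapping)
        rows.append({"arm": arm, **counts})
    return pd.DataFrame(rows, columns=["arm", *categories, "total"])


def scatter_table(tm, reference) -> pd.DataFrame:
    """One (TM, reference) PFS point per doubly-resolved patient."""
    tm_df, ref_df = _survival_frame(tm), _survival_frame(reference)
    shared = tm_df.index.intersection(ref_df.index)
    return pd.DataFrame(
        {
            "patient_id": shared,
            "tm_months": tm_df.loc[shared, "time_months"].to_numpy(float),
            "reference_months": ref_df.loc[shared, "time_months"].to_numpy(float),
        }
    )
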