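"""End-to-end drivers: corpus + treatments + config -> analysis tables.

Two pipelines share the readers and the rule config but differ in
normalization and resolution:

* PS: mine every note (structured PS rows merged in), then match one
  baseline PS per patient against the treatment-initiation date.
* PFS: drop pre-treatment notes, classify sentences into BP/PP/AP, call
  the progression/censor date per patient, realign called events to scan
  dates, and convert to survival records.  Patients whose timeline cannot
  be resolved are routed to a manual-review list, never guessed.

Both return a per-patient status accounting (resolved / unresolved /
no-follow-up / unmatched) that partitions the treated cohort, so every
downstream denominator is explicit.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .config import RuleConfig, default_config
from .corpus_io import NoteCorpus, TreatmentRecord, filter_pre_treatment, treatment_index
from .extract import PSObservation, mine_corpus
from .temporal import (ProgressionCall, SurvivalRecord, Timeline,
                       align_event_to_scan, call_progression, compute_pfs,
                       match_baseline_ps)


@dataclass
class PSResult:
    baseline: pd.DataFrame  # patient_id, date, score, secondary_score, source
    statuses: dict  # patient_id -> resolved | unmatched
    observations: list = field(default_factory=list)


@dataclass
class PFSResult:
    calls: list  # ProgressionCall per patient
    survival: pd.DataFrame  # patient_id, time_months, event
    review: pd.DataFrame  # patient_id, reason — the manual-review list
    statuses: dict  # patient_id -> resolved | unresolved | no_follow_up
    observations: list = field(default_factory=list)

    def survival_records(self) -> list[SurvivalRecord]:
        return [
            SurvivalRecord(r.patient_id, float(r.time_months), bool(r.event))
            for r in self.survival.itertuples(index=False)
        ]


def run_ps_pipeline(
    corpus: NoteCorpus,
    treatments: Iterable[TreatmentRecord],
    config: Optional[RuleConfig] = None,
    structured_ps: Iterable[PSObservation] = (),
) -> PSResult:
    """Mine PS mentions and match one baseline PS per treated patient."""
    config = config or default_config()
    init = treatment_index(treatments, drug=config.drugs.drug_of_interest)
    if not init:
        raise ValueError("treatment table is empty: no cohort to analyze")
    observations = mine_corpus(corpus, "ps", config, structured=structured_ps)
    by_patient: dict[str, list[PSObservation]] = {}
    for o in observations:
        by_patient.setdefault(o.patient_id, []).append(o)
    rows, statuses = [], {}
    for pid, init_date in sorted(init.items()):
        match = match_baseline_ps(
            by_patient.get(pid, []),
            init_date,
            window_before_days=config.baseline_window_before_days,
            window_after_days=config.baseline_window_after_days,
        )
        if match is None:
            statuses[pid] = "unmatched"
            continue
        statuses[pid] = "resolved"
        rows.append(
            {
                "patient_id": pid,
                "date": match.date.isoformat(),
                "score": match.resolved_score(config.ps_range_policy),
                "secondary_score": match.secondary_score,
                "source": match.source,
            }
        )
    baseline = pd.DataFrame(rows, columns=["patient_id", "date", "score", "secondary_score", "source"])
    return PSResult(baseline=baseline, statuses=statuses, observations=observations)


def run_pfs_pipeline(
    corpus: NoteCorpus,
    treatments: Iterable[TreatmentRecord],
    config: Optional[RuleConfig] = None,
    scans: Optional[Mapping[str, list]] = None,
    structured_progression: Iterable = (),
    deaths: Optional[Mapping[str, dt.date]] = None,
) -> PFSResult:
    """Derive per-patient PFS from the note stream.

    ``scans`` maps patient id -> scan dates for event-date realignment;
    ``deaths`` (optional, absent by default) maps patient id -> death
    date, which counts as a progression event per the PFS definition.
    """
    config = config or default_config()
    init = treatment_index(treatments, drug=config.drugs.drug_of_interest)
    if not init:
        raise ValueError("treatment table is empty: no cohort to analyze")
    scans = scans or {}
    deaths = deaths or {}
    filtered, no_follow_up = filter_pre_treatment(corpus, treatments, drug=config.drugs.drug_of_interest)
    observations = mine_corpus(filtered, "pfs", config, structured=structured_progression)
    by_patient: dict[str, list] = {}
    for o in observations:
        if o.date >= init.get(o.patient_id, o.date):
            by_patient.setdefault(o.patient_id, []).append(o)
    calls, surv_rows, review_rows, statuses = [], [], [], {}
    missing = sorted(set(init) - set(corpus.patients()))
    for pid, init_date in sorted(init.items()):
        if pid in no_follow_up or pid in missing:
            statuses[pid] = "no_follow_up"
            review_rows.append({"patient_id": pid, "reason": "no follow-up data after initiation"})
            continue
        timeline = Timeline(pid, init_date, by_patient.get(pid, []))
        call = call_progression(timeline, confirm_window_days=config.confirm_window_days)
        if call.status == "progressed":
            aligned = align_event_to_scan(
                call.event_date, scans.get(pid, []), max_lag_days=config.scan_max_lag_days
            )
            if aligned != call.event_date:
                call = ProgressionCall(pid, call.status, aligned, call.basis, call.evidence)
        if pid in deaths and (call.status != "progressed" or deaths[pid] < call.event_date):
            if deaths[pid] >= init_date:
                call = ProgressionCall(pid, "progressed", deaths[pid], "death", ("death date",))
        calls.append(call)
        if call.status == "unresolved":
            statuses[pid] = "unresolved"
            review_rows.append({"patient_id": pid, "reason": "contradictory or empty timeline"})
            continue
        statuses[pid] = "resolved"
        rec = compute_pfs(call, init_date)
        surv_rows.append(
            {"patient_id": pid, "time_months": rec.time_months, "event": rec.event,
             "event_date": call.event_date.isoformat(), "basis": call.basis}
        )
    survival = pd.DataFrame(surv_rows, columns=["patient_id", "time_months", "event", "event_date", "basis"])
    review = pd.DataFrame(review_rows, columns=["patient_id", "reason"])
    return PFSResult(calls=calls, survival=survival, review=review,
                     statuses=statuses, observations=observations)
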