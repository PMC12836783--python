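"""Temporal resolution: baseline PS matching, scan-date alignment, and
progression calling on per-patient timelines.

The extraction layer produces dated point observations; this module turns
them into per-patient analysis values.  A baseline PS is the observation
closest to treatment initiation within 30 days before it, falling back to
the earliest one up to 14 days after initiation only when nothing precedes
it.  A progression event noted at an outpatient visit is usually triggered
by an imaging scan a few days earlier, so called event dates are realigned
to the latest scan within a lag window.  Progression calling itself walks
the chronological BP/PP/AP timeline: the earliest "possible progression"
stands unless a "before progression" observation contradicts it shortly
after without the progression ever being re-asserted; a post-progression
drug start (AP) with no PP dates the event on its own; a timeline of only
BP observations is a censoring at the last visit; irreducibly contradictory
or empty timelines are routed to manual review rather than guessed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .extract import PhaseObservation, PSObservation

#: average Gregorian month length, used for day -> month conversion
DAYS_PER_MONTH = 30.44


@dataclass
class Timeline:
    """Chronological phase observations for one patient from day 0."""

    patient_id: str
    init_date: dt.date
    observations: list[PhaseObservation] = field(default_factory=list)

    def __post_init__(self):
        for o in self.observations:
            if o.date < self.init_date:
                raise ValueError(
                    f"{self.patient_id}: observation at {o.date} precedes init {self.init_date}"
                )
        self.observations = sorted(self.observations, key=lambda o: o.date)  # stable


@dataclass(frozen=True)
class ProgressionCall:
    """Resolved event-or-censor decision for one patient."""

    patient_id: str
    status: str  # progressed | censored | unresolved
    event_date: Optional[dt.date] = None
    basis: str = "none"  # pp_confirmed | ap_only | structured | censor_last_note | none
    evidence: tuple[str, ...] = ()


@dataclass(frozen=True)
class SurvivalRecord:
    """One PFS observation: time in months since initiation + event flag."""

    patient_id: str
    time_months: float
    event: bool

    def __post_init__(self):
        if self.time_months < 0:
            raise ValueError("negative survival time")


def match_baseline_ps(
    observations: Sequence[PSObservation],
    init_date: dt.date,
    window_before_days: int = 30,
    window_after_days: int = 14,
) -> Optional[PSObservation]:
    """Pick the baseline PS for one patient.

    Among observations dated in ``[init - window_before, init]``, the one
    closest to initiation wins; only if that window is empty is the
    earliest observation in ``(init, init + window_after]`` used.  Same-day
    ties break structured-before-mined, then lowest score (conservative),
    then input order.
    """
    before = [
        o for o in observations
        if dt.timedelta(0) <= init_date - o.date <= dt.timedelta(days=window_before_days)
    ]
    if before:
        best = min(
            enumerate(before),
            key=lambda io: (
                (init_date - io[1].date).days,
                io[1].source != "structured",
                io[1].resolved_score(),
                io[0],
            ),
        )
        return best[1]
    after = [
        o for o in observations
        if dt.timedelta(0) < o.date - init_date <= dt.timedelta(days=window_after_days)
    ]
    if after:
        best = min(
            enumerate(after),
            key=lambda io: (
                (io[1].date - init_date).days,
                io[1].source != "structured",
                io[1].resolved_score(),
                io[0],
            ),
        )
        return best[1]
    return None


def align_event_to_scan(
    event_date: dt.date, scan_dates: Iterable[dt.date], max_lag_days: int = 14
) -> dt.date:
    """Replace a visit-dated event with the latest scan shortly before it.

    Imaging scans typically precede the outpatient visit where progression
    is discussed, so the scan date is the more accurate event date.
    Returns ``event_date`` unchanged when no scan falls in
    ``[event - max_lag_days, event]``.
    """
    window = [
        s for s in scan_dates
        if dt.timedelta(0) <= event_date - s <= dt.timedelta(days=max_lag_days)
    ]
    return max(window) if window else event_date


def call_progression(timeline: Timeline, confirm_window_days: int = 30) -> ProgressionCall:
    """Resolve a timeline into progressed / censored / unresolved.

    Resolution order:

    a. The earliest PP observation is the candidate.  It stands (status
       ``progressed``, basis ``pp_confirmed``, event date = candidate date)
       unless a BP observation falls within ``confirm_window_days`` after it
       with no other PP/AP on or after the candidate up to that BP.  A
       contradicted candidate is abandoned and the next PP after the
       contradicting BP is tried.
    b. No PP at all but at least one AP: progressed at the first AP date,
       basis ``ap_only`` (a next treatment line implies progression at or
       before its start).  Likewise, PPs all contradicted but an AP occurs
       after the last contradiction.
    c. Only BP observations: censored at the last BP date.
    d. Otherwise (contradiction never re-asserted, or empty timeline):
       unresolved — the patient goes to manual review.
    """
    obs = timeline.observations
    pid = timeline.patient_id
    if not obs:
        return ProgressionCall(pid, "unresolved", basis="none")
    window = dt.timedelta(days=confirm_window_days)
    pps = [o for o in obs if o.phase == "PP"]
    last_contradiction: Optional[dt.date] = None
    for i, pp in enumerate(pps):
        bp_after = next(
            (o for o in obs if o.phase == "BP" and pp.date < o.date <= pp.date + window), None
        )
        if bp_after is None:
            return ProgressionCall(pid, "progressed", pp.date, "pp_confirmed", (pp.evidence,))
        reassert = next(
            (
                o for o in obs
                if o.phase in ("PP", "AP") and o is not pp and pp.date <= o.date <= bp_after.date
            ),
            None,
        )
        if reassert is not None:
            return ProgressionCall(pid, "progressed", pp.date, "pp_confirmed",
                                   (pp.evidence, reassert.evidence))
        last_contradiction = bp_after.date
    if pps:
        # every candidate contradicted: a later AP still re-asserts progression
        ap_after = next(
            (o for o in obs if o.phase == "AP" and o.date > last_contradiction), None
        )
        if ap_after is not None:
            return ProgressionCall(pid, "progressed", ap_after.date, "ap_only", (ap_after.evidence,))
        return ProgressionCall(pid, "unresolved", basis="none")
    aps = [o for o in obs if o.phase == "AP"]
    if aps:
        first_ap = aps[0]
        return ProgressionCall(pid, "progressed", first_ap.date, "ap_only", (first_ap.evidence,))
    last_bp = max((o for o in obs if o.phase == "BP"), key=lambda o: o.date)
    return ProgressionCall(pid, "censored", last_bp.date, "censor_last_note", (last_bp.evidence,))


def compute_pfs(call: ProgressionCall, init_date: dt.date) -> SurvivalRecord:
    """Convert a resolved call into a survival record (months, event flag).

    Months use the average month length of 30.44 days.  Unresolved calls
    are not representable and must be excluded (or manually resolved)
    upstream.
    """
    if call.status not in ("progressed", "censored"):
        raise ValueError(f"{call.patient_id}: cannot compute PFS for status {call.status!r}")
    if call.event_date is None:
        raise ValueError(f"{call.patient_id}: call has no event date")
    days = (call.event_date - init_date).days
    if days < 0:
        raise ValueError(f"{call.patient_id}: event date precedes treatment initiation")
    return SurvivalRecord(call.patient_id, days / DAYS_PER_MONTH, call.status == "progressed")
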