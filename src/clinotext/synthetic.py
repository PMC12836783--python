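"""Synthetic patient cohorts rendered as clinical-note corpora.

Real oncology notes cannot ship with a package, so end-to-end behavior is
exercised on simulated cohorts with known ground truth.  Each synthetic
patient gets a treatment-initiation date, a latent baseline performance
status, and a latent progression (or censoring) time drawn from an
exponential or Weibull distribution parameterized by its median in months.
The patient is then rendered as a stream of dated visit notes: visits
before progression carry stable-disease ("before progression") language,
the visit just after the progression scan carries progression language,
and later visits carry next-line-treatment ("after progression") language.
An imaging scan date is emitted a few days before the progression visit,
mirroring the real documentation lag between scan and outpatient visit.

The generator also reproduces the documented failure modes of rule-based
PS extraction as tunable noise rates: the digit zero written as a letter O
("WHO O"), words between keyword and score ("PS is 2"), drug shorthands
("osi"), vague progression wording that names no progression keyword, and
simply undocumented PS.  Every rendered PS mention is recorded in a ledger
with its adversarial mode, so tests can compare extraction output against
exact bookkeeping rather than against expectations.

Censoring is independent of the event process: a censoring time is drawn
from an exponential distribution calibrated so the probability of being
censored before the event equals the configured rate, and an
administrative follow-up cutoff truncates both.  Kaplan-Meier estimates on
the resulting tables are therefore unbiased, which the statistical
recovery tests rely on.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from .corpus_io import ClinicalNote, NoteCorpus, TreatmentRecord
from .temporal import DAYS_PER_MONTH

#: baseline-PS probabilities for scores 0-5; mass concentrated on 0-2 as in
#: advanced-NSCLC cohorts starting a next-line targeted agent
DEFAULT_PS_DISTRIBUTION = {0: 0.28, 1: 0.50, 2: 0.15, 3: 0.06, 4: 0.01, 5: 0.0}


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the cohort generator.  Defaults are the package's
    reference study conditions; see docs/methods.md for rationale."""

    n_patients: int = 100
    ps_distribution: tuple[float, ...] = tuple(DEFAULT_PS_DISTRIBUTION[k] for k in range(6))
    pfs_distribution: str = "exponential"  # or "weibull"
    median_pfs_months: float = 8.0
    weibull_shape: float = 1.5
    censor_prob: float = 0.13
    followup_cutoff_months: float = 28.0
    visit_interval_days: float = 42.0
    visit_jitter_days: float = 10.0
    scan_lead_days_min: int = 3
    scan_lead_days_max: int = 10
    baseline_ps_offset_max_days: int = 20
    p_misspell_zero: float = 0.0
    p_intervening: float = 0.0
    p_vague_progression: float = 0.0
    p_abbrev: float = 0.0
    p_missing_ps_mention: float = 0.0
    p_structured_ps: float = 0.0
    language: str = "en"
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        bad = []
        if self.n_patients < 1:
            bad.append("n_patients")
        if self.median_pfs_months <= 0:
            bad.append("median_pfs_months")
        probs = list(self.ps_distribution)
        if len(probs) != 6 or any(p < 0 for p in probs) or not math.isclose(sum(probs), 1.0, abs_tol=1e-6):
            bad.append("ps_distribution")
        for name in ("censor_prob", "p_misspell_zero", "p_intervening",
                     "p_vague_progression", "p_abbrev", "p_missing_ps_mention",
                     "p_structured_ps"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                bad.append(name)
        if self.pfs_distribution not in ("exponential", "weibull"):
            bad.append("pfs_distribution")
        if self.language not in ("en", "nl"):
            bad.append("language")
        if self.scan_lead_days_min < 0 or self.scan_lead_days_max < self.scan_lead_days_min:
            bad.append("scan_lead_days")
        if bad:
            raise ValueError(f"invalid synthetic config field(s): {', '.join(bad)}")
        return self


@dataclass(frozen=True)
class PlantedMention:
    """Bookkeeping for one rendered PS mention."""

    patient_id: str
    date: dt.date
    score: int
    rendered: str
    mode: str  # clean | misspelled_zero | intervening
    extractable: bool


@dataclass(frozen=True)
class PatientTruth:
    patient_id: str
    init_date: dt.date
    baseline_ps: int
    event: bool
    event_date: dt.date  # true progression (scan) date, or censor date
    progression_visit_date: Optional[dt.date] = None
    scan_date: Optional[dt.date] = None
    vague: bool = False

    @property
    def time_months(self) -> float:
        return (self.event_date - self.init_date).days / DAYS_PER_MONTH


@dataclass
class GroundTruth:
    """The generator's full bookkeeping: the oracle for every downstream test."""

    config: SyntheticConfig
    patients: list[PatientTruth] = field(default_factory=list)
    ps_ledger: list[PlantedMention] = field(default_factory=list)

    def patient(self, patient_id: str) -> PatientTruth:
        return next(p for p in self.patients if p.patient_id == patient_id)


def _event_sampler(config: SyntheticConfig):
    if config.pfs_distribution == "exponential":
        scale = config.median_pfs_months / math.log(2)
        return stats.expon(scale=scale)
    shape = config.weibull_shape
    scale = config.median_pfs_months / math.log(2) ** (1.0 / shape)
    return stats.weibull_min(shape, scale=scale)


def _censor_rate(config: SyntheticConfig, event_dist) -> float:
    """Exponential censoring rate giving P(censor before event) = censor_prob."""
    p = config.censor_prob
    if p <= 0:
        return 0.0
    if config.pfs_distribution == "exponential":
        lam = 1.0 / event_dist.kwds["scale"]
        return lam * p / (1.0 - p)

    def prob_censored(rate: float) -> float:
        val, _ = integrate.quad(lambda c: rate * math.exp(-rate * c) * event_dist.sf(c), 0, np.inf)
        return val

    return optimize.brentq(lambda r: prob_censored(r) - p, 1e-8, 100.0)


def generate_cohort(config: SyntheticConfig) -> GroundTruth:
    """Draw the latent cohort (no text yet).  Reproducible given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    event_dist = _event_sampler(config)
    censor_rate = _censor_rate(config, event_dist)
    cutoff_days = int(round(config.followup_cutoff_months * DAYS_PER_MONTH))
    truth = GroundTruth(config=config)
    base = dt.date(2020, 1, 1)
    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        init = base + dt.timedelta(days=int(rng.integers(0, 365)))
        ps = int(rng.choice(6, p=np.asarray(config.ps_distribution) / sum(config.ps_distribution)))
        t_days = max(1, int(round(event_dist.rvs(random_state=rng) * DAYS_PER_MONTH)))
        if censor_rate > 0:
            c_days = max(0, int(round(rng.exponential(1.0 / censor_rate) * DAYS_PER_MONTH)))
        else:
            c_days = cutoff_days + t_days + 1
        observed = min(t_days, c_days, cutoff_days)
        event = t_days <= min(c_days, cutoff_days)
        event_date = init + dt.timedelta(days=observed)
        scan_date = prog_visit = None
        vague = False
        if event:
            scan_date = event_date
            lead = int(rng.integers(config.scan_lead_days_min, config.scan_lead_days_max + 1))
            prog_visit = scan_date + dt.timedelta(days=lead)
            vague = bool(rng.random() < config.p_vague_progression)
        truth.patients.append(
            PatientTruth(pid, init, ps, event, event_date,
                         progression_visit_date=prog_visit, scan_date=scan_date, vague=vague)
        )
    return truth


_TEMPLATES = {
    "en": {
        "bp": ("no signs of progression", "stable disease on imaging",
               "good response, no evidence of progression"),
        "pp": ("ct shows progression of known lesions", "new lesions in the left lung, progression"),
        "vague": "growth of known metastasis   puncture planned to determine resistance mechanism",
        "ap_start": "start lorlatinib today",
        "ap_followup": "after progression follow-up, tolerating next-line treatment",
        "drug_line": "continues {drug} 80 mg daily",
        "filler": ("weight {w} kg", "blood pressure within normal limits"),
        "drug_full": "osimertinib", "drug_short": "osi",
    },
    "nl": {
        "bp": ("geen aanwijzingen voor progressie", "stabiel beeld",
               "goede respons, geen tekenen van progressie"),
        "pp": ("ct toont progressie van bekende laesies", "nieuwe laesies in de linker long, progressie"),
        "vague": "groei van bekende metastase   punctie gepland voor bepaling resistentiemechanisme",
        "ap_start": "start lorlatinib vandaag",
        "ap_followup": "controle na progressie, verdraagt vervolgbehandeling goed",
        "drug_line": "continueert {drug} 80 mg dagelijks",
        "filler": ("gewicht {w} kg", "bloeddruk normaal"),
        "drug_full": "osimertinib", "drug_short": "osi",
    },
}

_PS_FORMS = ("WHO {s}", "ECOG {s}", "PS {s}", "ECOG: {s}", "who {s}")


def _render_ps_line(rng, score: int, config: SyntheticConfig) -> tuple[str, str, bool]:
    """Return (line, mode, extractable) for one PS mention."""
    if score == 0 and rng.random() < config.p_misspell_zero:
        return "WHO O", "misspelled_zero", False
    if rng.random() < config.p_intervening:
        return f"PS is {score}", "intervening", False
    form = _PS_FORMS[int(rng.integers(0, len(_PS_FORMS)))]
    return form.format(s=score), "clean", True


def _visit_days(rng, config: SyntheticConfig, last_day: int) -> list[int]:
    """Visit offsets (days since initiation): day 0, then jittered intervals,
    always ending exactly at ``last_day``."""
    days = [0]
    while True:
        step = max(7, int(round(rng.normal(config.visit_interval_days, config.visit_jitter_days))))
        nxt = days[-1] + step
        if nxt >= last_day:
            break
        days.append(nxt)
    if last_day > 0:
        days.append(last_day)
    return days


@dataclass
class RenderedCohort:
    """The generator's output in pipeline-ready form."""

    corpus: NoteCorpus
    treatments: list[TreatmentRecord]
    scans: dict[str, list[dt.date]]
    structured_ps: pd.DataFrame  # patient_id, date, value (may be empty)


def render_notes(truth: GroundTruth, config: Optional[SyntheticConfig] = None) -> RenderedCohort:
    """Render the latent cohort as dated clinical notes plus side tables.

    Deterministic: the render stream is driven by a fresh generator seeded
    from ``config.seed``, so the corpus text is byte-identical across runs.
    """
    config = (config or truth.config).validate()
    tpl = _TEMPLATES[config.language]
    rng = np.random.default_rng(config.seed + 1_000_003)
    notes: list[ClinicalNote] = []
    treatments: list[TreatmentRecord] = []
    scans: dict[str, list[dt.date]] = {}
    structured_rows = []
    truth.ps_ledger.clear()

    def ps_line(pid: str, date: dt.date, score: int) -> Optional[str]:
        if rng.random() < config.p_missing_ps_mention:
            return None
        line, mode, ok = _render_ps_line(rng, score, config)
        truth.ps_ledger.append(PlantedMention(pid, date, score, line, mode, ok))
        return line

    for p in truth.patients:
        treatments.append(TreatmentRecord(p.patient_id, tpl["drug_full"], p.init_date))
        # dedicated intake note shortly before initiation carrying the baseline PS
        offset = int(rng.integers(0, config.baseline_ps_offset_max_days + 1))
        intake_date = p.init_date - dt.timedelta(days=offset)
        intake_lines = ["intake visit" if config.language == "en" else "intake gesprek"]
        line = ps_line(p.patient_id, intake_date, p.baseline_ps)
        if line:
            intake_lines.append(line)
        notes.append(ClinicalNote(p.patient_id, intake_date, "outpatient", "\n".join(intake_lines)))
        if rng.random() < config.p_structured_ps:
            structured_rows.append(
                {"patient_id": p.patient_id, "date": p.init_date.isoformat(), "value": p.baseline_ps}
            )
        # follow-up visits strictly before the progression scan (or to censor date)
        if p.event:
            last_bp_day = max(0, (p.scan_date - p.init_date).days - 1)
        else:
            last_bp_day = (p.event_date - p.init_date).days
        for day in _visit_days(rng, config, last_bp_day):
            date = p.init_date + dt.timedelta(days=day)
            lines = []
            filler = tpl["filler"][int(rng.integers(0, len(tpl["filler"])))]
            lines.append(filler.format(w=60 + int(rng.integers(0, 40))))
            line = ps_line(p.patient_id, date, p.baseline_ps)
            if line:
                lines.append(line)
            lines.append(tpl["bp"][int(rng.integers(0, len(tpl["bp"])))])
            if rng.random() < 0.5:
                drug = tpl["drug_short"] if rng.random() < config.p_abbrev else tpl["drug_full"]
                lines.append(tpl["drug_line"].format(drug=drug))
            notes.append(ClinicalNote(p.patient_id, date, "outpatient", "\n".join(lines)))
        if p.event:
            scans.setdefault(p.patient_id, []).append(p.scan_date)
            pp_text = tpl["vague"] if p.vague else tpl["pp"][int(rng.integers(0, len(tpl["pp"])))]
            notes.append(ClinicalNote(p.patient_id, p.progression_visit_date, "outpatient", pp_text))
            ap1 = p.progression_visit_date + dt.timedelta(days=int(rng.integers(7, 21)))
            notes.append(ClinicalNote(p.patient_id, ap1, "outpatient", tpl["ap_start"]))
            ap2 = ap1 + dt.timedelta(days=int(rng.integers(21, 42)))
            notes.append(ClinicalNote(p.patient_id, ap2, "outpatient", tpl["ap_followup"]))
    structured_ps = pd.DataFrame(structured_rows, columns=["patient_id", "date", "value"])
    return RenderedCohort(NoteCorpus(notes), treatments, scans, structured_ps)


def truth_tables(truth: GroundTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reference tables in the schema the evaluation layer consumes:
    (PS table: patient_id, score; survival table: patient_id, time_months,
    event).  Stands in for a manually curated reference arm."""
    ps = pd.DataFrame(
        [{"patient_id": p.patient_id, "score": p.baseline_ps} for p in truth.patients],
        columns=["patient_id", "score"],
    )
    surv = pd.DataFrame(
        [{"patient_id": p.patient_id, "time_months": p.time_months, "event": p.event}
         for p in truth.patients],
        columns=["patient_id", "time_months", "event"],
    )
    return ps, surv


def simulate(config: SyntheticConfig) -> tuple[GroundTruth, RenderedCohort]:
    """Convenience: generate and render in one call."""
    truth = generate_cohort(config)
    return truth, render_notes(truth, config)


def write_simulation(truth: GroundTruth, rendered: RenderedCohort, outdir) -> None:
    """Write notes.csv, treatments.csv, scans.csv and the truth tables."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rendered.corpus.to_frame().to_csv(outdir / "notes.csv", index=False)
    pd.DataFrame(
        [{"patient_id": t.patient_id, "drug": t.drug, "init_date": t.init_date.isoformat()}
         for t in rendered.treatments]
    ).to_csv(outdir / "treatments.csv", index=False)
    pd.DataFrame(
        [{"patient_id": pid, "scan_date": d.isoformat(), "modality": "CT"}
         for pid, dates in rendered.scans.items() for d in dates],
        columns=["patient_id", "scan_date", "modality"],
    ).to_csv(outdir / "scans.csv", index=False)
    if len(rendered.structured_ps):
        rendered.structured_ps.to_csv(outdir / "structured_ps.csv", index=False)
    ps, surv = truth_tables(truth)
    ps.to_csv(outdir / "truth_ps.csv", index=False)
    surv.to_csv(outdir / "truth_survival.csv", index=False)
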