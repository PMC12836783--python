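"""Tabular interchange I/O for clinical note corpora.

The pipeline's raw inputs are flat tables: a note table (one row per dated
documentation event per patient), a treatment table (patient, drug, treatment
initiation date), optional structured performance-status and structured
progression tables, and an optional scan-date table.  CSV with UTF-8 is the
canonical interchange format; ``.xlsx`` is accepted as a convenience and
mapped onto the same schema.

Clinical exports mix date dialects (ISO ``yyyy-mm-dd`` next to European
``dd-mm-yyyy``), so parsing is dialect-aware: the dialect is either stated
explicitly or auto-detected, and day/month-ambiguous literals such as
``03-04-2020`` are resolved by the configured day-first preference and
flagged rather than guessed silently.  Rows that cannot be parsed are never
dropped silently; they are collected in a rejects table attached to the
corpus (and written to a side report by the CLI).
"""

from __future__ import annotations

import datetime as dt
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

NOTE_SOURCES = ("outpatient", "admission", "note", "radiology", "structured")

#: plausible calendar range for documentation events
DATE_MIN = dt.date(1990, 1, 1)
DATE_MAX = dt.date(2100, 12, 31)

_ISO_RE = re.compile(r"^(\d{4})-(\d{1,2})-(\d{1,2})$")
_EURO_RE = re.compile(r"^(\d{1,2})[-/.](\d{1,2})[-/.](\d{4})$")


class ConfigurationError(ValueError):
    """A required column or configuration entry is missing or invalid."""


def parse_date(
    value, dialect: str = "auto", dayfirst: bool = True
) -> tuple[Optional[dt.date], bool]:
    """Parse one date literal.

    Parameters
    ----------
    value : str or date-like
    dialect : {"iso", "dmy", "mdy", "auto"}
        ``auto`` accepts ISO directly and infers day/month order from the
        numeric values when possible.
    dayfirst : bool
        How ``auto`` resolves literals where both leading fields are <= 12.

    Returns
    -------
    (date or None, ambiguous flag)
        ``None`` when the literal is not a valid calendar date in the
        plausible range; the flag is True only for auto-resolved ambiguous
        day/month literals.
    """
    if isinstance(value, dt.datetime):
        value = value.date()
    if isinstance(value, dt.date):
        return (value, False) if DATE_MIN <= value <= DATE_MAX else (None, False)
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None, False
    s = str(value).strip()
    if not s:
        return None, False

    def _mk(y: int, m: int, d: int) -> Optional[dt.date]:
        try:
            out = dt.date(y, m, d)
        except ValueError:
            return None
        return out if DATE_MIN <= out <= DATE_MAX else None

    m = _ISO_RE.match(s)
    if m and dialect in ("iso", "auto"):
        return _mk(int(m.group(1)), int(m.group(2)), int(m.group(3))), False
    m = _EURO_RE.match(s)
    if m is None:
        return None, False
    a, b, y = int(m.group(1)), int(m.group(2)), int(m.group(3))
    if dialect == "dmy":
        return _mk(y, b, a), False
    if dialect == "mdy":
        return _mk(y, a, b), False
    if dialect == "auto":
        if a > 12 and b <= 12:
            return _mk(y, b, a), False
        if b > 12 and a <= 12:
            return _mk(y, a, b), False
        # both fields could be the day: resolve by preference, flag it
        date = _mk(y, b, a) if dayfirst else _mk(y, a, b)
        return date, a != b
    if dialect == "iso":
        return None, False
    raise ConfigurationError(f"unknown date dialect {dialect!r}")


@dataclass(frozen=True)
class ClinicalNote:
    """One dated free-text documentation event for one patient."""

    patient_id: str
    date: dt.date
    source: str = "note"
    text: str = ""

    def __post_init__(self):
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if not (DATE_MIN <= self.date <= DATE_MAX):
            raise ValueError(f"note date {self.date} outside plausible range")


@dataclass(frozen=True)
class TreatmentRecord:
    """Treatment initiation of one drug for one patient."""

    patient_id: str
    drug: str
    init_date: dt.date


class NoteCorpus:
    """A collection of clinical notes, iterable per patient in date order.

    Per-patient iteration is date-sorted with input order preserved for
    equal dates (stable sort).  The ``rejects`` frame lists input rows that
    failed validation, with a reason per row.
    """

    def __init__(self, notes: Iterable[ClinicalNote] = (), rejects: Optional[pd.DataFrame] = None):
        self._notes: list[ClinicalNote] = list(notes)
        self._by_patient: dict[str, list[ClinicalNote]] = {}
        for note in self._notes:
            self._by_patient.setdefault(note.patient_id, []).append(note)
        for pid in self._by_patient:
            self._by_patient[pid].sort(key=lambda n: n.date)  # stable
        self.rejects = rejects if rejects is not None else _empty_rejects()

    def __len__(self) -> int:
        return len(self._notes)

    def __iter__(self) -> Iterator[ClinicalNote]:
        for pid in self.patients():
            yield from self._by_patient[pid]

    def patients(self) -> list[str]:
        return sorted(self._by_patient)

    def notes_for(self, patient_id: str) -> list[ClinicalNote]:
        return list(self._by_patient.get(patient_id, []))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient_id": n.patient_id,
                    "date": n.date.isoformat(),
                    "source": n.source,
                    "text": n.text,
                }
                for n in self
            ],
            columns=["patient_id", "date", "source", "text"],
        )


def _empty_rejects() -> pd.DataFrame:
    return pd.DataFrame(columns=["row", "patient_id", "value", "reason"])


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, dtype=str)
    else:
        try:
            df = pd.read_csv(path, dtype=str, keep_default_na=False)
        except pd.errors.EmptyDataError:
            return pd.DataFrame()
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _require_columns(df: pd.DataFrame, required: Iterable[str], colmap: Optional[dict] = None):
    colmap = colmap or {}
    rename = {v: k for k, v in colmap.items() if v in df.columns}
    df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"missing required column(s): {', '.join(missing)} (found: {', '.join(df.columns)})"
        )
    return df


def read_note_table(
    path,
    dialect: str = "auto",
    dayfirst: bool = True,
    column_map: Optional[dict] = None,
) -> NoteCorpus:
    """Read a note table into a :class:`NoteCorpus`.

    Required columns (after applying ``column_map``, a mapping from
    canonical name to the file's column name): ``patient_id``, ``date``,
    ``source``, ``text``.  Rows with unparseable dates or empty patient ids
    go to ``corpus.rejects``; ambiguous auto-dialect dates are parsed with
    the day-first preference and additionally listed in the rejects frame
    with reason ``ambiguous-date`` (the note itself is retained).
    """
    df = _read_table(path)
    if df.empty:
        warnings.warn(f"{path}: empty note table", stacklevel=2)
        return NoteCorpus()
    df = _require_columns(df, ["patient_id", "date", "source", "text"], column_map)
    notes, rej = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        pid = str(row.patient_id).strip()
        date, ambiguous = parse_date(row.date, dialect=dialect, dayfirst=dayfirst)
        if not pid:
            rej.append((i, pid, str(row.date), "empty patient_id"))
            continue
        if date is None:
            rej.append((i, pid, str(row.date), "unparseable date"))
            continue
        if ambiguous:
            rej.append((i, pid, str(row.date), "ambiguous-date"))
        notes.append(ClinicalNote(pid, date, str(row.source).strip() or "note", str(row.text)))
    rejects = pd.DataFrame(rej, columns=["row", "patient_id", "value", "reason"])
    return NoteCorpus(notes, rejects=rejects if len(rej) else None)


def write_note_table(corpus: NoteCorpus, path) -> None:
    corpus.to_frame().to_csv(path, index=False)


def read_treatment_table(path, dialect: str = "auto", dayfirst: bool = True) -> list[TreatmentRecord]:
    """Read the treatment-initiation table.

    One record per (patient, drug); duplicate rows keep the earliest
    initiation date with a warning.
    """
    df = _read_table(path)
    if df.empty:
        return []
    df = _require_columns(df, ["patient_id", "drug", "init_date"])
    best: dict[tuple[str, str], dt.date] = {}
    order: list[tuple[str, str]] = []
    for row in df.itertuples(index=False):
        pid, drug = str(row.patient_id).strip(), str(row.drug).strip().lower()
        date, _ = parse_date(row.init_date, dialect=dialect, dayfirst=dayfirst)
        if not pid or date is None:
            warnings.warn(f"treatment row skipped (patient={pid!r}, init_date={row.init_date!r})")
            continue
        key = (pid, drug)
        if key in best:
            warnings.warn(f"duplicate treatment row for {key}; keeping earliest init_date")
            best[key] = min(best[key], date)
        else:
            best[key] = date
            order.append(key)
    return [TreatmentRecord(pid, drug, best[(pid, drug)]) for pid, drug in order]


def treatment_index(treatments: Iterable[TreatmentRecord], drug: Optional[str] = None) -> dict[str, dt.date]:
    """Map patient id -> initiation date, optionally restricted to one drug."""
    out: dict[str, dt.date] = {}
    for t in treatments:
        if drug is not None and t.drug != drug.lower():
            continue
        out[t.patient_id] = min(out.get(t.patient_id, t.init_date), t.init_date)
    return out


def filter_pre_treatment(
    corpus: NoteCorpus, treatments: Iterable[TreatmentRecord], drug: Optional[str] = None
) -> tuple[NoteCorpus, list[str]]:
    """Drop each patient's notes dated strictly before treatment initiation.

    Notes dated exactly on the initiation date are kept (baseline visits are
    often documented that day, and progression cannot precede day 0).
    Patients without a treatment record are excluded entirely.

    Returns the filtered corpus and the list of retained patients left with
    zero notes ("no follow-up"), who must be routed to manual review.
    """
    init = treatment_index(treatments, drug=drug)
    kept = [n for n in corpus if n.patient_id in init and n.date >= init[n.patient_id]]
    kept_ids = {n.patient_id for n in kept}
    no_follow_up = sorted(pid for pid in corpus.patients() if pid in init and pid not in kept_ids)
    return NoteCorpus(kept, rejects=corpus.rejects), no_follow_up


def read_structured_observations(path, kind: str, dialect: str = "auto", dayfirst: bool = True,
                                 progression_map: Optional[dict] = None):
    """Read structured PS or structured closed-question progression rows.

    ``kind="ps"`` rows become :class:`~clinotext.extract.PSObservation` with
    ``source="structured"``; out-of-range scores (outside ECOG 0-5) are
    rejected and reported.  ``kind="progression"`` rows map the closed-
    question answer onto a phase label (remission/stable -> BP,
    progression -> PP) via ``progression_map``.

    Returns ``(observations, rejects_frame)``.
    """
    from .extract import PhaseObservation, PSObservation

    if kind not in ("ps", "progression"):
        raise ConfigurationError(f"kind must be 'ps' or 'progression', got {kind!r}")
    pmap = {
        "remissie": "BP", "remission": "BP", "stabiel": "BP", "stable": "BP",
        "progressie": "PP", "progression": "PP",
    }
    pmap.update({k.lower(): v for k, v in (progression_map or {}).items()})
    df = _read_table(path)
    if df.empty:
        return [], _empty_rejects()
    df = _require_columns(df, ["patient_id", "date", "value"])
    obs, rej = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        pid = str(row.patient_id).strip()
        date, _ = parse_date(row.date, dialect=dialect, dayfirst=dayfirst)
        val = str(row.value).strip()
        if not pid or date is None:
            rej.append((i, pid, val, "bad patient_id or date"))
            continue
        if kind == "ps":
            try:
                score = int(float(val))
            except ValueError:
                rej.append((i, pid, val, "non-numeric PS"))
                continue
            if not 0 <= score <= 5:
                rej.append((i, pid, val, "PS outside 0-5"))
                continue
            obs.append(PSObservation(pid, date, score, source="structured", evidence=val))
        else:
            phase = pmap.get(val.lower())
            if phase is None:
                rej.append((i, pid, val, "unmapped progression answer"))
                continue
            obs.append(PhaseObservation(pid, date, phase, rule_id="structured", evidence=val))
    return obs, pd.DataFrame(rej, columns=["row", "patient_id", "value", "reason"])


def read_scan_table(path, dialect: str = "auto", dayfirst: bool = True) -> dict[str, list[dt.date]]:
    """Read the scan-date table into patient -> sorted scan dates."""
    df = _read_table(path)
    if df.empty:
        return {}
    df = _require_columns(df, ["patient_id", "scan_date"])
    out: dict[str, list[dt.date]] = {}
    for row in df.itertuples(index=False):
        pid = str(row.patient_id).strip()
        date, _ = parse_date(row.scan_date, dialect=dialect, dayfirst=dayfirst)
        if pid and date is not None:
            out.setdefault(pid, []).append(date)
    return {pid: sorted(v) for pid, v in out.items()}
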