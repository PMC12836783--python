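"""The rule engine: PS extraction and sentence phase classification.

Performance status (PS) is mined from aggressively normalized text with a
single pattern: a PS keyword ("ps", "who", "ecog", ...) immediately
followed by one or two digits, each a valid ECOG score (0-5).  Two digits
are read as a clinician's range ("WHO 1-2" normalizes to "who12" and yields
score 1 with secondary score 2) — never as a two-digit integer.  The strict
pattern deliberately misses two documented real-world failure modes: a
letter O written for the digit zero ("WHO O" normalizes to "whoo", no
digit, no match) and intervening words ("PS is 2" normalizes to "psis2",
letters between keyword and digit, no match under the default).  A relaxed
pattern tolerating a couple of short intervening words can be switched on
in the rule config; it ships off because silent false positives are worse
than documented misses in this setting.

Progression is located by classifying each sentence into one of three
phases — before progression (BP), around/possible progression (PP), after
progression (AP) — with prioritized regular-expression rules.  All
semantics, including negation ("geen progressie" is BP, not PP), live in
the rules: a negated-progression BP rule simply outranks the bare
progression-keyword PP rule.  Additionally, a sentence that pairs a
treatment-start pattern with a known post-progression drug is labelled AP:
starting a next anticancer line implies progression has occurred.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .preprocess import normalize_for_pfs, normalize_for_ps
from .tokenize import Sentence, split_sentences

DEFAULT_PS_KEYWORDS = ("ecog", "who", "ps", "performancestatus", "performance")
DEFAULT_START_PATTERNS = ("start", "gestart", "starten", "begonnen", "switch",
                          "started", "starting", "begin", "commenced")


@dataclass(frozen=True)
class PSObservation:
    """One performance-status value with its provenance."""

    patient_id: str
    date: dt.date
    score: int
    secondary_score: Optional[int] = None
    source: str = "mined"  # "mined" or "structured"
    evidence: str = ""
    note_source: str = ""

    def __post_init__(self):
        if not 0 <= self.score <= 5:
            raise ValueError(f"PS score {self.score} outside ECOG range 0-5")
        if self.secondary_score is not None:
            if not 0 <= self.secondary_score <= 5:
                raise ValueError("secondary PS score outside ECOG range 0-5")
            if abs(self.secondary_score - self.score) > 2:
                raise ValueError("implausible PS range (difference > 2)")

    def resolved_score(self, policy: str = "first") -> int:
        """Collapse a range onto one value: ``first`` (default; clinicians
        usually write best-worst) or ``worst``."""
        if self.secondary_score is None or policy == "first":
            return self.score
        return max(self.score, self.secondary_score)


@dataclass(frozen=True)
class DrugLexicon:
    """The drug of interest and the drugs that imply a later treatment line."""

    drug_of_interest: str
    interest_aliases: tuple[str, ...] = ()
    post_progression: tuple[str, ...] = ()
    post_progression_aliases: tuple[str, ...] = ()
    start_patterns: tuple[str, ...] = DEFAULT_START_PATTERNS

    def __post_init__(self):
        interest = {self.drug_of_interest.lower(), *(a.lower() for a in self.interest_aliases)}
        post = {p.lower() for p in self.post_progression} | {
            a.lower() for a in self.post_progression_aliases
        }
        clash = interest & post
        if clash:
            raise ValueError(f"alias(es) in both drug groups: {sorted(clash)}")

    def post_progression_terms(self) -> tuple[str, ...]:
        return tuple(
            sorted(
                {p.lower() for p in self.post_progression}
                | {a.lower() for a in self.post_progression_aliases},
                key=len,
                reverse=True,
            )
        )


@dataclass(frozen=True)
class PhaseRule:
    """One prioritized phase-classification rule."""

    rule_id: str
    phase: str  # BP | PP | AP
    pattern: str
    priority: int = 0

    def __post_init__(self):
        if self.phase not in ("BP", "PP", "AP"):
            raise ValueError(f"phase must be BP/PP/AP, got {self.phase!r}")
        try:
            re.compile(self.pattern)
        except re.error as exc:
            raise ValueError(f"rule {self.rule_id}: invalid pattern: {exc}") from exc

    def compiled(self) -> re.Pattern:
        return re.compile(self.pattern)


@dataclass(frozen=True)
class PhaseObservation:
    """One dated sentence-level phase label for a patient."""

    patient_id: str
    date: dt.date
    phase: str
    rule_id: str = ""
    evidence: str = ""

    def __post_init__(self):
        if self.phase not in ("BP", "PP", "AP"):
            raise ValueError(f"phase must be BP/PP/AP, got {self.phase!r}")


def _ps_pattern(keywords: Sequence[str], allow_intervening: bool) -> re.Pattern:
    alts = "|".join(re.escape(k.lower()) for k in sorted(keywords, key=len, reverse=True))
    if allow_intervening:
        # normalized text has no spaces: "ps is 2" -> "psis2"; tolerate a
        # couple of short words' worth of letters between keyword and digit
        gap = r"[a-z]{0,12}?"
    else:
        gap = ""
    return re.compile(rf"({alts}){gap}([0-5])([0-5])?(?!\d)")


def extract_ps_mentions(
    text: str,
    keywords: Sequence[str] = DEFAULT_PS_KEYWORDS,
    date: Optional[dt.date] = None,
    patient_id: str = "",
    allow_intervening_words: bool = False,
    note_source: str = "",
) -> list[PSObservation]:
    """Extract PS mentions from PS-normalized text.

    Matches are leftmost, non-overlapping.  Each match yields one
    observation; a second adjacent digit becomes the secondary score of a
    range when plausible (difference <= 2), otherwise only the first digit
    is kept.
    """
    pat = _ps_pattern(keywords, allow_intervening_words)
    out = []
    for m in pat.finditer(text):
        score = int(m.group(2))
        secondary = int(m.group(3)) if m.group(3) is not None else None
        if secondary is not None and abs(secondary - score) > 2:
            secondary = None
        out.append(
            PSObservation(
                patient_id=patient_id,
                date=date if date is not None else dt.date(1990, 1, 1),
                score=score,
                secondary_score=secondary,
                source="mined",
                evidence=m.group(0),
                note_source=note_source,
            )
        )
    return out


def _drug_start_rule(lexicon: DrugLexicon, priority: int = 90) -> Optional[PhaseRule]:
    terms = lexicon.post_progression_terms()
    if not terms:
        return None
    starts = "|".join(re.escape(s) for s in lexicon.start_patterns)
    drugs = "|".join(re.escape(t) for t in terms)
    # either order within the sentence: "start lorlatinib" / "lorlatinib gestart"
    pattern = rf"\b(?:{starts})\b.*\b(?:{drugs})\b|\b(?:{drugs})\b.*\b(?:{starts})\b"
    return PhaseRule(rule_id="drug_start_ap", phase="AP", pattern=pattern, priority=priority)


def classify_sentence(
    sentence: Sentence,
    rules: Sequence[PhaseRule],
    lexicon: Optional[DrugLexicon] = None,
    drug_start_priority: int = 90,
) -> Optional[PhaseObservation]:
    """Assign a BP/PP/AP phase to one sentence, or None.

    Rules are evaluated in descending priority; ties break on rule_id
    (lexicographically lowest wins).  The post-progression drug-start check
    participates as a synthesized AP rule at ``drug_start_priority``.
    """
    candidates = list(rules)
    if lexicon is not None:
        synth = _drug_start_rule(lexicon, priority=drug_start_priority)
        if synth is not None:
            candidates.append(synth)
    for rule in sorted(candidates, key=lambda r: (-r.priority, r.rule_id)):
        if rule.compiled().search(sentence.text):
            if sentence.date is None:
                raise ValueError("sentence from the PFS pipeline must carry a date")
            return PhaseObservation(
                patient_id=sentence.patient_id,
                date=sentence.date,
                phase=rule.phase,
                rule_id=rule.rule_id,
                evidence=sentence.text,
            )
    return None


def mine_corpus(corpus, mode: str, config, structured: Iterable = ()) -> list:
    """Run the full extraction over a corpus.

    ``mode="ps"``: PS normalization + PS mention extraction per note.
    ``mode="pfs"``: PFS normalization + sentence segmentation + phase
    classification per note.  Structured observations (from the structured
    PS / closed-question progression tables) are merged in unchanged; every
    observation carries its provenance.

    Deterministic: same corpus + config -> identical observation list.
    """
    if mode not in ("ps", "pfs"):
        raise ValueError(f"mode must be 'ps' or 'pfs', got {mode!r}")
    observations: list = list(structured)
    for note in corpus:
        if not note.text:
            continue
        if mode == "ps":
            norm = normalize_for_ps(note.text)
            observations.extend(
                extract_ps_mentions(
                    norm,
                    keywords=config.ps_keywords,
                    date=note.date,
                    patient_id=note.patient_id,
                    allow_intervening_words=config.ps_allow_intervening_words,
                    note_source=note.source,
                )
            )
        else:
            norm = normalize_for_pfs(note.text, abbrev=config.abbreviations, stopwords=config.stopwords)
            for sent in split_sentences(norm, patient_id=note.patient_id, date=note.date,
                                        min_space_run=config.min_space_run):
                obs = classify_sentence(sent, config.phase_rules, lexicon=config.drugs,
                                        drug_start_priority=config.drug_start_priority)
                if obs is not None:
                    observations.append(obs)
    return observations


def observations_frame(observations: Iterable) -> pd.DataFrame:
    """Extraction log: one row per observation, CSV-ready."""
    rows = []
    for o in observations:
        if isinstance(o, PSObservation):
            rows.append(
                {"patient_id": o.patient_id, "date": o.date.isoformat(), "type": "ps",
                 "value": o.score if o.secondary_score is None else f"{o.score}-{o.secondary_score}",
                 "source": o.source, "rule_id": "", "evidence": o.evidence}
            )
        else:
            rows.append(
                {"patient_id": o.patient_id, "date": o.date.isoformat(), "type": "phase",
                 "value": o.phase, "source": "structured" if o.rule_id == "structured" else "mined",
                 "rule_id": o.rule_id, "evidence": o.evidence}
            )
    return pd.DataFrame(rows, columns=["patient_id", "date", "type", "value", "source", "rule_id", "evidence"])
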