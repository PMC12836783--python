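"""Rule/lexicon configuration.

Everything the extraction engine matches on — PS keywords, abbreviation
expansions, removable stop words, phase rules, the drug lexicon — is data,
not code, so a site can retarget the pipeline (different drug of interest,
different language, local spelling habits) by editing a YAML file.  Two
starter configurations ship: an English one (default, so the synthetic
corpora are readable to most developers) and a Dutch one mirroring the
phrasing conventions of Dutch oncology notes.  Both are deliberately small:
rule discovery via the n-gram/concordance tools is part of the intended
workflow, and real deployments are expected to grow their own rule lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .extract import (DEFAULT_PS_KEYWORDS, DEFAULT_START_PATTERNS, DrugLexicon,
                      PhaseRule)
from .preprocess import (DEFAULT_PROTECTED, DEFAULT_REMOVABLE, AbbreviationMap,
                         StopwordPolicy)

#: starter abbreviation expansions (short form -> full form); period-bearing
#: short forms must be expanded before sentence segmentation
DEFAULT_ABBREVIATIONS = (
    ("osi", "osimertinib"),
    ("crizo", "crizotinib"),
    ("mg.", "mg"),
    ("pat.", "patient"),
    ("ca.", "circa"),
    ("tab.", "tablet"),
    ("dd.", "dagelijks"),
)

_RULES_EN = (
    PhaseRule("bp_no_progression", "BP", r"\bno (?:signs? of |evidence of )?progression\b", 100),
    PhaseRule("bp_stable", "BP", r"\bstable (?:disease|picture)\b|\bremission\b|\bpartial response\b|\bgood response\b", 40),
    PhaseRule("pp_progression", "PP", r"\bprogressi(?:on|ve)\b", 50),
    PhaseRule("pp_new_lesion", "PP", r"\bnew (?:lesions?|metastas[ei]s)\b", 50),
    PhaseRule("ap_after_progression", "AP", r"\bafter progression\b|\bpost-?progression\b", 60),
)

_RULES_NL = (
    PhaseRule("bp_geen_progressie", "BP", r"\bgeen (?:aanwijzingen voor |tekenen van )?progressie\b", 100),
    PhaseRule("bp_stabiel", "BP", r"\bstabiel(?:e)? (?:beeld|ziekte)\b|\bremissie\b|\bpartiele respons\b|\bpartiële respons\b", 40),
    PhaseRule("pp_progressie", "PP", r"\bprogressie(?:f|ve)?\b", 50),
    PhaseRule("pp_nieuwe_laesie", "PP", r"\bnieuwe (?:laesies?|metastasen?)\b|\btoename van\b", 50),
    PhaseRule("ap_na_progressie", "AP", r"\bna progressie\b", 60),
)

_DRUGS_DEFAULT = DrugLexicon(
    drug_of_interest="osimertinib",
    interest_aliases=("tagrisso",),
    post_progression=("lorlatinib", "carboplatin", "pemetrexed", "docetaxel", "brigatinib"),
    post_progression_aliases=("carboplatine", "lorla",),
    start_patterns=DEFAULT_START_PATTERNS,
)


@dataclass(frozen=True)
class RuleConfig:
    """The full, validated rule configuration consumed by the pipeline."""

    ps_keywords: tuple[str, ...] = DEFAULT_PS_KEYWORDS
    ps_allow_intervening_words: bool = False
    ps_range_policy: str = "first"  # or "worst"
    abbreviations: AbbreviationMap = field(
        default_factory=lambda: AbbreviationMap.from_pairs(DEFAULT_ABBREVIATIONS)
    )
    stopwords: StopwordPolicy = field(default_factory=StopwordPolicy)
    phase_rules: tuple[PhaseRule, ...] = _RULES_EN
    drugs: DrugLexicon = _DRUGS_DEFAULT
    drug_start_priority: int = 90
    min_space_run: int = 3
    date_dialect: str = "auto"
    dayfirst: bool = True
    baseline_window_before_days: int = 30
    baseline_window_after_days: int = 14
    confirm_window_days: int = 30
    scan_max_lag_days: int = 14
    language: str = "en"


def default_config(language: str = "en") -> RuleConfig:
    """Starter configuration for ``language`` ("en" or "nl")."""
    if language == "en":
        return RuleConfig()
    if language == "nl":
        return RuleConfig(phase_rules=_RULES_NL, language="nl")
    raise ValueError(f"no starter configuration for language {language!r}")


def config_from_dict(data: dict) -> RuleConfig:
    """Build a :class:`RuleConfig` from the YAML/JSON schema.

    Recognized keys: ``language``, ``ps.keywords``, ``ps.allow_intervening_words``,
    ``ps.range_policy``, ``abbreviations`` (mapping short -> full),
    ``stopwords.removable``, ``stopwords.protected``, ``phases.bp/pp/ap``
    (lists of {rule_id, pattern, priority}), ``drugs.of_interest``,
    ``drugs.interest_aliases``, ``drugs.post_progression``,
    ``drugs.post_progression_aliases``, ``drugs.start_patterns``,
    ``dates.dialect``, ``dates.dayfirst``, ``tokenizer.min_space_run``,
    ``windows.baseline_before/baseline_after/confirm/scan_lag``.
    Unspecified keys fall back to the starter configuration for the chosen
    language.
    """
    base = default_config(data.get("language", "en"))
    kwargs: dict = {}
    ps = data.get("ps", {})
    if "keywords" in ps:
        kwargs["ps_keywords"] = tuple(str(k).lower() for k in ps["keywords"])
    if "allow_intervening_words" in ps:
        kwargs["ps_allow_intervening_words"] = bool(ps["allow_intervening_words"])
    if "range_policy" in ps:
        kwargs["ps_range_policy"] = str(ps["range_policy"])
    if "abbreviations" in data:
        kwargs["abbreviations"] = AbbreviationMap.from_pairs(
            list(data["abbreviations"].items())
            if isinstance(data["abbreviations"], dict)
            else data["abbreviations"]
        )
    sw = data.get("stopwords", {})
    if sw:
        kwargs["stopwords"] = StopwordPolicy(
            removable=frozenset(sw.get("removable", DEFAULT_REMOVABLE)),
            protected=frozenset(sw.get("protected", DEFAULT_PROTECTED)),
        )
    phases = data.get("phases", {})
    if phases:
        rules = []
        for phase_key, phase in (("bp", "BP"), ("pp", "PP"), ("ap", "AP")):
            for r in phases.get(phase_key, []):
                rules.append(PhaseRule(r["rule_id"], phase, r["pattern"], int(r.get("priority", 0))))
        ids = [r.rule_id for r in rules]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate rule_id in phase rules")
        kwargs["phase_rules"] = tuple(rules)
    drugs = data.get("drugs", {})
    if drugs:
        kwargs["drugs"] = DrugLexicon(
            drug_of_interest=str(drugs.get("of_interest", base.drugs.drug_of_interest)).lower(),
            interest_aliases=tuple(str(a).lower() for a in drugs.get("interest_aliases", ())),
            post_progression=tuple(str(d).lower() for d in drugs.get("post_progression", ())),
            post_progression_aliases=tuple(
                str(a).lower() for a in drugs.get("post_progression_aliases", ())
            ),
            start_patterns=tuple(drugs.get("start_patterns", DEFAULT_START_PATTERNS)),
        )
    dates = data.get("dates", {})
    if "dialect" in dates:
        kwargs["date_dialect"] = dates["dialect"]
    if "dayfirst" in dates:
        kwargs["dayfirst"] = bool(dates["dayfirst"])
    tok = data.get("tokenizer", {})
    if "min_space_run" in tok:
        kwargs["min_space_run"] = int(tok["min_space_run"])
    win = data.get("windows", {})
    mapping = {"baseline_before": "baseline_window_before_days",
               "baseline_after": "baseline_window_after_days",
               "confirm": "confirm_window_days",
               "scan_lag": "scan_max_lag_days"}
    for k, attr in mapping.items():
        if k in win:
            kwargs[attr] = int(win[k])
    return replace(base, **kwargs)


def load_config(path) -> RuleConfig:
    """Load a rule configuration from a YAML (or JSON) file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level of the rule config must be a mapping")
    return config_from_dict(data)
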