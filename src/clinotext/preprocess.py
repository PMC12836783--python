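"""Text normalization pipelines.

Two deliberately different normalizations are used downstream:

* :func:`normalize_for_ps` — aggressive.  Performance-status mentions are
  written in many spacings and casings ("WHO 1", "ECOG: 2", "ps=1");
  lowercasing and stripping whitespace and punctuation (keeping only periods
  and commas, which delimit sentences and clauses) collapses them onto a
  handful of forms a single regular expression can match.

* :func:`normalize_for_pfs` — sentence-preserving.  Progression phrases are
  matched per sentence, so newlines must survive (the segmenter uses them),
  period-bearing abbreviations must be expanded before segmentation (a
  trailing "mg." is not a sentence end), and drug shorthands ("osi",
  "crizo") are expanded to canonical names so one rule set covers both
  spellings.  Stop-word removal is minimal on purpose: generic stop-word
  sets contain negation and hedging words ("no", "maybe") whose removal
  would flip the meaning of progression sentences, so only explicitly
  whitelisted articles are ever removed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

#: Dutch/English negation and hedging words that must never be removable.
DEFAULT_PROTECTED = frozenset(
    {"geen", "niet", "nee", "mogelijk", "misschien", "twijfel",
     "no", "not", "without", "maybe", "possible", "possibly", "doubt"}
)

DEFAULT_REMOVABLE = frozenset({"de", "het"})


@dataclass(frozen=True)
class AbbreviationMap:
    """Ordered short-form -> full-form expansions, matched on word
    boundaries, longest short form first, in a single left-to-right pass
    (produced text is never re-expanded)."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self):
        for short, full in self.entries:
            if short.lower() == full.lower():
                raise ValueError(f"abbreviation {short!r} expands to itself")

    @classmethod
    def from_pairs(cls, pairs: Iterable[Sequence[str]]) -> "AbbreviationMap":
        return cls(tuple((str(s), str(f)) for s, f in pairs))

    def pattern(self) -> re.Pattern | None:
        if not self.entries:
            return None
        shorts = sorted((s.lower() for s, _ in self.entries), key=len, reverse=True)
        alts = "|".join(re.escape(s) for s in shorts)
        # custom boundaries: short forms may end in "." which defeats \b
        return re.compile(rf"(?<![\w.])({alts})(?!\w)")

    def lookup(self) -> dict[str, str]:
        return {s.lower(): f.lower() for s, f in self.entries}


@dataclass(frozen=True)
class StopwordPolicy:
    """Words removable as whole tokens.  Construction rejects any overlap
    with the protected negation/hedging lexicon."""

    removable: frozenset[str] = DEFAULT_REMOVABLE
    protected: frozenset[str] = DEFAULT_PROTECTED

    def __post_init__(self):
        clash = set(self.removable) & set(self.protected)
        if clash:
            raise ValueError(f"stop words overlap the protected negation lexicon: {sorted(clash)}")


def normalize_for_ps(text: str) -> str:
    """Lowercase and strip whitespace and punctuation except "." and ",".

    Digits and letters (including accented letters, lowercased) are kept in
    order.  Unicode punctuation and symbol classes are removed, so hyphens
    vanish too: "WHO 1-2" -> "who12", which the extractor reads as a
    possible score range.  Idempotent.
    """
    # keep-set, not a drop-set: letters, decimal digits, "." and "," only
    return "".join(
        ch for ch in text.lower() if ch in ".," or ch.isalpha() or ch.isdigit()
    )


def normalize_for_pfs(
    text: str,
    abbrev: AbbreviationMap | None = None,
    stopwords: StopwordPolicy | None = None,
) -> str:
    """Lowercase, expand abbreviations, drop removable stop words.

    Newlines and interior space runs are preserved — both carry sentence-
    boundary signal for the segmenter.  Abbreviation expansion runs before
    stop-word removal and applies each entry at most once per occurrence.
    """
    stopwords = stopwords or StopwordPolicy()
    s = text.lower()
    if abbrev is not None:
        pat = abbrev.pattern()
        if pat is not None:
            table = abbrev.lookup()
            s = pat.sub(lambda m: table[m.group(1)], s)
    if stopwords.removable:
        alts = "|".join(re.escape(w) for w in sorted(stopwords.removable, key=len, reverse=True))
        # consume one trailing space so removal does not double the spacing
        s = re.sub(rf"\b({alts})\b ?", "", s)
    # trim line edges only: interior space runs are sentence-boundary signal
    return "\n".join(ln.strip() for ln in s.split("\n"))
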