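"""Sentence segmentation and n-gram/concordance utilities.

Clinical text is punctuation-poor: authors end sentences with newlines or
wide whitespace at least as often as with a period, so off-the-shelf
sentence tokenizers mis-segment it.  The segmenter here uses three explicit
boundary rules tuned to that style:

1. ``.``, ``?`` or ``!`` followed by whitespace or end of text (a period
   between digits, as in "1.5", is therefore never a boundary);
2. any newline;
3. a run of three or more consecutive spaces (two spaces are common after
   manual edits and do not mark a boundary; the threshold is configurable).

The n-gram counter and keyword-in-context concordance support the rule
discovery workflow: scan a corpus for frequent phrases around a pattern,
then promote the productive ones to extraction rules.
"""

from __future__ import annotations

import datetime as dt
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Pattern, Union

import pandas as pd


@dataclass(frozen=True)
class Sentence:
    """One segmented sentence, with its provenance."""

    text: str
    patient_id: str = ""
    date: Optional[dt.date] = None
    index: int = 0


def _boundary_pattern(min_space_run: int) -> re.Pattern:
    return re.compile(rf"[.?!](?=\s|$)|\n| {{{min_space_run},}}")


def split_sentences(
    text: str,
    patient_id: str = "",
    date: Optional[dt.date] = None,
    min_space_run: int = 3,
) -> list[Sentence]:
    """Segment normalized text into sentences.

    Expects text that already passed PFS normalization (period-bearing
    abbreviations expanded).  Boundary characters are not part of any
    sentence; empty fragments are discarded.
    """
    if min_space_run < 1:
        raise ValueError("min_space_run must be >= 1")
    fragments = _boundary_pattern(min_space_run).split(text)
    out = []
    for frag in fragments:
        frag = frag.strip()
        if frag:
            out.append(Sentence(frag, patient_id=patient_id, date=date, index=len(out)))
    return out


@dataclass
class NgramTable:
    """Counts of contiguous n-token windows (whitespace tokens)."""

    n: int
    counts: Counter = field(default_factory=Counter)
    tag: str = ""

    @property
    def total(self) -> int:
        # for unigrams this equals the token count of the scanned text
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"ngram": " ".join(gram), "count": c}
            for gram, c in sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ]
        return pd.DataFrame(rows, columns=["ngram", "count"])


def ngram_counts(sentences: Iterable[Union[Sentence, str]], n: int, tag: str = "") -> NgramTable:
    """Count every contiguous length-``n`` token window per sentence.

    Windows never cross sentence boundaries.  Tokens are whitespace-
    delimited; no stemming or further normalization is applied.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    table = NgramTable(n=n, tag=tag)
    for s in sentences:
        tokens = (s.text if isinstance(s, Sentence) else s).split()
        for i in range(len(tokens) - n + 1):
            table.counts[tuple(tokens[i : i + n])] += 1
    return table


@dataclass(frozen=True)
class ConcordanceRow:
    match: str
    left: str
    right: str
    patient_id: str
    date: Optional[dt.date]


def concordance(
    sentences: Iterable[Union[Sentence, str]],
    pattern: Union[str, Pattern],
    window: int = 5,
) -> list[ConcordanceRow]:
    """Keyword-in-context listing: one row per match with up to ``window``
    tokens of context on each side."""
    try:
        pat = re.compile(pattern) if isinstance(pattern, str) else pattern
    except re.error as exc:
        raise ValueError(f"invalid pattern: {exc}") from exc
    rows = []
    for s in sentences:
        if isinstance(s, str):
            s = Sentence(s)
        for m in pat.finditer(s.text):
            before, after = s.text[: m.start()], s.text[m.end() :]
            left = before.split()
            if before and not before[-1].isspace() and left:
                left = left[:-1]  # partial token belongs to the match
            right = after.split()
            if after and not after[0].isspace() and right:
                right = right[1:]
            left = left[-window:] if window else []
            right = right[:window] if window else []
            rows.append(
                ConcordanceRow(
                    match=m.group(0),
                    left=" ".join(left),
                    right=" ".join(right),
                    patient_id=s.patient_id,
                    date=s.date,
                )
            )
    return rows
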