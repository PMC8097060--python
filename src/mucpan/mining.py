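"""Keyword flagging of pathology-report text.

Candidate mucinous cases are triaged by case-insensitive substring search for
a small keyword list — by default ``mucin``, ``mucous`` and ``colloid`` — so
that e.g. "mucinous" and "MUCIN-PRODUCING" both hit "mucin".  No stemming and
no negation detection is attempted: a report saying "no mucinous features
identified" is flagged, and the surrounding context string is reported so a
reviewer can resolve such false positives, mirroring a manual-inspection
triage step.  Text is NFKC-normalized before matching to absorb OCR-style
unicode artifacts (ligatures, full-width characters).
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["DEFAULT_KEYWORDS", "KeywordMatch", "MiningFlag", "flag_mucinous", "flag_reports"]

DEFAULT_KEYWORDS: tuple[str, ...] = ("mucin", "mucous", "colloid")

#: characters of context reported on each side of a match
CONTEXT_CHARS = 40


@dataclass(frozen=True)
class KeywordMatch:
    keyword: str
    offset: int  # character offset into the NFKC-normalized text
    context: str


@dataclass(frozen=True)
class MiningFlag:
    sample_id: str
    flagged: bool
    matches: tuple[KeywordMatch, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.flagged != bool(self.matches):
            raise ValueError("flagged must be true iff matches is non-empty")


def flag_mucinous(text: str, keywords=DEFAULT_KEYWORDS, sample_id: str = "") -> MiningFlag:
    """Flag a single report by case-insensitive substring matching.

    Every occurrence of every keyword is reported with its character offset
    and +/-40 characters of context.  Deterministic; matches are ordered by
    offset then keyword.
    """
    if text is None:
        raise ValueError("text must not be None")
    keywords = tuple(keywords)
    if not keywords:
        raise ValueError("keywords must be non-empty")
    for kw in keywords:
        if not kw:
            raise ValueError("empty keyword string is not allowed")

    norm = unicodedata.normalize("NFKC", text)
    low = norm.casefold()
    matches: list[KeywordMatch] = []
    for kw in keywords:
        kwl = unicodedata.normalize("NFKC", kw).casefold()
        start = 0
        while (pos := low.find(kwl, start)) != -1:
            ctx = norm[max(0, pos - CONTEXT_CHARS) : pos + len(kwl) + CONTEXT_CHARS]
            matches.append(KeywordMatch(kw, pos, ctx))
            start = pos + 1
    matches.sort(key=lambda m: (m.offset, m.keyword))
    return MiningFlag(sample_id, bool(matches), tuple(matches))


def flag_reports(reports: dict[str, str], keywords=DEFAULT_KEYWORDS) -> pd.DataFrame:
    """Flag a whole cohort; one output row per match (or one unflagged row).

    Columns: sample_id, flagged, keyword, offset, context.
    """
    rows = []
    for sid in sorted(reports):
        flag = flag_mucinous(reports[sid], keywords, sample_id=sid)
        if flag.matches:
            for m in flag.matches:
                rows.append((sid, True, m.keyword, m.offset, m.context))
        else:
            rows.append((sid, False, "", -1, ""))
    return pd.DataFrame(rows, columns=["sample_id", "flagged", "keyword", "offset", "context"])
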