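"""Locating report sections and extracting diagnosis / location spans.

A pathology report is a run of named sections (DIAGNOSIS, PROGNOSIS,
CLINICAL HISTORY, HISTOLOGY, COMMENTS — or the cytology-dialect
equivalents). The diagnosis text sits between the diagnosis keyword and the
first of PROGNOSIS / CLINICAL HISTORY; the lesion location can appear in up
to three places, ranked: next to the diagnosis, in the clinical history, or
in the histology section.

Keyword matching is deliberately simple: case-insensitive substring search,
first occurrence wins, no word-boundary anchoring. That mirrors the
mechanism of the source system and is a documented source of false keyword
hits. Exports carry markup remnants (``<br>``, ``&nbsp;``, stray ``>``);
these are normalized to single spaces in one preprocessing pass so that
character positions are stable, and all spans refer to the normalized text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .config import DialectKeywords
from .ingest import EPRRecord

_BR = re.compile(r"<\s*br\s*/?\s*>", re.IGNORECASE)
_ENTITY = re.compile(r"&[a-z]+;", re.IGNORECASE)
_ANGLE = re.compile(r"[<>]")
_WS = re.compile(r"\s+")


def normalize_markup(text: str) -> str:
    """Replace markup remnants with spaces and collapse whitespace runs."""
    text = _BR.sub(" ", text)
    text = _ENTITY.sub(" ", text)
    text = _ANGLE.sub(" ", text)
    return _WS.sub(" ", text).strip()


def locate_keyword(text: str, phrases: Sequence[str]) -> Optional[int]:
    """Smallest 1-based position at which any phrase occurs (else None).

    Case-insensitive plain substring search over all phrases; the earliest
    occurrence across phrases wins.
    """
    hit = _locate(text, phrases)
    return None if hit is None else hit[0]


def _locate(text: str, phrases: Sequence[str]) -> Optional[tuple[int, str]]:
    """(1-based position, matched phrase) of the earliest phrase occurrence.

    Ties at the same position go to the longest phrase so that a compound
    keyword ("MORPHOLOGICAL DIAGNOSIS") beats its own suffix.
    """
    if not phrases:
        raise ValueError("phrases must be non-empty")
    folded = text.casefold()
    best: Optional[tuple[int, str]] = None
    for phrase in phrases:
        pos = folded.find(phrase.casefold())
        if pos < 0:
            continue
        if best is None or pos + 1 < best[0] or (
                pos + 1 == best[0] and len(phrase) > len(best[1])):
            best = (pos + 1, phrase)
    return best


@dataclass(frozen=True)
class LocationCandidate:
    """One candidate source span for the lesion location, with priority rank
    1 (diagnosis-adjacent) / 2 (clinical history) / 3 (histology)."""

    rank: int
    start: int  # 1-based, half-open [start, end)
    end: int
    text: str


@dataclass(frozen=True)
class SectionSpans:
    """Keyword positions and extracted spans for one report.

    All indices are 1-based character positions into ``text`` (the
    markup-normalized report text); intervals are half-open.
    """

    text: str
    diagnosis: Optional[tuple[int, int]]
    prognosis_pos: Optional[int]
    clinical_history_pos: Optional[int]
    histology_pos: Optional[int]
    comments_pos: Optional[int]
    location_candidates: tuple[LocationCandidate, ...] = field(default=())

    @property
    def diagnosis_text(self) -> str:
        if self.diagnosis is None:
            return ""
        start, end = self.diagnosis
        return self.text[start - 1:end - 1]


def _span_between(text: str, start_hit: Optional[tuple[int, str]],
                  *end_positions: Optional[int]) -> Optional[tuple[int, int]]:
    """Half-open 1-based span from the end of a keyword hit to the earliest
    following keyword position (or end of text)."""
    if start_hit is None:
        return None
    start = start_hit[0] + len(start_hit[1])
    ends = [p for p in end_positions if p is not None and p > start]
    end = min(ends) if ends else len(text) + 1
    return (start, end)


def locate_sections(record: EPRRecord, keywords: DialectKeywords) -> SectionSpans:
    """Find every section keyword and derive diagnosis/location spans."""
    text = normalize_markup(record.report_text)
    diag_hit = _locate(text, keywords.diagnosis_start)
    prog = locate_keyword(text, keywords.prognosis)
    ch = locate_keyword(text, keywords.clinical_history)
    histo = locate_keyword(text, keywords.histology)
    comments = locate_keyword(text, keywords.comments)

    diagnosis = _span_between(text, diag_hit, prog, ch)

    candidates: list[LocationCandidate] = []
    if diagnosis is not None:
        candidates.append(LocationCandidate(
            1, diagnosis[0], diagnosis[1],
            text[diagnosis[0] - 1:diagnosis[1] - 1]))
    ch_hit = _locate(text, keywords.clinical_history) if ch is not None else None
    ch_span = _span_between(text, ch_hit, histo, comments)
    if ch_span is not None:
        candidates.append(LocationCandidate(
            2, ch_span[0], ch_span[1], text[ch_span[0] - 1:ch_span[1] - 1]))
    histo_hit = _locate(text, keywords.histology) if histo is not None else None
    histo_span = _span_between(text, histo_hit, comments)
    if histo_span is not None:
        candidates.append(LocationCandidate(
            3, histo_span[0], histo_span[1],
            text[histo_span[0] - 1:histo_span[1] - 1]))

    return SectionSpans(
        text=text,
        diagnosis=diagnosis,
        prognosis_pos=prog,
        clinical_history_pos=ch,
        histology_pos=histo,
        comments_pos=comments,
        location_candidates=tuple(candidates),
    )


def extract_diagnosis_section(record: EPRRecord,
                              keywords: DialectKeywords) -> str:
    """Text between the diagnosis keyword and the first of PROGNOSIS /
    CLINICAL HISTORY; to end of text if neither terminator exists; empty if
    there is no diagnosis keyword (the report is later discarded if it also
    yields no tumour)."""
    return locate_sections(record, keywords).diagnosis_text


def extract_location_candidates(
        record: EPRRecord,
        keywords: DialectKeywords) -> tuple[LocationCandidate, ...]:
    """Up to three ranked location source spans (missing sections yield
    missing candidates; ranks are preserved)."""
    return locate_sections(record, keywords).location_candidates
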