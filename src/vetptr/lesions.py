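"""Splitting a diagnosis span into individual lesions.

Multi-tumour submissions almost always list one diagnosis per delimiter:
numbered ("1." to "6.") or lettered ("A" to "F") items. At most six lesions
are looked for; anything after a hypothetical seventh marker stays attached
to the sixth lesion. Undelimited multi-tumour phrasings ("Seminoma in both
testicles") are deliberately *not* recovered: they are a documented failure
mode of the method and the validation module measures them.

Numeric markers are matched as digit + "." so that grades written without a
dot ("grade 2") are not mistaken for delimiters. Alphabetic markers are
uppercase standalone tokens, optionally suffixed "." or ")"; the sequence
must start "A" then "B" so the article "A" alone never counts as a marker.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

MAX_LESIONS = 6

_ALPHA_MARKERS = "ABCDEF"


@dataclass(frozen=True)
class LesionText:
    """The free text of one separated lesion and its ordinal in the report."""

    report_ref: str
    ordinal: int  # 1..6, contiguous within a report
    text: str


def _find_numeric_markers(span: str) -> list[tuple[int, int]]:
    """(start, end) of markers "1." .. "6." found in order, each searched
    after the previous one."""
    markers: list[tuple[int, int]] = []
    offset = 0
    for i in range(1, MAX_LESIONS + 1):
        pos = span.find(f"{i}.", offset)
        if pos < 0:
            break
        markers.append((pos, pos + 2))
        offset = pos + 2
    return markers


def _alpha_pattern(letter: str) -> re.Pattern[str]:
    # uppercase standalone token, optionally suffixed "." or ")"
    return re.compile(rf"(?:(?<=^)|(?<=[\s:;,])){letter}(?:[.)]|(?=\s))")


def _find_alpha_markers(span: str) -> list[tuple[int, int]]:
    markers: list[tuple[int, int]] = []
    offset = 0
    for letter in _ALPHA_MARKERS:
        m = _alpha_pattern(letter).search(span, offset)
        if m is None:
            break
        markers.append((m.start(), m.end()))
        offset = m.end()
    return markers


def detect_delimiter_style(diagnosis_span: str) -> str:
    """``numeric`` if "1." occurs with "2." after it; else ``alphabetic`` if
    the marker sequence A, B ... is present; else ``none``."""
    numeric = _find_numeric_markers(diagnosis_span)
    if len(numeric) >= 2:
        return "numeric"
    if len(_find_alpha_markers(diagnosis_span)) >= 2:
        return "alphabetic"
    return "none"


def partition(diagnosis_span: str) -> tuple[str, list[tuple[str, str]]]:
    """Exact partition of the span into (preamble, [(marker, chunk), ...]).

    Concatenating preamble + every marker + chunk reconstructs the span
    verbatim; ``split_lesions`` is this partition plus trimming.
    """
    style = detect_delimiter_style(diagnosis_span)
    if style == "numeric":
        markers = _find_numeric_markers(diagnosis_span)
    elif style == "alphabetic":
        markers = _find_alpha_markers(diagnosis_span)
    else:
        return "", [("", diagnosis_span)]
    parts: list[tuple[str, str]] = []
    preamble = diagnosis_span[:markers[0][0]]
    for k, (start, end) in enumerate(markers):
        chunk_end = markers[k + 1][0] if k + 1 < len(markers) else len(diagnosis_span)
        parts.append((diagnosis_span[start:end], diagnosis_span[end:chunk_end]))
    return preamble, parts


def split_lesions(diagnosis_span: str, report_ref: str = "") -> list[LesionText]:
    """Separate a diagnosis span into 1..6 lesions.

    Without delimiters the whole span is one lesion. Lesions are trimmed of
    surrounding whitespace and stray punctuation left over from markup
    removal; empty chunks are dropped and ordinals renumbered contiguously.
    """
    if not diagnosis_span.strip():
        return []
    _, parts = partition(diagnosis_span)
    lesions: list[LesionText] = []
    for _, chunk in parts:
        text = chunk.strip().strip(";,").strip()
        if text:
            lesions.append(LesionText(report_ref, len(lesions) + 1, text))
    if not lesions:
        # span was nothing but markers/whitespace; keep it as one lesion
        lesions = [LesionText(report_ref, 1, diagnosis_span.strip())]
    return lesions
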