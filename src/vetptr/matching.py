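"""Ordered first-match lexicon lookup: the heart of the extraction.

Six curated look-up tables — primary tumour, two-tier grade, three-tier
grade, differentiation, uncertainty terms, location — are scanned top-down
for every lesion. The *first entry in list order* that occurs anywhere in
the text wins, so curators enforce specificity by placing specific phrases
("Mixed mammary gland tumour") above generic capture terms ("Tumour").
Matching is case-insensitive substring search without word boundaries; the
resulting false-positive class (an abbreviation inside another token) is a
property of the method and is measured, not patched, by the validation
module.

The lexicon file format is one surface form per line, order = priority,
with optional tab-separated flags:

* ``excluded`` — the lesion matches but is not a registrable neoplasm
  (hamartomas, cysts, tumour-like masses);
* ``maps_to=<preferred>`` — a normalization pairing (e.g. the adjective
  "cutaneous" mapping onward to "Skin") consumed by the normalizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .lesions import LesionText
from .sections import LocationCandidate

CATEGORIES = (
    "primary_tumour",
    "grade_2_tier",
    "grade_3_tier",
    "differentiation",
    "uncertainty",
    "location",
)


@dataclass(frozen=True)
class LexiconEntry:
    surface: str
    excluded: bool = False
    maps_to: Optional[str] = None


@dataclass
class Lexicon:
    """An ordered list of surface forms for one category.

    Order is meaningful: earlier entries have higher match priority.
    Entries must be unique after case-folding.
    """

    category: str
    entries: list[LexiconEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown lexicon category {self.category!r}")
        seen: set[str] = set()
        for e in self.entries:
            key = e.surface.casefold()
            if key in seen:
                raise ValueError(
                    f"duplicate entry {e.surface!r} in {self.category} lexicon")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.entries)

    def surfaces(self) -> list[str]:
        return [e.surface for e in self.entries]

    def entry(self, surface: str) -> LexiconEntry:
        key = surface.casefold()
        for e in self.entries:
            if e.surface.casefold() == key:
                return e
        raise KeyError(surface)

    def mapping_pairs(self) -> dict[str, str]:
        """surface → preferred pairs declared via ``maps_to`` flags."""
        return {e.surface: e.maps_to for e in self.entries if e.maps_to}

    @classmethod
    def from_file(cls, path: Path | str, category: str) -> "Lexicon":
        entries = []
        for line in Path(path).read_text("utf-8").splitlines():
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            surface = fields[0].strip()
            excluded = False
            maps_to = None
            for flag in fields[1:]:
                flag = flag.strip()
                if flag == "excluded":
                    excluded = True
                elif flag.startswith("maps_to="):
                    maps_to = flag[len("maps_to="):]
                elif flag:
                    raise ValueError(f"unknown lexicon flag {flag!r} in {path}")
            entries.append(LexiconEntry(surface, excluded, maps_to))
        return cls(category=category, entries=entries)


def first_match(text: str, lexicon: Lexicon) -> Optional[str]:
    """First lexicon entry (by list order, not text position) occurring
    case-insensitively as a substring of ``text``; None if none occurs."""
    if not len(lexicon):
        raise ValueError("lexicon must be non-empty")
    folded = text.casefold()
    for e in lexicon.entries:
        if e.surface.casefold() in folded:
            return e.surface
    return None


@dataclass(frozen=True)
class RawAnnotation:
    """Matched surface forms for one lesion (at most one per category)."""

    tumour_ref: str
    lesion_text: str
    primary_tumour: Optional[str] = None
    grade_2_tier: Optional[str] = None
    grade_3_tier: Optional[str] = None
    differentiation: Optional[str] = None
    uncertainty: Optional[str] = None
    location: Optional[str] = None
    location_source_rank: Optional[int] = None


def annotate_lesion(
    lesion: LesionText,
    location_candidates: Sequence[LocationCandidate],
    lexicons: dict[str, Lexicon],
) -> RawAnnotation:
    """Match all six categories for one lesion.

    Five categories search the lesion text itself. Location searches the
    lesion text first (the diagnosis-adjacent source, rank 1), then the
    clinical-history span (rank 2), then the histology span (rank 3),
    recording the rank of the first source that yields a match.
    """
    missing = [c for c in CATEGORIES if c not in lexicons]
    if missing:
        raise ValueError(f"missing lexicons for categories: {missing}")

    location = None
    rank = None
    sources: list[tuple[int, str]] = [(1, lesion.text)]
    for cand in location_candidates:
        if cand.rank >= 2:
            sources.append((cand.rank, cand.text))
    for r, source in sources:
        m = first_match(source, lexicons["location"])
        if m is not None:
            location, rank = m, r
            break

    return RawAnnotation(
        tumour_ref=lesion.report_ref,
        lesion_text=lesion.text,
        primary_tumour=first_match(lesion.text, lexicons["primary_tumour"]),
        grade_2_tier=first_match(lesion.text, lexicons["grade_2_tier"]),
        grade_3_tier=first_match(lesion.text, lexicons["grade_3_tier"]),
        differentiation=first_match(lesion.text, lexicons["differentiation"]),
        uncertainty=first_match(lesion.text, lexicons["uncertainty"]),
        location=location,
        location_source_rank=rank,
    )


def is_registrable_tumour(annotation: RawAnnotation,
                          primary_lexicon: Lexicon) -> bool:
    """True iff the primary match is a neoplasm (not an excluded entry:
    hamartomas, cysts, tumour-like masses). Reports with zero registrable
    tumours are discarded downstream."""
    if annotation.primary_tumour is None:
        return False
    return not primary_lexicon.entry(annotation.primary_tumour).excluded


def sample_unmatched(
    annotations: Iterable[RawAnnotation],
    category: str,
    n: int,
    seed: int,
) -> list[str]:
    """Seeded uniform sample (without replacement) of up to ``n`` lesion
    texts whose given category is unmatched.

    Supports the human-in-the-loop lexicon-growth workflow: batches of
    unmatched texts are read and any newly identified terms added to the
    lexicon, iterating until a batch yields no new terms.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    pool = [a.lesion_text for a in annotations if getattr(a, category) is None]
    rng = np.random.default_rng(seed)
    if len(pool) <= n:
        return pool
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]
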