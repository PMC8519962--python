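"""Laboratory dialect configuration.

Submitting laboratories differ in the section keywords they print in a
report ("DIAGNOSIS" on a histology report, "CYTOLOGICAL INTERPRETATION" on a
cytology one) and in the assay codes that identify histology vs cytology
submissions. Those conventions are data, not code: they live in a plain-text
YAML file with one block per laboratory dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

ASSAY_TYPES = ("histology", "cytology")


@dataclass(frozen=True)
class DialectKeywords:
    """Section keyword phrases for one (laboratory, assay type) pair.

    Phrases are stored uppercase; matching downstream is case-insensitive
    substring search, so case here is purely cosmetic.
    """

    diagnosis_start: tuple[str, ...]
    prognosis: tuple[str, ...]
    clinical_history: tuple[str, ...]
    histology: tuple[str, ...]
    comments: tuple[str, ...]

    def __post_init__(self) -> None:
        for name in ("diagnosis_start", "prognosis", "clinical_history",
                     "histology", "comments"):
            phrases = getattr(self, name)
            if not phrases:
                raise ValueError(f"keyword list {name!r} must be non-empty")
            object.__setattr__(self, name, tuple(p.upper() for p in phrases))


@dataclass(frozen=True)
class LabDialect:
    """One laboratory's keyword conventions and assay-code map."""

    name: str
    # ordered (token, assay_type) pairs; first token contained in the
    # uppercased assay code wins
    assay_codes: tuple[tuple[str, str], ...]
    keywords: dict[str, DialectKeywords] = field(default_factory=dict)

    def assay_type(self, assay_code: str) -> str:
        code = (assay_code or "").upper()
        for token, assay in self.assay_codes:
            if token.upper() in code:
                return assay
        return "histology"

    def keywords_for(self, assay_type: str) -> DialectKeywords:
        if assay_type not in self.keywords:
            raise KeyError(
                f"dialect {self.name!r} has no keywords for {assay_type!r}")
        return self.keywords[assay_type]


def _parse_dialect(name: str, block: dict) -> LabDialect:
    codes = tuple((str(tok), str(assay)) for tok, assay in block["assay_codes"])
    for _, assay in codes:
        if assay not in ASSAY_TYPES:
            raise ValueError(f"unknown assay type {assay!r} in dialect {name!r}")
    keywords = {
        assay: DialectKeywords(
            diagnosis_start=tuple(kw["diagnosis_start"]),
            prognosis=tuple(kw["prognosis"]),
            clinical_history=tuple(kw["clinical_history"]),
            histology=tuple(kw["histology"]),
            comments=tuple(kw["comments"]),
        )
        for assay, kw in block["keywords"].items()
    }
    return LabDialect(name=name, assay_codes=codes, keywords=keywords)


def load_dialects(path: Optional[Path | str] = None) -> dict[str, LabDialect]:
    """Load dialect blocks from ``path`` or the bundled default config."""
    if path is None:
        path = Path(__file__).parent / "data" / "dialects.yaml"
    text = Path(path).read_text("utf-8")
    raw = yaml.safe_load(text)
    return {name: _parse_dialect(name, block)
            for name, block in raw["dialects"].items()}


def default_dialect() -> LabDialect:
    return load_dialects()["default"]
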