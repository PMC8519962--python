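"""Mapping matched surface forms and animal metadata to preferred terms.

Pathologists refer to the same tumour in many ways (an adenoma of the
hepatoid glands appears under six different names in the source data);
locations, grades and breeds show the same diversity. Normalization is an
exact case-folded, whitespace-trimmed lookup of surface form → preferred
term. Unmapped surfaces pass through *unchanged* and are logged — visible
pass-through supports the iterative curation loop, silent "other" buckets
would hide it. No normalization step ever drops a record; it only relabels.

Dog breeds follow FCI/AKC naming, cat breeds FIFE/TICA, augmented with
popular hybrids (labradoodle); the authority tables are editable data
files, bundled as skeletons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

from .matching import Lexicon, RawAnnotation

logger = logging.getLogger(__name__)

DOMAINS = ("tumour_type", "location", "grade", "differentiation",
           "breed_dog", "breed_cat", "gender")

#: the six catch-all labels a normalized annotation may aggregate into
CATCH_ALL_TERMS = (
    "Carcinoma_others",
    "Adenoma_others",
    "Epithelioma_others",
    "Epithelial tumour_others",
    "Mesenchymal_neoplasias_others",
    "Neoplasia_Tumours_others",
)

_SEX_TOKENS = {"female": "female", "f": "female", "male": "male", "m": "male"}
_NEUTER_TOKENS = {
    "entire": "entire", "intact": "entire",
    "neutered": "neutered", "neuter": "neutered",
    "spayed": "neutered", "castrated": "neutered",
}


def _fold(surface: str) -> str:
    return " ".join(surface.split()).casefold()


@dataclass
class NormalizationMap:
    """Surface form → preferred term for one domain.

    Every preferred term is a fixed point: unmapped surfaces (preferred
    terms included) pass through unchanged.
    """

    domain: str
    pairs: dict[str, str] = field(default_factory=dict)  # folded surface → preferred

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown normalization domain {self.domain!r}")
        self.pairs = {_fold(k): v for k, v in self.pairs.items()}

    @classmethod
    def from_file(cls, path: Path | str, domain: str) -> "NormalizationMap":
        """Load a two-column tab-separated (surface, preferred) file."""
        pairs: dict[str, str] = {}
        for line in Path(path).read_text("utf-8").splitlines():
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            surface, preferred = line.rstrip("\n").split("\t")[:2]
            pairs[surface.strip()] = preferred.strip()
        return cls(domain=domain, pairs=pairs)

    @classmethod
    def from_lexicon(cls, lexicon: Lexicon, domain: str) -> "NormalizationMap":
        """Build a map from a lexicon's ``maps_to`` flags."""
        return cls(domain=domain, pairs=lexicon.mapping_pairs())

    def merged_with(self, other: "NormalizationMap") -> "NormalizationMap":
        merged = dict(self.pairs)
        merged.update(other.pairs)
        out = NormalizationMap(domain=self.domain)
        out.pairs = merged
        return out


def normalize_term(surface: str, nmap: NormalizationMap) -> str:
    """Exact (case-folded, trimmed) lookup; unmapped surfaces pass through
    unchanged and are logged for curation."""
    if not nmap.pairs:
        raise ValueError("normalization map must be non-empty")
    key = _fold(surface)
    if key in nmap.pairs:
        return nmap.pairs[key]
    if surface.strip() and surface.strip() not in nmap.pairs.values():
        logger.debug("unmapped %s surface %r passed through", nmap.domain, surface)
    return surface.strip()


def normalize_breed(surface: str, species: str,
                    maps: dict[str, NormalizationMap]) -> str:
    """Map a raw breed label to the authority name; empty/unknown → "unknown"
    with the raw label logged."""
    if species not in ("canine", "feline"):
        raise ValueError(f"species must be canine or feline, got {species!r}")
    nmap = maps["breed_dog" if species == "canine" else "breed_cat"]
    key = _fold(surface)
    if not key or key in ("unknown", "?", "n/a", "na"):
        return "unknown"
    if key in nmap.pairs:
        return nmap.pairs[key]
    if surface.strip() in nmap.pairs.values():
        return surface.strip()
    logger.debug("unmapped %s breed %r passed through", species, surface)
    return surface.strip()


def parse_gender(surface: str) -> tuple[str, str]:
    """Split a gender phrase like "Female entire" into (sex, neuter status);
    unrecognized tokens yield ("unknown", "unknown")."""
    sex = "unknown"
    neuter = "unknown"
    for token in surface.replace("-", " ").split():
        t = token.strip(".,").lower()
        if t in _SEX_TOKENS and sex == "unknown":
            sex = _SEX_TOKENS[t]
        elif t in _NEUTER_TOKENS and neuter == "unknown":
            neuter = _NEUTER_TOKENS[t]
    return sex, neuter


def format_gender(sex: str, neuter: str) -> str:
    """Render (sex, neuter) back to the registry's Gender phrase."""
    if sex == "unknown":
        return "unknown"
    if neuter == "unknown":
        return sex.capitalize()
    return f"{sex.capitalize()} {neuter}"


@dataclass
class AggregationRules:
    """Named aggregations and catch-all assignments for tumour types.

    ``named`` maps a preferred term to its registry label unconditionally
    (plasmacytomas and multiple myelomas aggregate under "Plasma cell
    tumour"; generic capture terms go to their catch-all). The optional
    corpus-level rare-type pass sends any type occurring fewer than
    ``min_count`` times to a catch-all inferred from its name.
    """

    named: dict[str, str] = field(default_factory=dict)
    min_count: int = 10

    def __post_init__(self) -> None:
        self.named = {_fold(k): v for k, v in self.named.items()}

    @classmethod
    def from_file(cls, path: Path | str, min_count: int = 10) -> "AggregationRules":
        named: dict[str, str] = {}
        for line in Path(path).read_text("utf-8").splitlines():
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            preferred, label = line.rstrip("\n").split("\t")[:2]
            named[preferred.strip()] = label.strip()
        return cls(named=named, min_count=min_count)

    def catch_all_for(self, preferred: str) -> str:
        """Catch-all label for a rare type, inferred from its name."""
        name = preferred.casefold()
        if "adenocarcinoma" in name or "carcinoma" in name:
            return "Carcinoma_others"
        if "adenoma" in name:
            return "Adenoma_others"
        if "epithelioma" in name:
            return "Epithelioma_others"
        if "epithelial" in name:
            return "Epithelial tumour_others"
        if any(t in name for t in ("sarcoma", "fibroma", "mesenchymal")):
            return "Mesenchymal_neoplasias_others"
        return "Neoplasia_Tumours_others"


def assign_aggregate(preferred: str, rules: AggregationRules,
                     counts: Optional[dict[str, int]] = None) -> Optional[str]:
    """Catch-all / aggregate label for a preferred tumour type, or None when
    the term stands alone.

    Named rules always apply. The rare-type rule (below ``rules.min_count``
    occurrences → catch-all) applies only when corpus-level ``counts`` are
    supplied: the threshold is a property of a dataset, not of one report.
    """
    key = _fold(preferred)
    if key in rules.named:
        label = rules.named[key]
        return None if _fold(label) == key else label
    if counts is not None and counts.get(preferred, 0) < rules.min_count:
        return rules.catch_all_for(preferred)
    return None


@dataclass(frozen=True)
class NormalizedAnnotation:
    """A lesion annotation after mapping every field to preferred terms."""

    tumour_ref: str
    lesion_text: str
    primary_tumour: Optional[str] = None
    grade_2_tier: Optional[str] = None
    grade_3_tier: Optional[str] = None
    differentiation: Optional[str] = None
    uncertainty: Optional[str] = None
    location: Optional[str] = None
    location_source_rank: Optional[int] = None
    aggregate_category: Optional[str] = None  # always one of CATCH_ALL_TERMS

    def with_ref(self, tumour_ref: str) -> "NormalizedAnnotation":
        return replace(self, tumour_ref=tumour_ref)

    @property
    def registry_primary(self) -> Optional[str]:
        """The Primary_tumour column value: the aggregate label when one is
        assigned, else the preferred term."""
        return self.aggregate_category or self.primary_tumour


def normalize_annotation(
    raw: RawAnnotation,
    maps: dict[str, NormalizationMap],
    rules: Optional[AggregationRules] = None,
    counts: Optional[dict[str, int]] = None,
) -> NormalizedAnnotation:
    """Map one raw annotation's fields to preferred terms and assign any
    aggregate label. Grades from both tiers share the grade map ("second
    grade", "grade II" and "grade 2" collapse to one preferred phrase)."""
    primary = (normalize_term(raw.primary_tumour, maps["tumour_type"])
               if raw.primary_tumour is not None else None)
    aggregate = None
    if primary is not None and rules is not None:
        label = assign_aggregate(primary, rules, counts)
        if label is not None and label not in CATCH_ALL_TERMS:
            # named aggregation replaces the preferred term itself
            primary, label = label, None
        aggregate = label
    return NormalizedAnnotation(
        tumour_ref=raw.tumour_ref,
        lesion_text=raw.lesion_text,
        primary_tumour=primary,
        grade_2_tier=(normalize_term(raw.grade_2_tier, maps["grade"])
                      if raw.grade_2_tier is not None else None),
        grade_3_tier=(normalize_term(raw.grade_3_tier, maps["grade"])
                      if raw.grade_3_tier is not None else None),
        differentiation=(normalize_term(raw.differentiation, maps["differentiation"])
                         if raw.differentiation is not None else None),
        uncertainty=raw.uncertainty,
        location=(normalize_term(raw.location, maps["location"])
                  if raw.location is not None else None),
        location_source_rank=raw.location_source_rank,
        aggregate_category=aggregate,
    )
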