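"""Assembling the 15-column tumour registry.

One registry row per registrable tumour. Tumour references are the report
reference plus a contiguous ordinal ("R.123-T.1" ... "R.123-T.4" for a
four-tumour report); the animal table and the tumour table are merged on
the report reference. Output column order is fixed (columns A to O):

    ReportRef, TumourRef, ResultDate, Species, Breed, Gender,
    Anonymous_PracticeID, Histo_Cyto, Tumours_in_the_report,
    Primary_tumour, Grade_2_tier, Grade_3_tier, Differentiation,
    Location, Uncertainty_terms

Dates are emitted ISO-8601 regardless of input dialect; practice IDs pass
through opaquely (no geography is ever computed); the three-tier grade
column stores the bare numeral ("grade 2" family collapses to "2").
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .config import LabDialect
from .ingest import EPRRecord, normalize_species
from .lesions import split_lesions
from .matching import Lexicon, annotate_lesion, is_registrable_tumour
from .normalize import (AggregationRules, NormalizationMap, assign_aggregate,
                        format_gender, normalize_annotation, normalize_breed,
                        parse_gender, NormalizedAnnotation)
from .sections import locate_sections

REGISTRY_COLUMNS = [
    "ReportRef", "TumourRef", "ResultDate", "Species", "Breed", "Gender",
    "Anonymous_PracticeID", "Histo_Cyto", "Tumours_in_the_report",
    "Primary_tumour", "Grade_2_tier", "Grade_3_tier", "Differentiation",
    "Location", "Uncertainty_terms",
]

_SPECIES_LABEL = {"canine": "Canine", "feline": "Feline"}
_ASSAY_LABEL = {"histology": "Histology", "cytology": "Cytology"}


def assign_tumour_refs(
    report_ref: str,
    lesions: Sequence[NormalizedAnnotation],
    seen_refs: Optional[set[str]] = None,
) -> list[NormalizedAnnotation]:
    """Assign "R.x-T.1" ... refs contiguously to the given (registrable)
    annotations. A ``seen_refs`` set may be passed to reject a duplicate
    report reference across calls."""
    if seen_refs is not None:
        if report_ref in seen_refs:
            raise ValueError(f"duplicate report reference {report_ref!r}")
        seen_refs.add(report_ref)
    return [ann.with_ref(f"{report_ref}-T.{i}")
            for i, ann in enumerate(lesions, start=1)]


def _grade3_numeral(preferred: Optional[str]) -> str:
    """Collapse the normalized "grade N" phrase to the bare numeral."""
    if not preferred:
        return ""
    return preferred[len("grade "):] if preferred.lower().startswith("grade ") \
        else preferred


def animal_row(record: EPRRecord, maps: dict[str, NormalizationMap]) -> dict:
    """The animal half of the registry (everything except tumour fields)."""
    species = normalize_species(record.species)
    if species is None:
        raise ValueError(f"record {record.lab_no} has non-target species "
                         f"{record.species!r}; filter before building")
    sex, neuter = parse_gender(record.gender)
    return {
        "ReportRef": record.lab_no,
        "ResultDate": record.recd.isoformat() if record.recd else "",
        "Species": _SPECIES_LABEL[species],
        "Breed": normalize_breed(record.breed, species, maps),
        "Gender": format_gender(sex, neuter),
        "Anonymous_PracticeID": record.practice_id,
        "Histo_Cyto": _ASSAY_LABEL[record.assay_type],
    }


def extract_tumours(
    record: EPRRecord,
    dialect: LabDialect,
    lexicons: dict[str, Lexicon],
    maps: dict[str, NormalizationMap],
    rules: Optional[AggregationRules] = None,
) -> list[NormalizedAnnotation]:
    """Run one record through sections → lesions → matching → normalization
    and return the registrable tumours with refs assigned."""
    keywords = dialect.keywords_for(record.assay_type)
    spans = locate_sections(record, keywords)
    lesions = split_lesions(spans.diagnosis_text, record.lab_no)
    annotations = [annotate_lesion(l, spans.location_candidates, lexicons)
                   for l in lesions]
    registrable = [a for a in annotations
                   if is_registrable_tumour(a, lexicons["primary_tumour"])]
    normalized = [normalize_annotation(a, maps, rules) for a in registrable]
    return assign_tumour_refs(record.lab_no, normalized)


def build_registry(
    records: Sequence[EPRRecord],
    dialects: dict[str, LabDialect],
    lexicons: dict[str, Lexicon],
    maps: dict[str, NormalizationMap],
    rules: Optional[AggregationRules] = None,
    aggregate_rare: bool = False,
) -> pd.DataFrame:
    """Build the 15-column registry for a sequence of (species-filtered)
    records. Reports with zero registrable tumours contribute zero rows.

    ``aggregate_rare`` enables the corpus-level rare-type pass: after a
    first extraction, tumour types occurring fewer than ``rules.min_count``
    times are relabelled to their catch-all category.
    """
    seen: set[str] = set()
    per_report: list[tuple[dict, list[NormalizedAnnotation]]] = []
    for record in records:
        if record.lab_no in seen:
            raise ValueError(f"duplicate report reference {record.lab_no!r}")
        seen.add(record.lab_no)
        dialect = dialects[record.lab_dialect]
        tumours = extract_tumours(record, dialect, lexicons, maps, rules)
        if tumours:
            per_report.append((animal_row(record, maps), tumours))

    counts: Optional[dict[str, int]] = None
    if aggregate_rare and rules is not None:
        counts = {}
        for _, tumours in per_report:
            for t in tumours:
                key = t.registry_primary
                counts[key] = counts.get(key, 0) + 1

    rows = []
    for animal, tumours in per_report:
        for t in tumours:
            primary = t.registry_primary
            if counts is not None and t.aggregate_category is None:
                label = assign_aggregate(primary, rules, counts)
                if label is not None:
                    primary = label
            rows.append({
                **animal,
                "TumourRef": t.tumour_ref,
                "Tumours_in_the_report": len(tumours),
                "Primary_tumour": primary,
                "Grade_2_tier": t.grade_2_tier or "",
                "Grade_3_tier": _grade3_numeral(t.grade_3_tier),
                "Differentiation": t.differentiation or "",
                "Location": t.location or "",
                "Uncertainty_terms": t.uncertainty or "",
            })
    return pd.DataFrame(rows, columns=REGISTRY_COLUMNS)


def merge_animal_tumour(animal_rows: pd.DataFrame,
                        tumour_rows: pd.DataFrame) -> pd.DataFrame:
    """Inner join of the animal and tumour tables on ReportRef, in registry
    column order. Every tumour row's ReportRef must exist in the animal
    table; orphans are a hard error listing the offending refs."""
    orphans = sorted(set(tumour_rows["ReportRef"]) - set(animal_rows["ReportRef"]))
    if orphans:
        raise ValueError(f"tumour rows reference unknown reports: {orphans}")
    merged = tumour_rows.merge(animal_rows, on="ReportRef", how="inner")
    return merged[REGISTRY_COLUMNS].reset_index(drop=True)


def median_tumours_per_report(registry: pd.DataFrame) -> float:
    """Median of Tumours_in_the_report taken over *reports* (one value per
    distinct ReportRef)."""
    if registry.empty:
        return float("nan")
    per_report = registry.groupby("ReportRef")["Tumours_in_the_report"].first()
    return float(per_report.median())


def validate_registry(table: pd.DataFrame) -> None:
    """Check the RegistryRow invariants; raise ValueError on violation."""
    if list(table.columns) != REGISTRY_COLUMNS:
        raise ValueError("registry must have exactly the 15 columns A-O "
                         "in order")
    if table.empty:
        return
    if (table["Primary_tumour"].astype(str).str.strip() == "").any():
        raise ValueError("every registry row needs a non-empty Primary_tumour")
    for ref, group in table.groupby("ReportRef"):
        n = len(group)
        if set(group["Tumours_in_the_report"]) != {n}:
            raise ValueError(f"Tumours_in_the_report mismatch for {ref}")
        expected = {f"{ref}-T.{i}" for i in range(1, n + 1)}
        if set(group["TumourRef"]) != expected:
            raise ValueError(f"tumour refs for {ref} are not contiguous")


def write_registry(table: pd.DataFrame, path: Path | str,
                   fmt: str = "csv") -> Path:
    """Write the registry as CSV (RFC-4180 quoting) or JSON-lines; output is
    bit-stable for a fixed input table."""
    validate_registry(table)
    path = Path(path)
    if fmt == "csv":
        table.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
    elif fmt in ("json-lines", "jsonl"):
        with open(path, "w", encoding="utf-8") as fh:
            for rec in table.to_dict(orient="records"):
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    else:
        raise ValueError(f"unknown registry format {fmt!r}")
    return path


def read_registry(path: Path | str) -> pd.DataFrame:
    """Read back a registry written by :func:`write_registry`."""
    path = Path(path)
    if path.suffix in (".jsonl",) or path.name.endswith(".json-lines"):
        records = [json.loads(line) for line in
                   path.read_text("utf-8").splitlines() if line.strip()]
        table = pd.DataFrame(records, columns=REGISTRY_COLUMNS)
    else:
        table = pd.read_csv(path, dtype=str, keep_default_na=False,
                            encoding="utf-8")
        table["Tumours_in_the_report"] = table["Tumours_in_the_report"].astype(int)
    return table
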