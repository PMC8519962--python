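"""Reading laboratory exports and assembling one record per submission.

A laboratory export is a delimited table with one or more rows per
submission: animal metadata columns plus a free-text pathology report that
some laboratories deliver split across consecutive rows. This module reads
the table, joins each run of consecutive rows sharing a sample reference
into a single electronic pathology record (EPR), and filters to dogs and
cats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .config import LabDialect, default_dialect

logger = logging.getLogger(__name__)

#: canonical column names and the case-insensitive header prefixes they match
_COLUMNS = {
    "lab_no": ("LABNO",),
    "recd": ("RECD",),
    "species": ("SPECIES",),
    "breed": ("BREED",),
    "gender": ("GENDER", "SEX"),
    "practice_id": ("PRACTICE_ID", "PRACTICEID"),
    "assay_code": ("ASSAY_CODE", "ASSAYCODE", "ASSAY"),
    "rescomment": ("RESCOMMENT",),
}

_MANDATORY = ("lab_no", "rescomment")

_SPECIES_ALIASES = {
    "canine": "canine", "dog": "canine",
    "feline": "feline", "cat": "feline",
}


@dataclass(frozen=True)
class LabExportRow:
    """One data line of a laboratory export (possibly a report fragment)."""

    lab_no: str
    recd: Optional[date]
    species: str
    breed: str
    gender: str
    practice_id: str
    assay_code: str
    rescomment: str
    recd_raw: str = ""


@dataclass(frozen=True)
class EPRRecord:
    """One laboratory submission: animal metadata plus concatenated report."""

    lab_no: str
    recd: Optional[date]
    species: str
    breed: str
    gender: str
    practice_id: str
    assay_type: str
    report_text: str
    lab_dialect: str = "default"


def normalize_species(surface: str) -> Optional[str]:
    """Map a raw species label to ``canine``/``feline``; None if neither."""
    return _SPECIES_ALIASES.get((surface or "").strip().lower())


def _parse_date(raw: str) -> Optional[date]:
    # day-first (UK laboratory convention); two-digit years pivot at 2000
    ts = pd.to_datetime(raw, dayfirst=True, errors="coerce")
    return None if pd.isna(ts) else ts.date()


def _resolve_header(columns: Sequence[str]) -> dict[str, str]:
    resolved: dict[str, str] = {}
    for canonical, prefixes in _COLUMNS.items():
        for col in columns:
            folded = str(col).strip().upper().replace(" ", "_")
            if any(folded.startswith(p) for p in prefixes):
                resolved[canonical] = col
                break
    return resolved


def read_lab_export(
    path: Path | str,
    dialect: str = "default",
    delimiter: Optional[str] = None,
) -> list[LabExportRow]:
    """Read a delimited laboratory export into one row per data line.

    The delimiter is taken from the file extension (``.tsv`` → tab, else
    comma) unless given explicitly. Header matching is case-insensitive and
    prefix-based, so ``RESCOMMENT1 (Pathology report)`` resolves to the
    report column. Unparseable dates are kept as raw text on the row rather
    than dropped.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False,
                        encoding="utf-8")
    header = _resolve_header(frame.columns)
    for canonical in _MANDATORY:
        if canonical not in header:
            raise ValueError(
                f"export {path} is missing mandatory column "
                f"{_COLUMNS[canonical][0]}")

    def col(row: pd.Series, canonical: str) -> str:
        name = header.get(canonical)
        return str(row[name]).strip() if name is not None else ""

    rows = []
    for _, r in frame.iterrows():
        raw_date = col(r, "recd")
        rows.append(LabExportRow(
            lab_no=col(r, "lab_no"),
            recd=_parse_date(raw_date),
            species=col(r, "species"),
            breed=col(r, "breed"),
            gender=col(r, "gender"),
            practice_id=col(r, "practice_id"),
            assay_code=col(r, "assay_code"),
            rescomment=str(r[header["rescomment"]]),
            recd_raw=raw_date,
        ))
    return rows


def concatenate_submissions(
    rows: Sequence[LabExportRow],
    dialect: Optional[LabDialect] = None,
) -> list[EPRRecord]:
    """Join runs of consecutive rows sharing a sample reference.

    Report fragments are joined in order with a single newline; animal
    metadata comes from the first row of the run. Grouping is by *runs* of
    equal ``lab_no`` (fragments arrive in consecutive rows); a non-adjacent
    repeat of a reference is treated as a distinct submission and warned
    about.
    """
    if dialect is None:
        dialect = default_dialect()

    records: list[EPRRecord] = []
    seen_refs: set[str] = set()
    i = 0
    while i < len(rows):
        run = [rows[i]]
        j = i + 1
        while j < len(rows) and rows[j].lab_no == rows[i].lab_no:
            run.append(rows[j])
            j += 1
        first = run[0]
        if first.lab_no in seen_refs:
            logger.warning(
                "non-adjacent repeat of sample reference %s treated as a "
                "distinct submission", first.lab_no)
        seen_refs.add(first.lab_no)
        species_labels = {r.species.strip().lower() for r in run if r.species.strip()}
        if len(species_labels) > 1:
            logger.warning("conflicting species %s within submission %s; "
                           "keeping first", sorted(species_labels), first.lab_no)
        records.append(EPRRecord(
            lab_no=first.lab_no,
            recd=first.recd,
            species=first.species,
            breed=first.breed,
            gender=first.gender,
            practice_id=first.practice_id,
            assay_type=dialect.assay_type(first.assay_code),
            report_text="\n".join(r.rescomment for r in run),
            lab_dialect=dialect.name,
        ))
        i = j
    return records


def filter_species(records: Sequence[EPRRecord]) -> list[EPRRecord]:
    """Keep only canine and feline records; log discard counts per label.

    A pure filter: surviving records are returned unchanged (species labels
    are normalized where they are consumed, not here). Records whose species
    is missing or unrecognized are discarded and counted, never errored.
    """
    kept: list[EPRRecord] = []
    discards: dict[str, int] = {}
    for rec in records:
        if normalize_species(rec.species) is None:
            label = rec.species.strip().lower() or "<missing>"
            discards[label] = discards.get(label, 0) + 1
        else:
            kept.append(rec)
    for label, n in sorted(discards.items()):
        logger.info("discarded %d record(s) with species %r", n, label)
    return kept
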