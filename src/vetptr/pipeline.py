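"""End-to-end convenience wrappers over the extraction pipeline."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import ingest, resources
from .config import LabDialect, load_dialects
from .ingest import EPRRecord
from .registry import build_registry


def load_context(
    lexicon_dir: Optional[Path | str] = None,
    map_dir: Optional[Path | str] = None,
    dialect_config: Optional[Path | str] = None,
    min_count: int = 10,
) -> dict:
    """Load dialects, lexicons, normalization maps and aggregation rules
    (bundled defaults unless paths are given)."""
    lexicons = resources.load_lexicons(lexicon_dir)
    return {
        "dialects": load_dialects(dialect_config),
        "lexicons": lexicons,
        "maps": resources.load_maps(map_dir, lexicons),
        "rules": resources.load_aggregation_rules(min_count=min_count),
    }


def records_from_export(path: Path | str, dialect: str = "default",
                        dialects: Optional[dict[str, LabDialect]] = None,
                        ) -> list[EPRRecord]:
    """Read a laboratory export and return species-filtered EPR records."""
    if dialects is None:
        dialects = load_dialects()
    rows = ingest.read_lab_export(path, dialect=dialect)
    records = ingest.concatenate_submissions(rows, dialects[dialect])
    return ingest.filter_species(records)


def registry_from_export(path: Path | str, dialect: str = "default",
                         context: Optional[dict] = None,
                         aggregate_rare: bool = False) -> pd.DataFrame:
    """Export file → 15-column registry, using bundled resources unless a
    prepared ``context`` (see :func:`load_context`) is supplied."""
    if context is None:
        context = load_context()
    records = records_from_export(path, dialect, context["dialects"])
    return registry_from_records(records, context, aggregate_rare)


def registry_from_records(records: Sequence[EPRRecord],
                          context: Optional[dict] = None,
                          aggregate_rare: bool = False) -> pd.DataFrame:
    if context is None:
        context = load_context()
    return build_registry(records, context["dialects"], context["lexicons"],
                          context["maps"], context["rules"],
                          aggregate_rare=aggregate_rare)
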