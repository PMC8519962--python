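"""Loaders for the bundled lexicons, normalization maps and fixtures.

The bundled lexicons are a reduced working set (a few hundred entries);
loaders accept externally curated tables of the same plain-text formats in
their place, so a full curated lexicon directory can be dropped in without
code changes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

from .matching import CATEGORIES, Lexicon
from .normalize import AggregationRules, NormalizationMap

_LEXICON_FILES = {c: f"{c}.txt" for c in CATEGORIES}
_MAP_FILES = {
    "tumour_type": "tumour_type.tsv",
    "grade": "grade.tsv",
    "differentiation": "differentiation.tsv",
    "breed_dog": "breed_dog.tsv",
    "breed_cat": "breed_cat.tsv",
}


def _data_dir() -> Path:
    return Path(__file__).parent / "data"


def example_export_path() -> Path:
    """Path of the bundled single-report worked-example export."""
    return _data_dir() / "examples" / "lab_export_r123.csv"


def load_lexicons(directory: Optional[Path | str] = None) -> dict[str, Lexicon]:
    """Load the six category lexicons from ``directory`` (defaults to the
    bundled reduced set)."""
    base = Path(directory) if directory else _data_dir() / "lexicons"
    return {cat: Lexicon.from_file(base / fname, cat)
            for cat, fname in _LEXICON_FILES.items()}


def load_maps(
    directory: Optional[Path | str] = None,
    lexicons: Optional[dict[str, Lexicon]] = None,
) -> dict[str, NormalizationMap]:
    """Load the normalization maps; the location map is derived from the
    location lexicon's ``maps_to`` flags merged with any file of pairs."""
    base = Path(directory) if directory else _data_dir() / "maps"
    maps = {domain: NormalizationMap.from_file(base / fname, domain)
            for domain, fname in _MAP_FILES.items()}
    if lexicons is None:
        lexicons = load_lexicons()
    loc = NormalizationMap.from_lexicon(lexicons["location"], "location")
    loc_file = base / "location.tsv"
    if loc_file.exists():
        loc = loc.merged_with(NormalizationMap.from_file(loc_file, "location"))
    maps["location"] = loc
    return maps


def load_aggregation_rules(path: Optional[Path | str] = None,
                           min_count: int = 10) -> AggregationRules:
    base = Path(path) if path else _data_dir() / "maps" / "aggregates.tsv"
    return AggregationRules.from_file(base, min_count=min_count)


def load_hierarchy(path: Optional[Path | str] = None) -> dict[str, str]:
    """Tumour-type is-a table (child → parent) used by the validator."""
    base = Path(path) if path else _data_dir() / "maps" / "hierarchy.tsv"
    pairs: dict[str, str] = {}
    for line in base.read_text("utf-8").splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        child, parent = line.rstrip("\n").split("\t")[:2]
        pairs[child.strip()] = parent.strip()
    return pairs
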