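"""Scoring pipeline output against a gold standard.

A report counts as a success when the full multiset of its gold tumour
diagnoses is recovered (exact preferred-term match after normalization);
partial recovery — missing one of two seminomas, or naming a generic type
where the expert named a specific one — is a failure. Results are
stratified by gold tumour count (single vs multiple) and assay type, the
four cells of the reference validation design, and every error is run
through a rule-based classifier for the five misdiagnosis mechanisms.

Two additions beyond the reference design, both clearly labelled:
exact (Clopper-Pearson) binomial 95% confidence intervals per stratum, and
a per-lesion F1 convenience metric. Neither changes the headline
report-level accuracies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from scipy.stats import binomtest

from .lesions import detect_delimiter_style
from .resources import load_hierarchy

#: catch-all registry labels treated as their generic type when reasoning
#: about the tumour-type hierarchy
CATCH_ALL_ALIASES = {
    "Carcinoma_others": "Carcinoma",
    "Adenoma_others": "Adenoma",
    "Epithelioma_others": "Epithelioma",
    "Epithelial tumour_others": "Epithelial tumour",
    "Mesenchymal_neoplasias_others": "Mesenchymal neoplasia",
    "Neoplasia_Tumours_others": "Neoplasia",
}

#: hedging phrases that signal a provisional differential diagnosis
PROVISIONAL_PHRASES = ("not excluded", "cannot exclude", "ddx")

_ROOT = "Neoplasia"


@dataclass(frozen=True)
class StratumScore:
    total: int
    matched: int
    ci_low: float    # exact binomial 95% CI (artifact addition)
    ci_high: float

    @property
    def accuracy(self) -> float:
        return self.matched / self.total if self.total else float("nan")


@dataclass(frozen=True)
class ReportError:
    report_ref: str
    predicted: tuple[str, ...]
    gold: tuple[str, ...]
    reason: Optional[int]  # 1..5 or None (unclassified)


@dataclass
class ValidationResult:
    strata: dict[str, StratumScore]
    errors: list[ReportError] = field(default_factory=list)
    per_lesion_f1: float = float("nan")

    @property
    def overall_accuracy(self) -> float:
        return self.strata["overall"].accuracy

    def to_dict(self) -> dict:
        # empty strata serialize as None, not NaN (valid JSON, sane equality)
        return {
            "strata": {
                name: {"total": s.total, "matched": s.matched,
                       "accuracy": s.accuracy if s.total else None,
                       "ci95": [s.ci_low, s.ci_high] if s.total else None}
                for name, s in self.strata.items()
            },
            "errors": [
                {"report_ref": e.report_ref, "predicted": list(e.predicted),
                 "gold": list(e.gold), "reason": e.reason}
                for e in self.errors
            ],
            "per_lesion_f1": self.per_lesion_f1,
        }


class TumourHierarchy:
    """Is-a reasoning over tumour types for error classification."""

    def __init__(self, parents: Optional[dict[str, str]] = None) -> None:
        self.parents = parents if parents is not None else load_hierarchy()

    def dealias(self, t: str) -> str:
        return CATCH_ALL_ALIASES.get(t, t)

    def ancestors(self, t: str) -> set[str]:
        node = self.dealias(t)
        seen = {node}  # also guards against accidental cycles
        out: set[str] = set()
        while node in self.parents:
            node = self.parents[node]
            if node in seen:
                break
            seen.add(node)
            out.add(node)
        return out

    def is_generic_of(self, predicted: str, gold: str) -> bool:
        return self.dealias(predicted) in self.ancestors(gold)

    def base_family(self, t: str) -> str:
        """The top-but-one ancestor (the child of the root), e.g. every
        carcinoma's base family is "Epithelial tumour"."""
        node = self.dealias(t)
        seen = set()
        while node in self.parents and self.parents[node] != _ROOT \
                and node not in seen:
            seen.add(node)
            node = self.parents[node]
        return node


def _binom_ci(matched: int, total: int) -> tuple[float, float]:
    if total == 0:
        return (float("nan"), float("nan"))
    ci = binomtest(matched, total).proportion_ci(confidence_level=0.95,
                                                method="exact")
    return (float(ci.low), float(ci.high))


def classify_error(
    predicted: Sequence[tuple[str, str]],
    gold: Sequence[tuple[str, str]],
    report_text: str,
    hierarchy: Optional[TumourHierarchy] = None,
) -> Optional[int]:
    """Assign a misdiagnosis reason (1..5) to one erroneous report.

    ``predicted`` and ``gold`` are (tumour type, location) pairs; rules are
    tried in order:

    1. the gold diagnosis is a lipoma and the word never appears in the
       report text;
    2. the gold has more tumours than were predicted and the report uses no
       standard delimiters;
    3. a provisional phrase is present (the gold is typically non-tumour);
    4. predicted and gold types share a base family but the locations
       disagree (the location drove the wrong type);
    5. the predicted type is a generic ancestor of the gold type.

    Returns None when no rule fires (unclassified).
    """
    if hierarchy is None:
        hierarchy = TumourHierarchy()
    pred_types = [t for t, _ in predicted]
    gold_types = [t for t, _ in gold]
    text = report_text.casefold()

    n_gold_lipomas = sum(1 for t in gold_types if t == "Lipoma")
    n_pred_lipomas = sum(1 for t in pred_types if t == "Lipoma")
    if n_gold_lipomas and "lipoma" not in text \
            and n_pred_lipomas < n_gold_lipomas:
        return 1

    if len(gold_types) > len(pred_types) \
            and detect_delimiter_style(report_text) == "none":
        return 2

    if any(phrase in text for phrase in PROVISIONAL_PHRASES):
        return 3

    for pt, pl in predicted:
        for gt, gl in gold:
            if pl and gl and pl != gl \
                    and hierarchy.base_family(pt) == hierarchy.base_family(gt):
                return 4

    for pt, _ in predicted:
        for gt, _ in gold:
            if hierarchy.is_generic_of(pt, gt):
                return 5

    return None


def score_corpus(
    predicted: pd.DataFrame,
    gold: pd.DataFrame,
    hierarchy: Optional[TumourHierarchy] = None,
) -> ValidationResult:
    """Score a registry against a gold table.

    ``predicted`` is a 15-column registry; ``gold`` carries one row per
    gold tumour (non-tumour reports have one row with an empty
    Primary_tumour) plus Histo_Cyto and ReportText. Every predicted report
    must appear in the gold table; stratification follows the gold lesion
    count (0 or 1 → single group) and assay type.
    """
    if hierarchy is None:
        hierarchy = TumourHierarchy()

    gold_by_ref: dict[str, list] = {}
    assay_by_ref: dict[str, str] = {}
    text_by_ref: dict[str, str] = {}
    for _, row in gold.iterrows():
        ref = row["ReportRef"]
        gold_by_ref.setdefault(ref, [])
        if str(row["Primary_tumour"]).strip():
            gold_by_ref[ref].append(
                (row["Primary_tumour"], str(row.get("Location", "") or "")))
        assay_by_ref[ref] = row["Histo_Cyto"]
        text_by_ref[ref] = str(row.get("ReportText", "") or "")

    pred_by_ref: dict[str, list] = {ref: [] for ref in gold_by_ref}
    for _, row in predicted.iterrows():
        ref = row["ReportRef"]
        if ref not in gold_by_ref:
            raise ValueError(f"predicted report {ref!r} is absent from the "
                             "gold table")
        pred_by_ref[ref].append(
            (row["Primary_tumour"], str(row.get("Location", "") or "")))

    cells = {("single", "Cytology"): [0, 0], ("single", "Histology"): [0, 0],
             ("multiple", "Cytology"): [0, 0], ("multiple", "Histology"): [0, 0]}
    errors: list[ReportError] = []
    tp = fp = fn = 0
    for ref in sorted(gold_by_ref):
        gold_pairs = gold_by_ref[ref]
        pred_pairs = pred_by_ref[ref]
        group = "single" if len(gold_pairs) <= 1 else "multiple"
        cell = cells[(group, assay_by_ref[ref])]
        cell[0] += 1
        success = (Counter(t for t, _ in pred_pairs)
                   == Counter(t for t, _ in gold_pairs))
        if success:
            cell[1] += 1
        else:
            errors.append(ReportError(
                report_ref=ref,
                predicted=tuple(t for t, _ in pred_pairs),
                gold=tuple(t for t, _ in gold_pairs),
                reason=classify_error(pred_pairs, gold_pairs,
                                      text_by_ref[ref], hierarchy),
            ))
        inter = Counter(t for t, _ in pred_pairs) & Counter(t for t, _ in gold_pairs)
        tp += sum(inter.values())
        fp += len(pred_pairs) - sum(inter.values())
        fn += len(gold_pairs) - sum(inter.values())

    def stratum(total: int, matched: int) -> StratumScore:
        lo, hi = _binom_ci(matched, total)
        return StratumScore(total, matched, lo, hi)

    strata: dict[str, StratumScore] = {}
    for (group, assay), (total, matched) in cells.items():
        strata[f"{group}_{assay.lower()}"] = stratum(total, matched)
    for group in ("single", "multiple"):
        total = sum(v[0] for (g, _), v in cells.items() if g == group)
        matched = sum(v[1] for (g, _), v in cells.items() if g == group)
        strata[group] = stratum(total, matched)
    total = sum(v[0] for v in cells.values())
    matched = sum(v[1] for v in cells.values())
    strata["overall"] = stratum(total, matched)

    f1 = float("nan")
    if tp + fp and tp + fn:
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)

    return ValidationResult(strata=strata, errors=errors, per_lesion_f1=f1)
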