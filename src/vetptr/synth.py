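"""Synthetic electronic pathology records with known gold annotations.

The generator emulates the structures the extraction pipeline is sensitive
to — section layouts keyed by assay type and laboratory dialect, one to six
lesions per report behind numeric ("1."–"6.") or alphabetic ("A"–"F")
delimiters, tumour/grade/differentiation/uncertainty/location phrases drawn
from the bundled lexicons, markup remnants, multi-row report fragments and
animal metadata — and nothing more. No linguistic realism beyond that is
attempted.

Generation is closed-world: every phrase comes from the bundled lexicons
and preferred vocabularies, so on a clean corpus a correct pipeline
recovers the gold annotation exactly and any miss is a pipeline bug, not a
data gap. Corrupted corpora rewrite reports through the five misdiagnosis
mechanisms observed in expert review (gold is the *expert* answer, so the
pipeline is expected to err):

1. a lipoma described as aspirated fat without the word "lipoma";
2. multiple tumours without the usual delimiters ("Seminoma in both
   testicles");
3. a provisional diagnosis promoted to a definite one ("Lymphoma not
   excluded" with a non-tumour gold);
4. a generic tumour word attached to the wrong location (perianal
   carcinoma where the lesion is in the anal sacs);
5. a generic diagnosis where the expert knew the specific one
   (mesenchymal neoplasia for a soft tissue sarcoma).

Failure modes are mutually exclusive per report. Randomness comes from a
named, portable generator keyed by (seed, report index), so corpora are
reproducible across platforms and a report can be regenerated in isolation.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import LabDialect, load_dialects
from .ingest import EPRRecord

GOLD_COLUMNS = [
    "ReportRef", "ResultDate", "Species", "Breed", "Gender",
    "Anonymous_PracticeID", "Histo_Cyto", "GoldTumours", "Ordinal",
    "Primary_tumour", "Grade_2_tier", "Grade_3_tier", "Differentiation",
    "Location", "Uncertainty_terms", "InjectedReason", "ReportText",
]

#: report-level lesion-count distribution (1..6 tumours per report),
#: derived from the registry's published per-report tumour counts
LESION_COUNT_WEIGHTS = (82479, 8452, 2022, 620, 242, 126)

#: reason → frequency among the 400 expert-reviewed reports (total 23)
REFERENCE_FAILURE_COUNTS = {1: 6, 2: 7, 3: 6, 4: 2, 5: 2}
REFERENCE_VALIDATION_N = 400


def reference_failure_rates() -> dict[int, float]:
    """The failure-rate mix of the reference validation study (23/400)."""
    return {k: v / REFERENCE_VALIDATION_N
            for k, v in REFERENCE_FAILURE_COUNTS.items()}


# ---------------------------------------------------------------------------
# generation vocabulary (a closed subset of the bundled lexicons, chosen so
# that no phrase of one category occurs inside a phrase of another)

_TUMOURS = [
    # (surface forms, registry-level preferred term, g2?, g3?, weight)
    (("Lipoma",), "Lipoma", False, False, 0.22),
    (("Mast cell tumour", "MCT"), "Mast cell tumour", True, True, 0.13),
    (("Lymphoma",), "Lymphoma", True, False, 0.10),
    (("Histiocytoma",), "Histiocytoma", False, False, 0.08),
    (("Squamous cell carcinoma",), "Squamous cell carcinoma", False, False, 0.08),
    (("Melanoma",), "Melanoma", False, False, 0.07),
    (("Soft tissue sarcoma",), "Soft tissue sarcoma", False, True, 0.07),
    (("Osteosarcoma",), "Osteosarcoma", False, False, 0.05),
    (("Fibrosarcoma",), "Fibrosarcoma", False, False, 0.04),
    (("Haemangiosarcoma",), "Haemangiosarcoma", False, False, 0.04),
    (("Seminoma",), "Seminoma", False, False, 0.03),
    (("Basal cell tumour",), "Basal cell tumour", False, False, 0.03),
    (("Plasmacytoma",), "Plasma cell tumour", False, False, 0.03),
    (("Hepatoid adenoma", "Hepatoid gland adenoma"),
     "Adenoma of the hepatoid glands", False, False, 0.03),
]

_LOCATIONS = [
    # (surface written in the report, preferred term)
    ("forelimb", "Forelimb"), ("hindlimb", "Hindlimb"), ("neck", "Neck"),
    ("thorax", "Thorax"), ("chest", "Thorax"), ("abdomen", "Abdomen"),
    ("spleen", "Spleen"), ("liver", "Liver"), ("skin", "Skin"),
    ("cutaneous", "Skin"), ("mammary gland", "Mammary gland"),
    ("oral cavity", "Oral cavity"), ("bladder", "Bladder"),
    ("testicle", "Testicle"),
]

_UNCERTAINTY = ["Consistent with", "Highly likely", "Probable",
                "Compatible with"]
_DIFFERENTIATION = ["Malignant", "Benign", "Well differentiated"]
_GRADE2 = [("low-grade", "Low-grade"), ("high-grade", "High-grade")]
_GRADE3 = [("second grade", "2"), ("grade II", "2"), ("grade 2", "2"),
           ("grade I", "1"), ("first grade", "1"), ("grade III", "3"),
           ("third grade", "3")]

_DOG_BREEDS = [
    ("Labrador retriever", "Labrador Retriever"),
    ("Retriever, Labrador", "Labrador Retriever"),
    ("Crossbreed", "Crossbreed"),
    ("Staffordshire bull terrier", "Staffordshire Bull Terrier"),
    ("Cocker spaniel", "Cocker Spaniel"),
    ("German shepherd dog", "German Shepherd Dog"),
    ("Labradoodle", "Labradoodle"),
    ("Boxer", "Boxer"),
]
_CAT_BREEDS = [
    ("Domestic short hair", "Domestic Short Hair"),
    ("DSH", "Domestic Short Hair"),
    ("Domestic long hair", "Domestic Long Hair"),
    ("British blue", "British Blue"),
    ("Maine coon", "Maine Coon"),
]
_GENDERS = [("Female entire", "Female entire"),
            ("Female neutered", "Female neutered"),
            ("Male entire", "Male entire"),
            ("Male neutered", "Male neutered")]

_PROGNOSES = ["Good", "Guarded", "Cautious", "Fair"]
_HISTORY_PLAIN = "Mass removed and submitted for review"
_HISTO_TAIL = "Specimens are submitted and evaluated"
_CYTO_TAIL = "No further material required"


@dataclass(frozen=True)
class GoldLesion:
    """Registry-level expected annotation of one lesion."""

    ordinal: int
    primary: str
    grade_2_tier: str = ""
    grade_3_tier: str = ""
    differentiation: str = ""
    location: str = ""
    uncertainty: str = ""


@dataclass(frozen=True)
class CorpusSpec:
    """Study conditions for one synthetic corpus.

    Defaults reproduce the composition of the source registry: 63.4%
    histology, 90.9% canine, a lesion-count distribution with median 1, and
    no injected failures.
    """

    n_reports: int = 400
    seed: int = 0
    histology_frac: float = 0.634
    canine_frac: float = 85435 / 93941
    lesion_count_probs: tuple[float, ...] = tuple(
        w / sum(LESION_COUNT_WEIGHTS) for w in LESION_COUNT_WEIGHTS)
    dialect_mix: dict[str, float] = field(
        default_factory=lambda: {"default": 1.0})
    failure_rates: dict[int, float] = field(
        default_factory=lambda: {r: 0.0 for r in range(1, 6)})
    fragment_prob: float = 0.25        # chance a report arrives in >1 rows
    location_in_lesion_prob: float = 0.8

    def validate(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        if abs(sum(self.lesion_count_probs) - 1.0) > 1e-9:
            raise ValueError("lesion_count_probs must sum to 1")
        if abs(sum(self.dialect_mix.values()) - 1.0) > 1e-9:
            raise ValueError("dialect_mix must sum to 1")
        for r, p in self.failure_rates.items():
            if r not in range(1, 6) or not 0.0 <= p <= 1.0:
                raise ValueError(f"invalid failure rate {r}: {p}")
        if sum(self.failure_rates.values()) > 1.0 + 1e-12:
            raise ValueError("failure rates must sum to at most 1 "
                             "(modes are mutually exclusive per report)")
        if not 0.0 <= self.histology_frac <= 1.0:
            raise ValueError("histology_frac must be in [0, 1]")


@dataclass(frozen=True)
class GoldReport:
    """A generated report: the EPR content plus its gold annotation."""

    lab_no: str
    recd: dt.date
    species: str          # raw label as written in the export
    species_gold: str     # "Canine" / "Feline"
    breed: str
    breed_gold: str
    gender: str
    gender_gold: str
    practice_id: str
    assay_code: str
    assay_type: str
    dialect: str
    lesion_texts: tuple[str, ...]
    delimiter_style: str          # numeric / alphabetic / none
    prognosis: Optional[str]
    history: str
    tail: str
    gold_lesions: tuple[GoldLesion, ...]
    injected_reason: Optional[int] = None
    n_fragments: int = 1

    @property
    def diagnosis_block(self) -> str:
        if self.delimiter_style == "numeric":
            return "<br>".join(f"{i}. {t}" for i, t in
                               enumerate(self.lesion_texts, start=1))
        if self.delimiter_style == "alphabetic":
            letters = "ABCDEF"
            return "<br>".join(f"{letters[i]}) {t}" for i, t in
                               enumerate(self.lesion_texts))
        return "<br>".join(self.lesion_texts)

    @property
    def report_text(self) -> str:
        parts = [self.assay_code]
        if self.assay_type == "histology":
            header = ("MORPHOLOGICAL DIAGNOSIS" if self.dialect == "alt"
                      else "DIAGNOSIS")
            parts += [header, self.diagnosis_block]
            if self.prognosis is not None:
                parts += ["PROGNOSIS&nbsp;", self.prognosis]
            parts += ["CLINICAL HISTORY", self.history,
                      "HISTOLOGY", self.tail]
        else:
            header = ("CYTOLOGIC INTERPRETATION" if self.dialect == "alt"
                      else "CYTOLOGICAL INTERPRETATION")
            parts += [header, self.diagnosis_block,
                      "CLINICAL HISTORY", self.history,
                      "COMMENTS", self.tail]
        return "<br>".join(parts)

    @property
    def fragments(self) -> tuple[str, ...]:
        """The report text split across consecutive export rows."""
        if self.n_fragments <= 1:
            return (self.report_text,)
        pieces = self.report_text.split("<br>")
        n = min(self.n_fragments, len(pieces))
        bounds = np.linspace(0, len(pieces), n + 1).astype(int)
        return tuple("<br>".join(pieces[a:b])
                     for a, b in zip(bounds[:-1], bounds[1:]) if b > a)

    def to_record(self, dialect: LabDialect) -> EPRRecord:
        return EPRRecord(
            lab_no=self.lab_no, recd=self.recd, species=self.species,
            breed=self.breed, gender=self.gender,
            practice_id=self.practice_id,
            assay_type=dialect.assay_type(self.assay_code),
            report_text="\n".join(self.fragments),
            lab_dialect=dialect.name,
        )


def _pick(rng: np.random.Generator, items: Sequence):
    return items[int(rng.integers(len(items)))]


def _rng_for(spec: CorpusSpec, index: int) -> np.random.Generator:
    return np.random.default_rng([int(spec.seed) % (2 ** 31), int(index)])


def _draw_reason(spec: CorpusSpec, rng: np.random.Generator) -> Optional[int]:
    u = float(rng.random())
    acc = 0.0
    for reason in sorted(spec.failure_rates):
        acc += spec.failure_rates[reason]
        if u < acc:
            return reason
    return None


def _make_lesion(rng: np.random.Generator, ordinal: int,
                 with_location: bool) -> tuple[str, GoldLesion]:
    surfaces, preferred, g2_ok, g3_ok, _ = _pick_weighted_tumour(rng)
    surface = _pick(rng, surfaces)
    text = surface
    gold = {"primary": preferred}

    style = float(rng.random())
    if style < 0.25:
        unc = _pick(rng, _UNCERTAINTY)
        text = f"{unc} {text}" if rng.random() < 0.5 else f"{text}, {unc.lower()}"
        gold["uncertainty"] = unc
    elif style < 0.45:
        diff = _pick(rng, _DIFFERENTIATION)
        text = f"{diff} {text}" if rng.random() < 0.5 else f"{text}, {diff.lower()}"
        gold["differentiation"] = diff

    if rng.random() < 0.35:
        if g2_ok and (not g3_ok or rng.random() < 0.5):
            s, pref = _pick(rng, _GRADE2)
            text += f" ({s})"
            gold["grade_2_tier"] = pref
        elif g3_ok:
            s, pref = _pick(rng, _GRADE3)
            text += f" ({s})"
            gold["grade_3_tier"] = pref

    if with_location:
        s, pref = _pick(rng, _LOCATIONS)
        text += f", {s}"
        gold["location"] = pref

    return text, GoldLesion(ordinal=ordinal, **gold)


def _pick_weighted_tumour(rng: np.random.Generator):
    weights = np.array([t[4] for t in _TUMOURS])
    idx = int(rng.choice(len(_TUMOURS), p=weights / weights.sum()))
    return _TUMOURS[idx]


def generate_report(spec: CorpusSpec, index: int) -> GoldReport:
    """Deterministically generate report ``index`` of the corpus."""
    spec.validate()
    rng = _rng_for(spec, index)

    reason = _draw_reason(spec, rng)
    canine = bool(rng.random() < spec.canine_frac)
    histology = bool(rng.random() < spec.histology_frac)
    if reason == 1:
        histology = False  # the lipoma failure mode is a cytology artefact
    if reason in (1, 3, 4, 5):
        n_lesions = 1
    elif reason == 2:
        n_lesions = 2 + int(rng.integers(3))  # 2..4
    else:
        n_lesions = 1 + int(rng.choice(6, p=np.asarray(spec.lesion_count_probs)))

    dialect_names = sorted(spec.dialect_mix)
    dialect = dialect_names[int(rng.choice(
        len(dialect_names),
        p=np.array([spec.dialect_mix[d] for d in dialect_names])))]

    breed_raw, breed_gold = _pick(rng, _DOG_BREEDS if canine else _CAT_BREEDS)
    if rng.random() < 0.02:
        gender_raw, gender_gold = "?", "unknown"
    else:
        gender_raw, gender_gold = _pick(rng, _GENDERS)
    species_raw = _pick(rng, ["Canine", "Dog"] if canine else ["Feline", "Cat"])

    recd = dt.date(2018, 4, 1) + dt.timedelta(days=int(rng.integers(456)))
    practice = f"P{int(rng.integers(1, 300)):03d}"
    assay_code = "HISTO" if histology else "CYT"

    # section furniture
    prognosis = _pick(rng, _PROGNOSES) if histology and rng.random() < 0.85 else None
    history = _HISTORY_PLAIN
    tail = _HISTO_TAIL if histology else _CYTO_TAIL

    # lesions: multi-lesion reports always carry per-lesion locations; a
    # single lesion may instead have its location in the clinical history
    # (the rank-2 source) or none at all
    loc_mode = "lesion"
    if n_lesions == 1:
        u = float(rng.random())
        if u >= spec.location_in_lesion_prob:
            loc_mode = "history" if u < spec.location_in_lesion_prob + 0.15 else "none"

    texts: list[str] = []
    golds: list[GoldLesion] = []
    for i in range(1, n_lesions + 1):
        text, gold = _make_lesion(rng, i, with_location=(loc_mode == "lesion"))
        texts.append(text)
        golds.append(gold)
    if loc_mode == "history":
        s, pref = _pick(rng, _LOCATIONS)
        history = f"Mass removed from the {s} and submitted for review"
        golds = [replace(g, location=pref) for g in golds]

    style = "none"
    if n_lesions > 1:
        style = "numeric" if rng.random() < 0.8 else "alphabetic"

    n_fragments = 1
    if rng.random() < spec.fragment_prob:
        n_fragments = 2 + int(rng.integers(2))

    report = GoldReport(
        lab_no=f"R.{100000 + index}",
        recd=recd,
        species=species_raw, species_gold="Canine" if canine else "Feline",
        breed=breed_raw, breed_gold=breed_gold,
        gender=gender_raw, gender_gold=gender_gold,
        practice_id=practice,
        assay_code=assay_code,
        assay_type="histology" if histology else "cytology",
        dialect=dialect,
        lesion_texts=tuple(texts),
        delimiter_style=style,
        prognosis=prognosis,
        history=history,
        tail=tail,
        gold_lesions=tuple(golds),
        n_fragments=n_fragments,
    )
    if reason is not None:
        report = inject_failure(report, reason, rng)
    return report


_N_WORDS = {2: "two", 3: "three", 4: "four", 5: "five", 6: "six"}


def inject_failure(report: GoldReport, reason: int,
                   seed: int | np.random.Generator = 0) -> GoldReport:
    """Rewrite a clean report through misdiagnosis mechanism ``reason``.

    The gold annotation becomes the *expert* answer, so the default
    pipeline is expected to misread the rewritten text. Raises ValueError
    when the mechanism does not apply to the report (mechanism 2 needs at
    least two lesions, mechanism 1 a cytology report).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if reason not in range(1, 6):
        raise ValueError(f"unknown failure reason {reason}")

    if reason == 1:
        if report.assay_type != "cytology":
            raise ValueError("mechanism 1 (unnamed lipoma) applies to "
                             "cytology reports")
        text = _pick(rng, ["Consistent with aspiration of adipose tissue",
                           "Fat tissue aspiration",
                           "Aspiration of lipid material"])
        return replace(report, lesion_texts=(text,), delimiter_style="none",
                       history=_HISTORY_PLAIN,
                       gold_lesions=(GoldLesion(1, "Lipoma"),),
                       injected_reason=1)

    if reason == 2:
        n = len(report.gold_lesions)
        if n < 2:
            raise ValueError("mechanism 2 (missing delimiters) needs at "
                             "least two lesions")
        surfaces, preferred, *_ = _pick_weighted_tumour(rng)
        surface = _pick(rng, surfaces)
        if preferred == "Seminoma" and n == 2:
            text, loc = "Seminoma in both testicles", "Testicle"
        else:
            text, loc = f"All {_N_WORDS[n]} sites: {surface}", ""
        golds = tuple(GoldLesion(i, preferred, location=loc)
                      for i in range(1, n + 1))
        return replace(report, lesion_texts=(text,), delimiter_style="none",
                       history=_HISTORY_PLAIN, gold_lesions=golds,
                       injected_reason=2)

    if reason == 3:
        surface = _pick(rng, ["Lymphoma", "Melanocytic tumour", "Carcinoma"])
        text = _pick(rng, [f"{surface} not excluded",
                           f"Cannot exclude a {surface.lower()}",
                           f"Hyperplastic lesion (DDx early {surface.lower()})"])
        return replace(report, lesion_texts=(text,), delimiter_style="none",
                       history=_HISTORY_PLAIN, gold_lesions=(),
                       injected_reason=3)

    if reason == 4:
        variant = _pick(rng, [
            ("Carcinoma, perianal region", "Anal sac carcinoma", "Anal sac"),
            ("Epithelial neoplasia, abdomen", "Thyroid carcinoma",
             "Thyroid gland"),
        ])
        text, gold_type, gold_loc = variant
        return replace(report, lesion_texts=(text,), delimiter_style="none",
                       history=_HISTORY_PLAIN,
                       gold_lesions=(GoldLesion(1, gold_type, location=gold_loc),),
                       injected_reason=4)

    # reason 5: the specific diagnosis was never written down
    variant = _pick(rng, [
        ("Mesenchymal neoplasia", "Soft tissue sarcoma", None),
        ("Thyroid epithelial neoplasia", "Thyroid carcinoma", "Thyroid gland"),
    ])
    text, gold_type, gold_loc = variant
    if gold_loc is None:
        s, gold_loc = _pick(rng, _LOCATIONS)
        text = f"{text}, {s}"
    return replace(report, lesion_texts=(text,), delimiter_style="none",
                   history=_HISTORY_PLAIN,
                   gold_lesions=(GoldLesion(1, gold_type, location=gold_loc),),
                   injected_reason=5)


# ---------------------------------------------------------------------------
# corpus assembly

def generate_corpus(spec: CorpusSpec) -> list[GoldReport]:
    """All reports of the corpus, deterministic for a given spec."""
    spec.validate()
    return [generate_report(spec, i) for i in range(spec.n_reports)]


def corpus_records(reports: Sequence[GoldReport],
                   dialects: Optional[dict[str, LabDialect]] = None,
                   ) -> list[EPRRecord]:
    """EPR records for a corpus (the fast path around the CSV round trip)."""
    if dialects is None:
        dialects = load_dialects()
    return [r.to_record(dialects[r.dialect]) for r in reports]


def export_frame(reports: Sequence[GoldReport]) -> pd.DataFrame:
    """The corpus in laboratory-export layout (one or more rows per
    submission, day-first dates), ready for the ingest reader."""
    rows = []
    for r in reports:
        for k, frag in enumerate(r.fragments):
            first = k == 0
            rows.append({
                "LABNO": r.lab_no,  # repeated on every fragment row
                "RECD": r.recd.strftime("%d/%m/%Y") if first else "",
                "SPECIES": r.species if first else "",
                "BREED": r.breed if first else "",
                "GENDER": r.gender if first else "",
                "PRACTICE_ID": r.practice_id if first else "",
                "ASSAY_CODE": r.assay_code if first else "",
                "RESCOMMENT1": frag,
            })
    return pd.DataFrame(rows)


def gold_frame(reports: Sequence[GoldReport]) -> pd.DataFrame:
    """The gold table: one row per gold tumour, plus one row with an empty
    Primary_tumour for each report whose expert answer is "no tumour"."""
    rows = []
    for r in reports:
        base = {
            "ReportRef": r.lab_no,
            "ResultDate": r.recd.isoformat(),
            "Species": r.species_gold,
            "Breed": r.breed_gold,
            "Gender": r.gender_gold,
            "Anonymous_PracticeID": r.practice_id,
            "Histo_Cyto": "Histology" if r.assay_type == "histology" else "Cytology",
            "GoldTumours": len(r.gold_lesions),
            "InjectedReason": r.injected_reason or 0,
            "ReportText": r.report_text,
        }
        if not r.gold_lesions:
            rows.append({**base, "Ordinal": 0, "Primary_tumour": "",
                         "Grade_2_tier": "", "Grade_3_tier": "",
                         "Differentiation": "", "Location": "",
                         "Uncertainty_terms": ""})
        for g in r.gold_lesions:
            rows.append({**base, "Ordinal": g.ordinal,
                         "Primary_tumour": g.primary,
                         "Grade_2_tier": g.grade_2_tier,
                         "Grade_3_tier": g.grade_3_tier,
                         "Differentiation": g.differentiation,
                         "Location": g.location,
                         "Uncertainty_terms": g.uncertainty})
    return pd.DataFrame(rows, columns=GOLD_COLUMNS)


def write_corpus(reports: Sequence[GoldReport], out_dir: Path | str,
                 ) -> tuple[Path, Path]:
    """Write the export CSV and gold CSV for a corpus; returns both paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    export_path = out / "lab_export.csv"
    gold_path = out / "gold.csv"
    export_frame(reports).to_csv(export_path, index=False, encoding="utf-8",
                                 lineterminator="\n")
    gold_frame(reports).to_csv(gold_path, index=False, encoding="utf-8",
                               lineterminator="\n")
    return export_path, gold_path
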