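# vetptr

Rule-based extraction of tumour diagnoses from free-text veterinary
electronic pathology records (EPRs), assembled into a pathology-based
tumour registry (PTR).

Companion-animal cancer surveillance lacks the population-level reporting
infrastructure of human oncology. What does exist, at national scale, is
the stream of free-text histology and cytology reports that diagnostic
laboratories return to veterinary practices. `vetptr` implements the
pipeline that turns those reports into a searchable registry — one row per
tumour, with the diagnosis, grades, differentiation, anatomical location,
the pathologist's hedging language and the animal's metadata all normalized
to preferred vocabularies — together with a synthetic-record generator and
a validation harness so the whole chain can be developed and tested without
access to clinical data.

The package is aimed at veterinary epidemiologists and clinical-text-mining
researchers who need a transparent, auditable alternative to black-box NLP:
every extraction decision here is a dictionary entry a curator can read and
reorder.

## Method

Extraction is deliberately simple and fully rule-based:

1. **Ingest** — laboratory exports (CSV/TSV, one or more rows per
   submission) are read, report fragments sharing a sample reference are
   concatenated in order, and records are filtered to dogs and cats.
2. **Section location** — keywords (`DIAGNOSIS`, `PROGNOSIS`,
   `CLINICAL HISTORY`, `HISTOLOGY`, `COMMENTS`; `CYTOLOGICAL
   INTERPRETATION` on cytology reports) are found by case-insensitive
   substring search. The diagnosis text lies between the diagnosis keyword
   and the first of `PROGNOSIS`/`CLINICAL HISTORY`; lesion-location
   candidates come from three ranked sources — next to the diagnosis,
   the clinical history, the histology section.
3. **Lesion splitting** — numbered (`1.`–`6.`) or lettered (`A`–`F`)
   delimiters separate multi-tumour diagnoses, capped at six per report.
4. **Term matching** — six ordered look-up tables (primary tumour,
   two-tier grade, three-tier grade, differentiation, uncertainty terms,
   location) are scanned top-down; the first listed phrase found in the
   text wins, so specific diagnoses placed above generic "capture terms"
   take precedence. At most one match is recorded per category.
5. **Normalization** — matched surface forms map to preferred terms
   (tumour types, locations, grade numerals, FCI/AKC dog and FIFE/TICA cat
   breeds, sex + neuter status); rare and generic types can aggregate into
   six catch-all categories.
6. **Registry** — tumour references `R.x-T.n` are assigned and the animal
   and tumour tables merge into a fixed 15-column table.

The synthetic generator (`vetptr.synth`) emulates exactly the structures
this pipeline is sensitive to and can corrupt reports through the five
misdiagnosis mechanisms seen in expert review (an unnamed lipoma, missing
delimiters, provisional diagnoses, wrong locations, generic diagnoses);
the validator (`vetptr.validation`) scores report-level accuracy stratified
by lesion count and assay type and classifies every error against that
five-reason taxonomy.

## Worked example

The bundled fixture is a single histology submission for a Labrador
Retriever with four lesions:

```python
from vetptr import pipeline, resources

registry = pipeline.registry_from_export(resources.example_export_path())
print(registry[["TumourRef", "Primary_tumour", "Grade_2_tier",
                "Grade_3_tier", "Location", "Uncertainty_terms"]])
```

```
   TumourRef                     Primary_tumour Grade_2_tier Grade_3_tier       Location Uncertainty_terms
0  R.123-T.1                       Mixed tumour                             Mammary gland
1  R.123-T.2  Simple tubulo-papillary carcinoma                         2  Mammary gland
2  R.123-T.3                   Mast cell tumour                         2       Forelimb   Consistent with
3  R.123-T.4                           Lymphoma    Low-grade                        Skin     Highly likely
```

Reading the rows: the report held four tumours; the third was recorded by
the pathologist as "Consistent with MCT (second grade), forelimb", which
the pipeline resolves to a mast cell tumour, Patnaik grade 2, on the
forelimb, flagged with the hedging phrase "Consistent with"; the fourth, a
low-grade lymphoma, gets location "Skin" because the report wrote
"cutaneous" and the normalizer maps the adjective to its preferred noun.

The same run from a shell:

```sh
vetptr build-registry --input src/vetptr/data/examples/lab_export_r123.csv \
    --dialect default --out registry.csv
# wrote 4 tumour rows (1 reports) to registry.csv
```

Synthetic corpora and validation:

```sh
vetptr synth-corpus --n 400 --seed 7 \
    --failure-rates 0.015,0.0175,0.015,0.005,0.005 --out-dir corpus/
vetptr validate --pred registry.csv --gold corpus/gold.csv --report report.json
```

## Layout

```
src/vetptr/
  ingest.py      exports → one record per submission
  sections.py    keyword search, diagnosis and location spans
  lesions.py     delimiter detection and lesion splitting
  matching.py    ordered first-match lexicons, annotation, curation sampling
  normalize.py   preferred terms, breeds, gender, aggregation
  registry.py    refs, merging, the 15-column table, I/O
  synth.py       synthetic EPR corpora with gold annotations
  validation.py  stratified scoring and error-reason classification
  data/          bundled lexicons, normalization maps, dialect config
docs/methods.md  model, parameters, design choices, limitations
```
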