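# Methods

## The extraction model

`vetptr` treats a pathology report as a sequence of named sections and a
diagnosis as a short phrase drawn from a curated, ordered vocabulary. Three
assumptions carry the whole design:

1. **Sections are announced by keywords.** Every submitting laboratory
   prints recognisable headers (`DIAGNOSIS`, `PROGNOSIS`, `CLINICAL
   HISTORY`, `HISTOLOGY`, `COMMENTS`; cytology reports open the diagnosis
   with `CYTOLOGICAL INTERPRETATION`). Which headers a laboratory uses is
   configuration (a *dialect*), not code. Keyword search is
   case-insensitive plain substring matching, first occurrence wins, no
   word-boundary anchoring — faithfully simple, and therefore a documented
   source of false hits (`MCT` inside another token would match). The
   validation harness measures this class of error rather than patching it.
2. **Lesions are delimited lists.** Multi-tumour reports list one diagnosis
   per numbered (`1.`–`6.`) or lettered (`A`–`F`) item. At most six lesions
   are looked for (reports with more are negligibly rare in practice);
   material after a seventh marker stays attached to the sixth lesion.
   Undelimited phrasings ("Seminoma in both testicles") are *not*
   recovered: that is a known failure mode of the method, reproduced by
   default and counted by the validator. Numeric markers require the
   trailing dot so grades ("grade 2") are not delimiters; alphabetic
   markers must be uppercase standalone tokens and the sequence must start
   A, B so the article "A" never splits a report.
3. **Matching is ordered first-match, not longest-match.** Each of the six
   look-up tables (primary tumour, two-tier grade, three-tier grade,
   differentiation, uncertainty, location) is scanned top-down and the
   first listed phrase present anywhere in the lesion text wins.
   Specificity is enforced by *placement* — curators keep "Mixed mammary
   gland tumour" above the capture term "Tumour" — exactly the discipline
   an ordered dictionary imposes, which keeps the artefact auditable.
   Location additionally falls back through three ranked sources:
   the lesion text itself, then the clinical-history span, then the
   histology span.

Markup remnants in exports (`<br>`, `&nbsp;`, stray `>`) are normalized to
single spaces in one pass before any searching, so character positions are
stable; all spans refer to the normalized text.

## Normalization

Surface forms map to preferred terms by exact case-folded, trimmed lookup.
Unmapped surfaces pass through unchanged and are logged — visible
pass-through feeds the curation loop (`sample_unmatched` draws seeded
batches of 200 unmatched texts for human review, iterating until a batch
yields nothing new); a silent "other" bucket would hide it. Grade phrases
from both tiers share one map ("second grade", "grade II", "grade 2" →
"grade 2"); the registry's three-tier column stores the bare numeral.
Dog breeds follow FCI/AKC naming, cat breeds FIFE/TICA, plus recognised
hybrids; the authority tables are editable data files and deliberately
skeletal — breed coverage is a data problem, not a code problem.

Aggregation has two layers. Named rules always apply (plasmacytomas and
multiple myelomas → "Plasma cell tumour"; bare capture terms like
"Carcinoma" → "Carcinoma_others"). The corpus-level rare-type pass (types
below `min_count = 10` occurrences → one of six catch-all categories) is
**off by default**: the threshold is meaningful on a registry of ~10⁵
tumours, while on small corpora it would aggregate everything, so it is
exposed as an explicit option (`--min-count`).

## The registry

Fifteen fixed columns, one row per registrable tumour: report and tumour
references (`R.x-T.n`, ordinals contiguous), ISO result date, species,
breed, gender (sex + neuter status), opaque practice ID (no geography is
ever computed), assay type, tumours-in-report count, tumour type, both
grade tiers, differentiation, location and uncertainty terms. Lesions whose
primary match carries the `excluded` flag (hamartomas, cysts, tumour-like
masses) are not neoplasms and never enter the registry; a report with zero
registrable tumours contributes zero rows. The emitted date is the
laboratory's record date, the only date the export carries.

## Synthetic corpora

The generator produces the structures the pipeline is sensitive to and
nothing else: section templates per dialect and assay type, 1–6 lesions
behind numeric or alphabetic delimiters, phrases drawn from the bundled
lexicons, markup remnants, multi-row fragments, and animal metadata with
realistic variant spellings. Default composition follows the source
registry's published make-up: 63.4% histology, 90.9% canine, and a
lesion-count distribution (87.8% single-lesion, median 1) derived from the
registry's per-report tumour counts. Generation is closed-world — every
phrase comes from the bundled vocabularies — so on a clean corpus a correct
pipeline reproduces the gold annotation *exactly*, and any miss is a bug.
Randomness uses NumPy's `default_rng` (PCG64) keyed by (seed, report
index), so corpora are portable across platforms and any report can be
regenerated in isolation.

Corrupted corpora rewrite a seeded fraction of reports through five
misdiagnosis mechanisms, mutually exclusive per report, with gold set to
the *expert* answer so the pipeline is expected to err: (1) a cytology
lipoma described as aspirated fat without the word "lipoma"; (2) multiple
tumours without delimiters; (3) a provisional phrasing ("not excluded",
"cannot exclude", "DDx") whose correct reading is non-tumour; (4) a generic
tumour word with the wrong location (a perianal carcinoma where the lesion
is in the anal sacs); (5) a generic diagnosis where the specific one was
never written (mesenchymal neoplasia for a soft tissue sarcoma). The
reference failure mix is 23 corrupted reports per 400 with reasons
6/7/6/2/2.

What the generator does **not** emulate: free narrative, negation outside
the uncertainty vocabulary, misspellings, out-of-vocabulary diagnoses, or
laboratory keyword conventions beyond the two bundled dialects. A perfect
score on clean synthetic corpora therefore demonstrates internal
consistency of the pipeline, not performance on real clinical text.

## Validation

Scoring is at report level: a report succeeds when the full multiset of its
gold tumour types is recovered after normalization (exact preferred-term
match — the stricter of the plausible readings; partial recovery counts as
failure). Strata are gold lesion count (single, where non-tumour reports
also land, vs multiple) × assay type. Errors run through a rule-based
classifier for the five mechanisms, tried in order; reason 4 is recognised
as a shared *base family* (via the shipped is-a table, with catch-all
labels de-aliased to their generic type) plus a location mismatch, and
reason 5 as the predicted type being a hierarchy ancestor of the gold type.
Two additions beyond the reference design are clearly labelled as such:
exact Clopper–Pearson 95% intervals per stratum, and a per-lesion F1
convenience metric.

## Numerical and design choices

- Character indexing in section spans is 1-based with half-open intervals,
  mirroring spreadsheet-style position arithmetic while keeping span
  algebra clean.
- `CLINICAL DIAGNOSIS` is accepted as a synonym boundary for
  `CLINICAL HISTORY` (both appear in the wild; dialect config decides).
- Submission grouping is by *runs* of consecutive equal sample references;
  a non-adjacent repeat is a distinct submission plus a warning — global
  deduplication is never attempted because no animal identifier exists.
- Fragment joining uses a single newline; keyword search is line-agnostic,
  and the join is length-conserving (checked by property test).
- Dates parse day-first (UK exports); two-digit years pivot at 2000.
- Ties when several keyword phrases match at one position go to the longest
  phrase, so compound headers beat their own suffixes.
- The acceptance script uses a clean corpus of 1,000 reports and fifty
  corrupted corpora of 400 reports — large enough that binomial noise on
  the mean accuracy is ~0.2 percentage points, small enough to run in
  seconds.

## Known limitations

- Substring matching without word boundaries produces occasional false
  positives by construction; the lexicons manage, not eliminate, this.
- Location may record the sampling site, not the tumour site; the
  registry preserves what the report says.
- No animal ID exists, so repeat submissions of one tumour are counted
  repeatedly; the registry is a pathology-based sample, never a
  population denominator, and must not be used for incidence estimates.
- The bundled lexicons are a reduced working set suitable for the synthetic
  vocabulary; real deployments should load a fully curated lexicon
  directory (the loaders accept drop-in replacements of the same format).
- Human ICD-O codes are not emitted; veterinary tumour vocabularies do not
  yet map cleanly onto them, and the schema simply leaves room for a future
  code column.
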