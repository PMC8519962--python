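# Per-laboratory dialect configuration.
#
# Each dialect names the section keywords used by one submitting laboratory,
# split by assay type, plus the mapping from assay codes to assay types.
# Keyword phrases are matched case-insensitively as plain substrings;
# list order is only cosmetic (the earliest occurrence in the text wins).
dialects:
  default:
    # assay-code tokens are tested as substrings of the uppercased code,
    # in order; first hit wins.
    assay_codes:
      - [CYT, cytology]
      - [HISTO, histology]
      - [HIST, histology]
      - [BIOPSY, histology]
    keywords:
      histology:
        diagnosis_start: [DIAGNOSIS]
        prognosis: [PROGNOSIS]
        clinical_history: [CLINICAL HISTORY, CLINICAL DIAGNOSIS]
        histology: [HISTOLOGY]
        comments: [COMMENTS]
      cytology:
        diagnosis_start: [CYTOLOGICAL INTERPRETATION]
        prognosis: [PROGNOSIS]
        clinical_history: [CLINICAL HISTORY, CLINICAL DIAGNOSIS]
        histology: [HISTOLOGY]
        comments: [COMMENTS]
  # A second keyword convention seen in practice: the interpretation header
  # is shortened and histology reports open with a morphological diagnosis.
  alt:
    assay_codes:
      - [CYT, cytology]
      - [HISTO, histology]
      - [HIST, histology]
    keywords:
      histology:
        diagnosis_start: [MORPHOLOGICAL DIAGNOSIS, DIAGNOSIS]
        prognosis: [PROGNOSIS]
        clinical_history: [CLINICAL HISTORY, CLINICAL DIAGNOSIS]
        histology: [HISTOLOGY]
        comments: [COMMENTS]
      cytology:
        diagnosis_start: [CYTOLOGIC INTERPRETATION, INTERPRETATION]
        prognosis: [PROGNOSIS]
        clinical_history: [CLINICAL HISTORY, CLINICAL DIAGNOSIS]
        histology: [HISTOLOGY]
        comments: [COMMENTS]
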