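# Three-tier grade look-up table (Patnaik scheme for mast cell tumours,
# also mammary carcinomas and soft tissue sarcomas).
# Roman numerals are ordered III > II > I so that the longer numeral wins
# under substring matching.
grade III
grade II
grade I
grade 3
grade 2
grade 1
third grade
second grade
first grade
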