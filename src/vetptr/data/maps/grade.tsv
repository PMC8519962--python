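# surface form	preferred term
grade I	grade 1
grade II	grade 2
grade III	grade 3
first grade	grade 1
second grade	grade 2
third grade	grade 3
Low grade	Low-grade
Intermediate grade	Intermediate-grade
High grade	High-grade
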