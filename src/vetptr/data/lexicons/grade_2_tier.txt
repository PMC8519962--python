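# Two-tier grade look-up table (Kiupel scheme for mast cell tumours,
# also used for lymphomas). Order = match priority.
Low-grade
Low grade
Intermediate-grade
Intermediate grade
High-grade
High grade
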