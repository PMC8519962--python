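# Degree-of-differentiation look-up table. Order = match priority.
Malignant transformation
Well-differentiated
Well differentiated
Moderately-differentiated
Moderately differentiated
Poorly-differentiated
Poorly differentiated
Undifferentiated
Malignant
Benign
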