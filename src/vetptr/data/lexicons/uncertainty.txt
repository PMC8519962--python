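# Uncertainty / hedging terms expressing the pathologist's confidence in
# the diagnosis. Order = match priority ("Highly likely" above "Likely").
Highly likely
Highly suggestive
Consistent with
Compatible with
Keeping with
Indicative of
Suggestive of
Suspicious of
Favoured
Inconclusive
Probable
Possible
Likely
Suspect
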