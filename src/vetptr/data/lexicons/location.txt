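# Lesion-location look-up table. Order = match priority: compound site
# names sit above the single words they contain ("Anal sac" above "Anal",
# "Forelimb" above "Limb", "Subcutaneous" above "Cutaneous").
# The maps_to flag carries the adjective-to-noun pairing consumed by the
# normalizer (matching records the surface form; normalization maps it).
Mammary gland
Mammary	maps_to=Mammary gland
Anal sac
Anal gland	maps_to=Anal sac
Perianal
Anal region
Anal	maps_to=Anal region
Axilla
Forelimb
Hindlimb
Oral cavity
Mouth	maps_to=Oral cavity
Thyroid gland
Thyroid	maps_to=Thyroid gland
Testicle
Testis	maps_to=Testicle
Testicular	maps_to=Testicle
Bladder
Spleen
Splenic	maps_to=Spleen
Liver
Hepatic	maps_to=Liver
Brain
Eyelid
Eye
Ear
Neck
Head
Chest	maps_to=Thorax
Thorax
Abdomen
Abdominal	maps_to=Abdomen
Subcutis
Subcutaneous	maps_to=Subcutis
Cutaneous	maps_to=Skin
Skin
Leg	maps_to=Limb
Limb
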