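# surface form	preferred breed (FIFE/TICA naming)
Domestic short hair	Domestic Short Hair
Domestic shorthair	Domestic Short Hair
DSH	Domestic Short Hair
Domestic long hair	Domestic Long Hair
Domestic longhair	Domestic Long Hair
DLH	Domestic Long Hair
British blue	British Blue
British shorthair	British Short Hair
Maine coon	Maine Coon
Siamese	Siamese
Bengal	Bengal
Ragdoll	Ragdoll
Persian	Persian
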