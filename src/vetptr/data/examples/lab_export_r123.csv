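LABNO,RECD,SPECIES,BREED,GENDER,PRACTICE_ID,ASSAY_CODE,RESCOMMENT1
R.123,09/05/18,Canine,Labrador retriever,Female entire,XXXX XXX,HISTO,"<br>DIAGNOSIS<br>1. Malignant mixed mammary gland tumour, gland three<br>2. Simple intratubular tubulopapillary carcinoma of the mammary gland, grade 2 - gland four<br>3.Consistent with MCT (second grade), forelimb<br>4. Low-grade cutaneous Lymphoma, highly likely><br>PROGNOSIS&nbsp;&nbsp; <br> Cautious <br> CLINICAL HISTORY <br> Two mammary masses and a forelimb mass removed. Samples from skin lesions were also taken <br><br> HISTOLOGY&nbsp;&nbsp; <br> Four specimens are submitted and evaluated"
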