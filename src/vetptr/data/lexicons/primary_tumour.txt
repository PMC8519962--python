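# Primary tumour look-up table (reduced bundled edition).
# One surface form per line; order encodes match priority: specific
# diagnoses sit above generic "capture terms". Optional tab-separated
# flags: excluded (lesion is not a registrable neoplasm).
(hepatoid gland) adenocarcinoma
(hepatoid, circumanal) gland adenocarcinoma
(hepatoid, circumanal) gland adenoma
(hepatoid, circumanal) gland carcinoma
(hepatoid gland) adenoma
(hepatoid gland) carcinoma
Perianal (hepatoid) adenoma
Hepatoid gland adenoma
Hepatoid adenoma
Adenoma of the hepatoid glands
Hepatoid (perianal) carcinoma
Hepatoid carcinoma
adenocarcinoma of the anal sac apocrine glands
adenocarcinoma of the apocrine glands
Anal sac carcinoma
Simple intratubular tubulopapillary carcinoma
adenocarcinoma of the mammary gland, tubulopapillary
Adenocarcinoma arising in mixed gland mammary
Adenocarcinoma arising in mixed mammary
Mixed mammary gland tumour
Apocrine ductal carcinoma
adenocarcinoma of the Parathyroid gland
adenocarcinoma (anaplastic)
Squamous cell carcinoma
Transitional cell carcinoma
Hepatocellular carcinoma
Thyroid carcinoma
Islet cell carcinoma
Mammary gland carcinoma
Mast cell tumour
MCT
Peripheral nerve sheath tumour
Soft tissue sarcoma
Osteosarcoma
Haemangiosarcoma
Histiocytic sarcoma
Fibrosarcoma
Liposarcoma
Histiocytoma
Melanocytic tumour
Melanoma
Plasma cell tumour
Plasmacytoma
Multiple myeloma
Lymphoma
Leukaemia
Seminoma
Sertoli cell tumour
Basal cell tumour
Meibomian adenoma
Peripheral odontogenic fibroma
Rectal adenoma
Lipoma
Hamartoma	excluded
Epidermoid cyst	excluded
Follicular cyst	excluded
Cyst	excluded
Epithelial tumour
Epithelial neoplasia
Mesenchymal neoplasia
Adenocarcinoma
Carcinoma
Adenoma
Epithelioma
Sarcoma
Neoplasia
Neoplasm
Tumour
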