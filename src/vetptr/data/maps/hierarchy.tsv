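# Tumour-type is-a table: child	parent. Used by the validation module to
# recognise generic-vs-specific diagnoses (e.g. mesenchymal neoplasia is an
# ancestor of soft tissue sarcoma) and shared base families.
Soft tissue sarcoma	Mesenchymal neoplasia
Fibrosarcoma	Soft tissue sarcoma
Liposarcoma	Mesenchymal neoplasia
Osteosarcoma	Mesenchymal neoplasia
Haemangiosarcoma	Mesenchymal neoplasia
Histiocytic sarcoma	Mesenchymal neoplasia
Lipoma	Mesenchymal neoplasia
Sarcoma	Mesenchymal neoplasia
Anal sac carcinoma	Carcinoma
Hepatoid (perianal) carcinoma	Carcinoma
Thyroid carcinoma	Carcinoma
Squamous cell carcinoma	Carcinoma
Transitional cell carcinoma	Carcinoma
Hepatocellular carcinoma	Carcinoma
Mammary gland carcinoma	Carcinoma
Simple tubulo-papillary carcinoma	Carcinoma
Carcinoma arising in mixed tumour	Carcinoma
Adenocarcinoma	Carcinoma
Adenoma of the hepatoid glands	Adenoma
Meibomian adenoma	Adenoma
Rectal adenoma	Adenoma
Basal cell tumour	Epithelial tumour
Carcinoma	Epithelial tumour
Adenoma	Epithelial tumour
Epithelioma	Epithelial tumour
Epithelial neoplasia	Epithelial tumour
Epithelial tumour	Neoplasia
Mesenchymal neoplasia	Neoplasia
Melanoma	Melanocytic tumour
Melanocytic tumour	Neoplasia
Lymphoma	Neoplasia
Leukaemia	Neoplasia
Mast cell tumour	Neoplasia
Plasma cell tumour	Neoplasia
Seminoma	Neoplasia
Sertoli cell tumour	Neoplasia
Histiocytoma	Neoplasia
Mixed tumour	Neoplasia
Tumour	Neoplasia
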