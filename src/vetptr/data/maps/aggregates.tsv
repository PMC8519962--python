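# Named aggregations and generic capture terms mapped to their registry
# label. Catch-all labels end in "_others".
# preferred term	aggregate label
Plasmacytoma	Plasma cell tumour
Multiple myeloma	Plasma cell tumour
Islet cell carcinoma	Carcinoma_others
Carcinoma	Carcinoma_others
Adenocarcinoma	Carcinoma_others
Adenoma	Adenoma_others
Epithelioma	Epithelioma_others
Epithelial tumour	Epithelial tumour_others
Epithelial neoplasia	Epithelial tumour_others
Mesenchymal neoplasia	Mesenchymal_neoplasias_others
Sarcoma	Mesenchymal_neoplasias_others
Leukaemia	Neoplasia_Tumours_others
Neoplasia	Neoplasia_Tumours_others
Tumour	Neoplasia_Tumours_others
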