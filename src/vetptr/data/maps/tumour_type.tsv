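# surface form	preferred term
MCT	Mast cell tumour
Mixed mammary gland tumour	Mixed tumour
Simple intratubular tubulopapillary carcinoma	Simple tubulo-papillary carcinoma
adenocarcinoma of the mammary gland, tubulopapillary	Simple tubulo-papillary carcinoma
(hepatoid gland) adenoma	Adenoma of the hepatoid glands
(hepatoid, circumanal) gland adenoma	Adenoma of the hepatoid glands
Perianal (hepatoid) adenoma	Adenoma of the hepatoid glands
Hepatoid adenoma	Adenoma of the hepatoid glands
Hepatoid gland adenoma	Adenoma of the hepatoid glands
(hepatoid gland) adenocarcinoma	Hepatoid (perianal) carcinoma
(hepatoid gland) carcinoma	Hepatoid (perianal) carcinoma
(hepatoid, circumanal) gland adenocarcinoma	Hepatoid (perianal) carcinoma
(hepatoid, circumanal) gland carcinoma	Hepatoid (perianal) carcinoma
Hepatoid carcinoma	Hepatoid (perianal) carcinoma
adenocarcinoma of the anal sac apocrine glands	Anal sac carcinoma
adenocarcinoma of the apocrine glands	Anal sac carcinoma
Adenocarcinoma arising in mixed gland mammary	Carcinoma arising in mixed tumour
Adenocarcinoma arising in mixed mammary	Carcinoma arising in mixed tumour
Neoplasm	Neoplasia
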