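# surface form	preferred breed (FCI/AKC naming, plus recognised hybrids)
Labrador retriever	Labrador Retriever
Retriever, Labrador	Labrador Retriever
Labrador	Labrador Retriever
Golden retriever	Golden Retriever
Retriever, Golden	Golden Retriever
Crossbreed	Crossbreed
Cross breed	Crossbreed
X breed	Crossbreed
Staffordshire bull terrier	Staffordshire Bull Terrier
Staffie	Staffordshire Bull Terrier
Cocker spaniel	Cocker Spaniel
Spaniel, Cocker	Cocker Spaniel
Springer spaniel	English Springer Spaniel
English springer spaniel	English Springer Spaniel
German shepherd dog	German Shepherd Dog
Shepherd, German	German Shepherd Dog
GSD	German Shepherd Dog
Jack russell terrier	Jack Russell Terrier
JRT	Jack Russell Terrier
Border collie	Border Collie
French bulldog	French Bulldog
Boxer	Boxer
Pug	Pug
Labradoodle	Labradoodle
Cockapoo	Cockapoo
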