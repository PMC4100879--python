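S-Adenosylhomocysteine hydrolase deficiency	AHCY
Alkaptonuria	HGD
Argininemia	ARG1
Cystinuria	SLC3A1,SLC7A9
Lysinuric protein intolerance	SLC7A7
Formiminotransferase deficiency	FTCD
Histidinemia	HAL
Homocystinuria	CBS
Hyperprolinemia	PRODH
Maple syrup urine disease	DBT,BCKDHB,BCKDHA
Methionine adenosyltransferase deficiency	MAT1A
Methylmalonic aciduria	MUT
Phenylketonuria	PAH
Hyperphenylalaninemia	QDPR
Tyrosinemia type I	FAH
Tyrosinemia type III	HPD
Glycine encephalopathy	AMT,GLDC,GCSH
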