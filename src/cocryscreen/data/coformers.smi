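# Fixture molecule library: API, named coformers and generic filler
# coformers (amides, carboxylic acids, sulfonamides) for ranking tests.
# Format: name<TAB>SMILES
cilnidipine	COCCOC(=O)C1=C(C)NC(C)=C(C(=O)OC/C=C/c2ccccc2)C1c1cccc([N+](=O)[O-])c1
p-toluenesulfonamide	Cc1ccc(cc1)S(N)(=O)=O
naphthalene-2-sulfonamide	NS(=O)(=O)c1ccc2ccccc2c1
glycine	NCC(=O)O
L-valine	CC(C)[C@@H](N)C(=O)O
L-alanine	C[C@@H](N)C(=O)O
posaconazole	CC[C@@H]([C@H](C)O)N1C=NN(C1=O)c1ccc(cc1)N1CCN(CC1)c1ccc(cc1)OC[C@H]1CO[C@](C1)(Cn1cncn1)c1ccc(F)cc1F
urea	NC(N)=O
acetamide	CC(N)=O
benzamide	NC(=O)c1ccccc1
nicotinamide	NC(=O)c1cccnc1
isonicotinamide	NC(=O)c1ccncc1
saccharin	O=C1NS(=O)(=O)c2ccccc12
caffeine	Cn1cnc2c1c(=O)n(C)c(=O)n2C
theophylline	Cn1c(=O)c2[nH]cnc2n(C)c1=O
benzenesulfonamide	NS(=O)(=O)c1ccccc1
sulfanilamide	Nc1ccc(cc1)S(N)(=O)=O
methanesulfonamide	CS(N)(=O)=O
benzoic acid	OC(=O)c1ccccc1
salicylic acid	OC(=O)c1ccccc1O
4-aminobenzoic acid	Nc1ccc(cc1)C(=O)O
4-hydroxybenzoic acid	Oc1ccc(cc1)C(=O)O
nicotinic acid	OC(=O)c1cccnc1
oxalic acid	OC(=O)C(=O)O
malonic acid	OC(=O)CC(=O)O
succinic acid	OC(=O)CCC(=O)O
glutaric acid	OC(=O)CCCC(=O)O
adipic acid	OC(=O)CCCCC(=O)O
fumaric acid	OC(=O)/C=C/C(=O)O
maleic acid	OC(=O)/C=C\C(=O)O
citric acid	OC(=O)CC(O)(CC(=O)O)C(=O)O
L-tartaric acid	OC(=O)[C@H](O)[C@@H](O)C(=O)O
resorcinol	Oc1cccc(O)c1
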