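id,smiles,name,ic50,kd,cluster
ind_01,,"2-methyl-N-(1-(4-(trifluoromethyl)benzyl)-1H-indazol-3-yl)furan-3-carboxamide",0.2,nd,1
ind_02,,"4-methyl-N-(1-(4-(trifluoromethyl)benzyl)-1H-indazol-3-yl)isoxazole-5-carboxamide",0.19,nd,1
phe_01,,"N-(2,4-dichlorophenyl)-N-methylacetamide",nd,92,2
pyp_01,,"1-[(3R)-1,1-bis(oxidanylidene)thiolan-3-yl]-5-[(3,4-dichlorophenyl)methyl]pyrazolo[3,4-d]pyrimidin-4-one",67.6,29.5,3
iso_01,,"N-(1-methylpyrazol-4-yl)-1-oxidanylidene-2-(phenylmethyl)isoquinoline-4-carboxamide",67.9,29.3,4
iso_02,,"2-[(4-chlorophenyl)methyl]-N-(1-methylpyrazol-4-yl)-1-oxidanylidene-isoquinoline-4-carboxamide",4.6,2.7,4
iso_03,,"2-[(3-chlorophenyl)methyl]-N-(1-methylpyrazol-4-yl)-1-oxidanylidene-isoquinoline-4-carboxamide",11.4,7.6,4
iso_04,,"2-[(3,4-dichlorophenyl)methyl]-N-(1-methylpyrazol-4-yl)-1-oxidanylidene-isoquinoline-4-carboxamide",1.3,1.5,4
iso_05,,"2-(4-fluorobenzyl)-N-(1-methyl-1H-pyrazol-4-yl)-1-oxo-1,2-dihydroisoquinoline-4-carboxamide",nd,2.7,4
iso_06,,"2-(3-fluorobenzyl)-N-(1-methyl-1H-pyrazol-4-yl)-1-oxo-1,2-dihydroisoquinoline-4-carboxamide",nd,29.2,4
iso_07,,"2-(3-chloro-4-fluorobenzyl)-N-(1-methyl-1H-pyrazol-4-yl)-1-oxo-1,2-dihydroisoquinoline-4-carboxamide",2.1,1.2,4
iso_08,,"2-(4-fluoro-3-isocyanobenzyl)-N-(1-methyl-1H-pyrazol-4-yl)-1-oxo-1,2-dihydroisoquinoline-4-carboxamide",8.6,6.6,4
iso_09,,"2-(2,4-difluorobenzyl)-N-(1-methyl-1H-pyrazol-4-yl)-1-oxo-1,2-dihydroisoquinoline-4-carboxamide",nd,46,4
naph_01,,"2-[(3,4-dichlorophenyl)methyl]-N-(1-methylpyrazol-4-yl)-1-oxidanylidene-6-piperidin-4-yl-2,7-naphthyridine-4-carboxamide",0.51,0.25,5
naph_02,,"2-(3,4-dichlorobenzyl)-N-(1-methyl-1H-pyrazol-4-yl)-1-oxo-6-(pyrrolidin-1-yl)-1,2-dihydro-2,7-naphthyridine-4-carboxamide",nd,1.03,5
naph_03,,"2-(3,4-dichlorobenzyl)-N-(1-methyl-1H-pyrazol-4-yl)-1-oxo-6-(piperazin-1-yl)-1,2-dihydro-2,7-naphthyridine-4-carboxamide",0.63,0.58,5
naph_04,,"2-(3,4-dichlorobenzyl)-N-(1-methyl-1H-pyrazol-4-yl)-1-oxo-1,2-dihydro-2,6-naphthyridine-4-carboxamide",5.3,1.6,5
naph_05,,"2-(3,4-dichlorobenzyl)-N-(1-methyl-1H-pyrazol-4-yl)-1-oxo-1,2-dihydro-2,7-naphthyridine-4-carboxamide",3.8,1.3,5
naph_06,,"2-(3,4-dichlorobenzyl)-N-(1-methyl-1H-pyrazol-4-yl)-6-(methylamino)-1-oxo-1,2-dihydro-2,7-naphthyridine-4-carboxamide",nd,1.1,5
naph_07,,"2-(3,4-dichlorobenzyl)-N-(1-methyl-1H-pyrazol-4-yl)-6-(N-methylmethylsulfonamido)-1-oxo-1,2-dihydro-2,7-naphthyridine-4-carboxamide",nd,2,5
pzp_01,,"5-(3,4-dichlorobenzyl)-4-oxo-1-(piperidin-4-yl)-N-(pyridin-4-yl)-4,5-dihydro-1H-pyrazolo[4,3-c]pyridine-7-carboxamide",0.24,0.09,6
pzp_02,,"5-(3,4-dichlorobenzyl)-N-(1-methyl-1H-pyrazol-4-yl)-4-oxo-4,5-dihydro-1H-pyrazolo[4,3-c]pyridine-7-carboxamide",10.4,10,6
pzp_03,,"5-(3,4-dichlorobenzyl)-1-(1,1-dioxidotetrahydrothiophen-3-yl)-N-(1-methyl-1H-pyrazol-4-yl)-4-oxo-4,5-dihydro-1H-pyrazolo[4,3-c]pyridine-7-carboxamide",0.6,0.6,6
pzp_04,,"5-(3,4-dichlorobenzyl)-1-(1,1-dioxidotetrahydrothiophen-3-yl)-4-oxo-N-(pyridin-4-yl)-4,5-dihydro-1H-pyrazolo[4,3-c]pyridine-7-carboxamide",0.33,0.27,6
pyr_01,,"5-amino-1-(3,4-dichlorobenzyl)-6-oxo-N-(1-(pyrrolidin-3-yl)-1H-pyrazol-4-yl)-1,6-dihydropyridine-3-carboxamide",<100,21,7
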