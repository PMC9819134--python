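cluster	compound
1	Methanone
1	Thymol blue
1	Peracetyl-[1R-(1.alpha.,4a.beta.,10a.alpha.)]-1,2,3,4,4a,9,10,10a-octahydro-1,4a-dimethyl-7-(1'-methylethyl)-1-phenanthrenem
1	(E)-4,5-diphenyl-2-methyl-3-pentenoic
1	2,3,5-Trichloro-4,6-di(p-tolyl)thiopyridine
1	1,2,3,4-Tetrahydroisoquinoline-N-phosphorodiamide, N,N,N',N'-tetramethyl, 1-(2,2-dimethyl-1-hydroxypropyl)-
1	Diethyl Phthalate
1	1-Undecene, 4-methyl-
1	1-Bromo-4-bromomethyldecane
1	Sulfurous acid, dodecyl 2-propyl ester
1	1,2-Benzenedicarboxylic acid, dibutyl ester
1	Hexahydropyridine, 1-methyl-4-[4,5-dihydroxyphenyl]-
1	ilane, trimethyl[5-methyl-2-(1-methylethyl)phenoxy]-
1	4-Acetamido-N-tert-butyl-3-nitrobenzamide
1	3,9-Epoxypregn-16-ene-14,20-diol, 7,11,18-triacetoxy-3-methoxy-
1	dimethyl cis-8,8-dimethyl-5-oxobicyclo[5.1.0]oct-3-ene-1,7-dicarboxylate
1	Tris(2-pyridinecarboxylato-N(1),o(2))chromium(iii)
1	Olean-12-en-28-oic acid, 3.beta.-hydroxy-21-oxo-, methyl ester
1	3-Hydroxy-dl-kynurenine
1	tannane, trimethyl(p-neopentylphenyl)-
1	6-Nitro-1H-quinazoline-2,4-dione
2	TRISTRIMETHYLSILYL ETHER DERIVATIVE OF 1,25-DIHYDROXYVITAMIN D2
2	3,5,6-TRIMETHOXY-2-METHYLCHROMONE
2	3-(2-Hydroxy-6-methylphenyl)-4(3H)-quinazolinone
2	6-Dimethyl(chloromethyl)silyloxytridecane
2	1-Benzenesulfonyl-1H-pyrrole
2	Cyclotrisiloxane, hexamethyl-
2	Arabinitol, pentaacetate
2	1,1,1,3,5,7,9,9,9-Nonamethylpentasiloxane
2	Cyclopentasiloxane, decamethyl-
2	9,10 DIDEUTERO OCTADECANAL
2	3-Butoxy-1,1,1,7,7,7-hexamethyl-3,5,5-tris(trimethylsiloxy)tetrasiloxane
2	1-Tetradecanol
2	QUERCETIN 7,3',4'-TRIMETHOXY
2	Phthalic acid, bis(7-methyloctyl) ester
2	Cyclopropanetetradecanoic acid, 2-octyl-, methyl ester
2	ISOCHIAPIN B
2	Acetic acid, 17-(4-hydroxy-5-methoxy-1,5-dimethylhexyl)-4,4,10,13,14-pentamethyl-2,3,4,5,6,7,10,11,12,13,14,15,16,17-tetradec
2	Dotriacontane
2	Tetrapentacontane, 1,54-dibromo-
2	Phthalic acid, butyl undecyl ester
2	cis-1-Chloro-9-octadecene
2	Silicone oil
2	03027205002 FLAVONE 4'-OH,5-OH,7-DI-O-GLUCOSIDE
2	Dibutyl phthalate
2	2,4,6(1H,3H,5H)-Pyrimidinetrione, 5-(1-cyclohexen-1-yl)-5-ethyl-
2	9,9-Dimethoxybicyclo[3.3.1]nona-2,4-dione
2	Heptasiloxane, hexadecamethyl
2	Octadecanal, 2-bromo-
2	1,2-Bis(trimethylsilyl)benzene
2	1,2-Benzenedicarboxylic acid, bis(2-ethylhexyl) ester
2	Octasiloxane, 1,1,3,3,5,5,7,7,9,9,11,11,13,13,15,15-hexadecamethyl-
2	Cyclobuta[1,2:3,4]dicyclooctene, hexadecahydro-, (6a.alpha.,6b.alpha.,12a.alpha.,12b.alpha.)-
3	1H,1H,2H,2H-Perfluorooctyl iodide
3	Benzenesulfonic acid, N'-[2-(hydroxyimino)-1-methylpropylidene]hydrazide
3	Me-t-BDMS of LTB4
3	Quinovic Acid
3	1,2-Thiagermolane, 2,2-dibutyl-
3	2-Chloro-3-(4-chloro-2-phenyloxazol-5-yl)-indol-1-carboxylic acid, 2,2,2-trichloroethyl ester
3	2-Dodecyl-3-methoxy-5-(2-methylpropyl) phenylester of 17-(4-Methoxyphenyl)-2,4,6,8,10,12,14,16-heptadecaoctaenoic acid
3	1'H-Cholest-2-eno[3,2-b]indol-6-one, 1'-(phenylmethyl)-, oxime, (5.alpha.)-
3	Rhodium, bis(trimethylphosphine)-chloro-.eta.2-1,2-(2,4-di-t-butyl-1,3-diphosphacyclobutadiene)-
3	butyl decanoate
3	1,3,4-Tribromo-2,5-dichlorobenzene
3	3-Methyl-2-(phenylselenyl)butyric acid, ethyl ester
3	Pentanoic acid, 4-nitro-, methyl ester
3	T-2 TOXIN TRIMETHYLSILYL ETHER
3	Podocarpan-14.beta.-ol
3	Benzene, 4,6-difluoro-1,2,3,5-tetrakis(phenylthio)-
4	1,4-Diethylpiperazine
4	Chloroform
4	11-Methoxymacusine a
4	Acenaphthylene
4	Octasiloxane
4	methyl [G-(14)-C] palmitate
4	Butanoic acid, trimethylsilyl ester
4	Phthalic acid, di-(1-hexen-5-yl) ester
4	PROPYL 2-PHENYLSULPHONYLAMIDOACETATE
4	2-Acetylphenoxathin thiosemicarbazone
4	N-(Benzoylcarbonyl)-6-cyano-6-undecyl-2-methylpiperidine
4	Clomipramine
4	Phosphoric acid, 2,3-bis(trimethylsiloxy)propyl dimethyl ester
4	Stannane, tetrapropyl-
4	1,4-Naphthalenedione, 2,3-dichloro-
4	Acetamide, 2,2-dichloro-N-(2-chloro-3-pyridyl)-
4	6-Norlysergic acid diethylamide
4	5,5-Dimethyl-4-methylene-3-[2-(2-methyl-7-trifluoromethyl-1H-indol-3-yl)-ethyl]-oxazolidin-2-one
4	(2,4-DICHLORO-6-NITROPHENOXY)ACETIC ACID
4	1-Methyl-1-(3-methylbutyl)oxy-1-silacyclopentane
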