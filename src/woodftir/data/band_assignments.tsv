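constituent	center_cm1	functional_group	literature_ref
extractives	1730	C=O stretching, ester carbonyl	lipophilic extractives band compilations
extractives	1633	olefinic C=C stretching	lipophilic extractives band compilations
extractives	1600	C=C stretching / aromatic ring deformation	wood extractives band compilations
extractives	1510	benzene ring deformation vibration	aromatic wood compounds band compilations
extractives	1271	C-O stretching with in-plane C-OH bending, carboxylic acids	wood extractives band compilations
lignin	1735	C=O stretching	lignin band compilations
lignin	1658	conjugated C=O stretching	lignin band compilations
lignin	1510	aromatic skeletal vibration	lignin band compilations
lignin	1425	aromatic skeletal vibration with C-H in-plane deformation	lignin band compilations
lignin	1375	phenolic O-H plus aliphatic C-H in methyl groups	lignin band compilations
lignin	1328	aromatic skeletal vibration, S ring breathing	lignin band compilations
lignin	1269	G ring breathing with C=O stretching	lignin band compilations
lignin	1220	C-C, C-O and C=O stretching	lignin band compilations
lignin	1140	aromatic C-H in-plane deformation of G ring, secondary alcohols and C=O stretch	lignin band compilations
lignin	1116	aromatic C-H deformation in S ring	lignin band compilations
lignin	1033	aromatic C-H in-plane deformation, C-O deformation in primary alcohols, C=O stretch	lignin band compilations
lignin	835	C-H out-of-plane deformation in positions 2 and 6 of S ring	lignin band compilations
cellulose	1440	O-H in-plane bending	cellulose band compilations
cellulose	1380	C-H bending	cellulose band compilations
cellulose	1310	CH2 wagging	cellulose band compilations
cellulose	1280	C-H bending	cellulose band compilations
cellulose	1220	O-H in-plane bending	cellulose band compilations
cellulose	1160	C-O-C asymmetric stretching	cellulose band compilations
cellulose	1047	C-O stretching	cellulose band compilations
cellulose	1004	C-O stretching	cellulose band compilations
hemicellulose	1639	absorbed water / conjugated carbonyl groups	hemicellulose band compilations
hemicellulose	1453	CH2 symmetric bending	hemicellulose band compilations
hemicellulose	1426	C-H and O-H bending	hemicellulose band compilations
hemicellulose	1338	C-H wagging	hemicellulose band compilations
hemicellulose	1051	glycosidic C-O-C stretching	hemicellulose band compilations
hemicellulose	1008	glycosidic C-O-C stretching	hemicellulose band compilations
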