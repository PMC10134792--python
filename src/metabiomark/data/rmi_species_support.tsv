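species	phylum	prevalence_pct	supporting_datasets
Faecalibacterium_prausnitzii	Firmicutes	94	Frankel 2017;Gopalakrishnan 2018;Matson 2018;Baruch 2021;Davar 2021
Roseburia_faecis	Firmicutes	70	Gopalakrishnan 2018;Matson 2018;Baruch 2021;Davar 2021
Bacteroides_ovatus	Bacteroidetes	96	Gopalakrishnan 2018;Matson 2018;Davar 2021
Bacteroides_vulgatus	Bacteroidetes	99	Gopalakrishnan 2018;Matson 2018;Davar 2021
Blautia_wexlerae	Firmicutes	80	Frankel 2017;Matson 2018;Baruch 2021
Collinsella_aerofaciens	Actinobacteria	79	Matson 2018;Baruch 2021;Davar 2021
Eubacterium_siraeum	Firmicutes	52	Frankel 2017;Gopalakrishnan 2018;Matson 2018
Roseburia_hominis	Firmicutes	71	Frankel 2017;Gopalakrishnan 2018;Davar 2021
Ruminococcus_bromii	Firmicutes	47	Frankel 2017;Gopalakrishnan 2018;Davar 2021
Acidaminococcus_intestini	Firmicutes	36	Baruch 2021;Davar 2021
Bifidobacterium_adolescentis	Actinobacteria	47	Matson 2018;Baruch 2021
Bifidobacterium_longum	Actinobacteria	53	Matson 2018;Baruch 2021
Eubacterium_rectale	Firmicutes	87	Baruch 2021;Davar 2021
Fusicatenibacter_saccharivorans	Firmicutes	79	Gopalakrishnan 2018;Baruch 2021
Parabacteroides_distasonis	Bacteroidetes	96	Gopalakrishnan 2018;Davar 2021
Parabacteroides_merdae	Bacteroidetes	89	Matson 2018;Davar 2021
Phascolarctobacterium_faecium	Firmicutes	59	Gopalakrishnan 2018;Davar 2021
Ruminococcus_bicirculans	Firmicutes	46	Frankel 2017;Gopalakrishnan 2018
Ruthenibacterium_lactatiformans	Firmicutes	95	Matson 2018;Davar 2021
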