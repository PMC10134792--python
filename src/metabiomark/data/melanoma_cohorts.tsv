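dataset	phase	immunotherapy	individuals	samples	responders	nonresponders	reads_mean_mln	reads_sd_mln	platform	read_length_bp
Frankel 2017	discovery	anti-PD1/anti-CTLA4	39	39	19	20	36.8	10.6	Illumina	100
Gopalakrishnan 2018	discovery	anti-PD1	25	25	14	11	15.9	4.0	Illumina	100
Matson 2018	discovery	anti-PD1	38	38	14	24	39.7	16.9	Illumina	150
Baruch 2021	fmt	anti-PD1	10	42	3	7	15.8	5.5	Illumina	150
Davar 2021	fmt	anti-PD1	15	214	3	12	11.1	3.8	Illumina	150
Spencer 2021	validation	anti-PD1	158	158	100	58	12.5	7.8	Illumina	100-150
Lee 2022	validation	anti-PD1/anti-CTLA4	164	164	100	64	24.7	18.3	Illumina	150
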