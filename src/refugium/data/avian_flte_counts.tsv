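species	count_type	autosomes	chr_z	chr_w	male_2n	female_2n
Calypte_anna	line_dna	1	0	1	2	5
Calypte_anna	flerv_rt	171	71	503	484	916
Calypte_anna	flerv_ltrhd	302	63	671	730	1338
Dromaius_novaehollandiae	line_dna	9	2	0	22	40
Dromaius_novaehollandiae	flerv_rt	129	0	1	258	259
Dromaius_novaehollandiae	flerv_ltrhd	261	32	111	586	665
Gallus_gallus	line_dna	7	0	3	14	31
Gallus_gallus	flerv_rt	392	74	244	932	1102
Gallus_gallus	flerv_ltrhd	232	68	246	600	778
Lycocorax_pyrrhopterus	line_dna	1	0	0	2	4
Lycocorax_pyrrhopterus	flerv_rt	396	83	439	958	1314
Lycocorax_pyrrhopterus	flerv_ltrhd	558	88	678	1292	1882
Strigops_habroptila	line_dna	7	0	1	14	29
Strigops_habroptila	flerv_rt	354	102	458	912	1268
Strigops_habroptila	flerv_ltrhd	911	225	871	2272	2918
Taeniopygia_guttata	line_dna	0	0	0	0	0
Taeniopygia_guttata	flerv_rt	298	149	450	894	1195
Taeniopygia_guttata	flerv_ltrhd	552	184	723	1472	2011
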