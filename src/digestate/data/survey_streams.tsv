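# Nine-plant full-scale biogas survey: process streams.
# Digester/post-digester rows carry measured TS, VS-of-TS, pH, NH4-N and the
# plant-reported VS reduction; operating points (T, HRT, OLR) sit on the rows
# of the stage they describe.  Parallel digestion lines (AWM-A/B, WWTP2-A/B)
# are separate plants sharing a site.
# Macromolecule detail (protein, fat, NDF/ADF/ADL) is bundled only for the
# FW1 and FW-TD lines, reconstructed from the published aggregate values
# (VS shares and degradation efficiencies); synthetic reconstruction, see the
# package methods note.  vol_red is set to 0 for these lines because the
# published stream concentrations are used as given.
site	plant	stream_id	role	component_name	volume_fraction[frac]	density[kg/L]	temperature[C]	hrt[d]	olr[kgVS/m3/d]	specific_gas[NL/kg]	ch4_fraction[frac]	vol_red[frac]	vs_red_reported[frac]	ts[frac_ww]	vs_of_ts[frac_TS]	ph[-]	kjeldahl_n[g/kg_ww]	nh4_n[g/kg_ww]	protein[g/kg_ww]	crude_fat[g/kg_ww]	ndf[g/kg_ww]	adf[g/kg_ww]	adl[g/kg_ww]
FW1	FW1	FW1-S	substrate	food waste 60% + slaughterhouse waste 25% + industrial waste 15%	1.0	1.0								0.1333	0.90				27.0	38.4	36.0	24.0	9.6
FW1	FW1	FW1-D	digester			1.0	42	35	4.2			0.0	0.70	0.053	0.736	7.8	6.12	3.4	17.0	3.6	11.47	8.59	6.0
FW1	FW1	FW1-PD	post_digester			1.0	41	20				0.0	0.77	0.043	0.715	7.8	4.72	3.6	7.0	1.5	8.2	6.4	4.3
FW2	FW2	FW2-D	digester			1.0	37	30	3.0				0.48	0.039	0.667	7.9		3.6
FW2	FW2	FW2-PD	post_digester			1.0	37	5					0.50	0.038	0.655	7.9		3.8
FW3	FW3	FW3-D	digester			1.0	38	27	3.8				0.75	0.041	0.696	7.5		2.4
FW3	FW3	FW3-PD	post_digester			1.0	36	7					0.77	0.038	0.679	7.7		2.5
FW-TD	FW-TD	FWTD-S	substrate	municipal household waste 98% + garden waste 2%	1.0	1.0								0.20	0.90				36.0	19.8	66.6	39.6	18.0
FW-TD	FW-TD	FWTD-D	digester			1.0	55	27	4.7			0.0	0.65	0.116	0.666	7.8	6.136	3.8	14.6	4.1	29.6	21.7	12.0
AW1	AW1	AW1-D	digester			1.0	38	55	5.8				0.67	0.100	0.882	7.6		2.4
AW1	AW1	AW1-PD	post_digester			1.0	38	40					0.78	0.072	0.860	7.5		2.3
AW2	AW2	AW2-D	digester			1.0	38	40	3.1				0.66	0.086	0.818	7.3		3.3
AW2	AW2	AW2-PD	post_digester			1.0	38	45					0.77	0.063	0.773	7.8		2.4
AWM	AWM-A	AWMA-D	digester			1.0	38	55	3.4				0.62	0.073	0.741	7.9		2.0
AWM	AWM-B	AWMB-D	digester			1.0	38	55	3.4				0.62	0.074	0.742	7.8		3.4
WWTP1	WWTP1	WWTP1-D	digester			1.0	38	20	2.5				0.55	0.032	0.665	7.9		1.4
WWTP2	WWTP2-A	WWTP2A-D	digester			1.0	37	17	1.5				0.63	0.016	0.645	7.2		0.8
WWTP2	WWTP2-B	WWTP2B-D	digester			1.0	37	15	1.8				0.61	0.017	0.657	7.4		0.9
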