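# Long-format analyte panel for the survey fixture.
# VFA profiles: where only a total VFA concentration was published, it is
# carried as acetate equivalents (unit mg/L); FW-TD's profile is split into
# its published propionate share and an acetate remainder.
# Sugar monomers for the FW1 / FW-TD lines are synthetic reconstructions
# consistent with the published fiber fractions and free-sugar totals:
# glucose carries free sugars + cellulose (glucan), xylose hemicellulose.
plant	stream_id	group	analyte	value	unit
FW1	FW1-S	vfa	acetic	55.0	mmol/L
FW1	FW1-S	sugar	glucose	33.6	g/kg_ww
FW1	FW1-S	sugar	xylose	12.0	g/kg_ww
FW1	FW1-D	vfa	acetic	80.0	mg/L
FW1	FW1-D	sugar	glucose	2.59	g/kg_ww
FW1	FW1-D	sugar	xylose	2.88	g/kg_ww
FW1	FW1-PD	vfa	acetic	40.0	mg/L
FW1	FW1-PD	sugar	glucose	2.1	g/kg_ww
FW1	FW1-PD	sugar	xylose	1.8	g/kg_ww
FW2	FW2-D	vfa	acetic	1360.0	mg/L
FW2	FW2-PD	vfa	acetic	190.0	mg/L
FW3	FW3-D	vfa	acetic	40.0	mg/L
FW3	FW3-PD	vfa	acetic	20.0	mg/L
FW-TD	FWTD-S	sugar	glucose	66.6	g/kg_ww
FW-TD	FWTD-S	sugar	xylose	27.0	g/kg_ww
FW-TD	FWTD-D	vfa	propionic	7300.0	mg/L
FW-TD	FWTD-D	vfa	acetic	1150.0	mg/L
FW-TD	FWTD-D	sugar	glucose	9.7	g/kg_ww
FW-TD	FWTD-D	sugar	xylose	7.9	g/kg_ww
AW1	AW1-D	vfa	acetic	150.0	mg/L
AW1	AW1-PD	vfa	acetic	60.0	mg/L
AW2	AW2-D	vfa	acetic	320.0	mg/L
AW2	AW2-PD	vfa	acetic	2.0	mg/L
AWM-A	AWMA-D	vfa	acetic	370.0	mg/L
AWM-B	AWMB-D	vfa	acetic	420.0	mg/L
WWTP1	WWTP1-D	vfa	acetic	20.0	mg/L
WWTP2-A	WWTP2A-D	vfa	acetic	20.0	mg/L
WWTP2-B	WWTP2B-D	vfa	acetic	40.0	mg/L
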