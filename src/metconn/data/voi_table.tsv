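name	abbreviation	ml_mm	dv_mm	ap_mm	component
Left Hippocampus	Hp_L	-2.6	3.2	-3.2	IC1
Right Hippocampus	Hp_R	2.6	3.2	-3.2	IC1
Medial Prefrontal Cortex	MedF	0.0	3.8	4.0	IC1
Retrosplenial Cortex	Rsp	0.0	1.8	-6.4	IC5
Left Motor Cortex	Mot_L	-2.2	2.2	2.2	IC8
Right Motor Cortex	Mot_R	2.2	2.2	2.2	IC8
Left Somatosensory Cortex	SS_L	-5.0	3.8	0.6	IC9
Right Somatosensory Cortex	SS_R	5.0	3.8	0.6	IC9
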