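name	wt_im_sm	dpdz_im_sm
DLG1	2.81	1.25
TJP2	4.9	2.27
CSKP	1.34	1.12
SCRIB	1.42	1.44
TJP1	43.15	45.65
NEB2	26.48	28.06
NEB1	only_iM	only_iM
MPP5	only_iM	only_iM
PDZD8	only_sM	only_sM
AFAD	not_significant	0.44
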