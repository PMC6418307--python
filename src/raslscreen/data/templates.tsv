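gene	C1	C2	C3	C4	C5	C6	novel	null
Cx3cr1	0.0	1.5	0.0	0.0	0.0	0.0	-2.0	0.0
Aqp4	0.0	0.0	0.0	0.0	0.0	0.0	-2.0	0.0
Trem2	0.0	0.0	0.0	0.0	0.0	0.0	-2.0	0.0
Gfap	0.0	1.0	0.0	0.0	0.0	0.0	0.0	0.0
Aif1	0.0	0.0	0.0	1.5	0.0	0.0	0.0	0.0
C1qa	0.0	0.0	0.0	1.5	0.0	0.0	0.0	0.0
Csf1r	0.0	0.0	0.0	1.0	0.0	0.0	-1.0	0.0
P2ry12	0.0	0.0	0.0	-1.0	0.0	0.0	-1.5	0.0
Tmem119	0.0	0.0	0.0	-1.0	0.0	0.0	-1.5	0.0
Il1b	0.0	0.0	0.0	2.5	0.0	0.0	0.0	0.0
Tnf	0.0	0.0	0.0	2.5	0.0	0.0	0.0	0.0
Ccl2	0.0	0.0	0.0	2.0	0.0	0.0	0.0	0.0
Gsn	0.0	0.0	2.0	0.0	0.0	0.0	0.0	0.0
Pdlim2	0.0	0.0	2.0	0.0	0.0	0.0	0.0	0.0
Tubb3	0.0	0.0	1.0	0.0	0.0	0.0	0.0	0.0
Map2	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
Mapt	0.0	0.0	-1.5	0.0	0.0	0.0	0.0	0.0
Nefl	0.0	0.0	1.5	0.0	0.0	0.0	0.0	0.0
Gap43	0.0	0.0	1.5	0.0	0.0	0.0	0.0	0.0
Hmox1	0.0	2.5	0.0	0.0	0.0	0.0	0.0	0.0
Gsta4	0.0	2.0	0.0	0.0	0.0	0.0	0.0	0.0
Nqo1	0.0	1.5	0.0	0.0	0.0	1.0	0.0	0.0
Nfe2l2	0.0	0.0	0.0	0.0	0.0	1.0	0.0	0.0
Hspa5	0.0	0.0	0.0	0.0	0.0	2.0	0.0	0.0
Ddit3	0.0	1.0	0.0	0.0	1.0	1.5	0.0	0.0
Atf4	0.0	0.0	0.0	0.0	0.0	2.0	0.0	0.0
Fos	2.0	1.5	0.0	0.0	0.0	0.0	1.5	0.0
Vgf	1.5	0.0	0.0	0.0	0.0	0.0	0.0	0.0
Npas4	2.5	0.0	0.0	0.0	0.0	0.0	0.0	0.0
Arc	2.5	0.0	0.0	0.0	0.0	0.0	0.0	0.0
Egr1	2.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
Junb	2.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
Bdnf	1.5	0.0	0.0	0.0	0.0	0.0	0.0	0.0
Homer1	1.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
Nrxn1	0.0	-1.5	0.0	0.0	-2.5	0.0	1.5	0.0
Syt1	0.0	-2.0	0.0	0.0	0.0	0.0	0.0	0.0
Rbfox3	0.0	-2.0	0.0	0.0	0.0	0.0	0.0	0.0
Snap25	0.0	-1.5	0.0	0.0	0.0	0.0	0.0	0.0
Syn1	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
Dlg4	0.0	0.0	0.0	0.0	-2.0	0.0	0.0	0.0
Grin1	0.0	0.0	0.0	0.0	-1.5	0.0	0.0	0.0
Grin2b	0.0	0.0	0.0	0.0	-2.0	0.0	0.0	0.0
Gria1	0.0	0.0	0.0	0.0	-1.5	0.0	0.0	0.0
Stx1a	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
Gabra1	0.0	0.0	0.0	0.0	-2.0	0.0	0.0	0.0
Gad1	0.0	0.0	0.0	0.0	0.0	-1.5	0.0	0.0
Slc17a7	0.0	0.0	0.0	0.0	0.0	-1.5	0.0	0.0
Camk2a	0.0	0.0	-1.0	0.0	-1.0	0.0	0.0	0.0
Shank3	0.0	0.0	0.0	0.0	-2.0	0.0	0.0	0.0
Rest	0.0	0.0	0.0	0.0	0.0	0.0	2.0	0.0
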