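symbol	rho_female	rho_male
Fth1	0.76200	0.70108
Ftl1	0.73929	0.72690
Uqcrfs1	0.72211	0.72262
Slco1a1	0.71333	0.57202
Cyp2f2	0.71038	0.62087
Uqcrq	0.70934	0.69592
Cyc1	0.69421	0.74445
Uqcrc2	0.68905	0.76097
Nudt7	0.68766	0.49148
Fasn	0.68388	0.47521
Uqcrc1	0.66495	0.68388
Uqcr10	0.65462	0.76820
Ttc39c	0.64533	0.63430
Pklr	0.63326	0.61332
Mup3	0.62158	0.66288
Uqcrb	0.58028	0.72483
Cyp4a12a	0.56582	0.70212
Uqcrh	0.53278	0.63500
C4b	-0.49587	-0.66632
Hist1h1b	-0.55756	-0.49871
Stat3	-0.59607	-0.53795
Mbl2	-0.79608	-0.67011
Cdo1	-0.81612	-0.79608
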