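# fragment template (synthetic idealized geometry)
# kind: AMIDE_ANALOG
# resname: NMA
# net_charge: 0
# anchors: collinear_donor=N:H
# columns: name element x y z sigma epsilon
N	N	0.000000	0.000000	0.000000	3.250	0.170
H	H	1.010000	0.000000	0.000000	0.500	0.010
C	C	-0.647221	1.167617	0.000000	3.750	0.105
O	O	-1.874927	1.242707	-0.000000	2.960	0.210
CT1	C	0.224615	2.412728	0.000000	3.500	0.066
CT2	C	-0.702974	-1.268199	0.000000	3.500	0.066
H11	H	0.853911	2.415612	-0.889988	2.500	0.030
H12	H	-0.408815	3.299783	-0.000000	2.500	0.030
H13	H	0.853911	2.415612	0.889988	2.500	0.030
H21	H	-1.328521	-1.336846	-0.889988	2.500	0.030
H22	H	0.019709	-2.084182	-0.000000	2.500	0.030
H23	H	-1.328521	-1.336846	0.889988	2.500	0.030
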