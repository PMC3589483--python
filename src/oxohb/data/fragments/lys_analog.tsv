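# fragment template (synthetic idealized geometry)
# kind: LYS_ANALOG
# resname: LYS
# net_charge: 1
# anchors: collinear_donor=NZ:HZ1
# columns: name element x y z sigma epsilon
NZ	N	0.000000	0.000000	0.000000	3.250	0.170
HZ1	H	1.010000	0.000000	0.000000	0.500	0.010
HZ2	H	-0.336677	-0.476122	0.824655	0.500	0.010
HZ3	H	-0.336677	-0.476122	-0.824655	0.500	0.010
CE	C	-0.496637	1.404796	0.000000	3.500	0.066
HE1	H	-0.133282	1.918600	-0.889988	2.500	0.030
HE2	H	-1.586637	1.404796	-0.000000	2.500	0.030
HE3	H	-0.133282	1.918600	0.889988	2.500	0.030
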