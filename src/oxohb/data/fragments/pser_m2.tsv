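# fragment template (synthetic idealized geometry)
# kind: PSER_M2
# resname: SEP
# net_charge: -2
# anchors: center=P; collinear_oxygen=O1P; bidentate_oxygens=O1P,O2P
# columns: name element x y z sigma epsilon
P	P	0.000000	0.000000	0.000000	3.740	0.200
O1P	O	0.822405	1.266393	0.000000	2.960	0.210
O2P	O	0.822405	-1.266393	0.000000	2.960	0.210
O3P	O	-0.871812	0.000000	-1.232901	2.960	0.210
OG	O	-0.946869	-0.000000	1.339044	2.900	0.140
CB	C	-1.882692	1.052484	1.520459	3.500	0.066
HB1	H	-2.586442	1.060383	0.688129	2.500	0.030
HB2	H	-2.425102	0.899551	2.453467	2.500	0.030
HB3	H	-1.354832	2.005362	1.559029	2.500	0.030
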