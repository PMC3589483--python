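# fragment template (synthetic idealized geometry)
# kind: GLU_ANALOG
# resname: GLU
# net_charge: -1
# anchors: center=CD; collinear_oxygen=OE1; bidentate_oxygens=OE1,OE2
# columns: name element x y z sigma epsilon
CD	C	0.000000	0.000000	0.000000	3.750	0.105
OE1	O	0.567488	1.113758	0.000000	2.960	0.210
OE2	O	0.567488	-1.113758	0.000000	2.960	0.210
CG	C	-1.520000	0.000000	0.000000	3.500	0.066
HG2	H	-1.876451	-0.518640	0.889975	2.500	0.030
HG3	H	-1.876451	-0.518640	-0.889975	2.500	0.030
CB	C	-2.068303	1.428378	0.000000	3.500	0.066
HB1	H	-1.718796	1.951700	-0.889988	2.500	0.030
HB2	H	-3.157914	1.399275	-0.000000	2.500	0.030
HB3	H	-1.718796	1.951700	0.889988	2.500	0.030
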