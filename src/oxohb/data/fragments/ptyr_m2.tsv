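# fragment template (synthetic idealized geometry)
# kind: PTYR_M2
# resname: PTR
# net_charge: -2
# anchors: center=P; collinear_oxygen=O1P; bidentate_oxygens=O1P,O2P
# columns: name element x y z sigma epsilon
P	P	0.000000	0.000000	0.000000	3.740	0.200
O1P	O	0.822405	1.266393	0.000000	2.960	0.210
O2P	O	0.822405	-1.266393	0.000000	2.960	0.210
O3P	O	-0.871812	0.000000	-1.232901	2.960	0.210
OH	O	-0.946869	-0.000000	1.339044	2.900	0.140
CZ	C	-1.856331	1.022837	1.515349	3.550	0.070
CE1	C	-3.147280	0.898884	1.015162	3.550	0.070
HE1	H	-3.438566	0.002094	0.488550	2.420	0.030
CE2	C	-1.481435	2.177038	2.193118	3.550	0.070
HE2	H	-0.478396	2.273347	2.581753	2.420	0.030
CD1	C	-4.063332	1.929132	1.192744	3.550	0.070
HD1	H	-5.066371	1.832823	0.804109	2.420	0.030
CD2	C	-2.397488	3.207287	2.370701	3.550	0.070
HD2	H	-2.106201	4.104077	2.897313	2.420	0.030
CG	C	-3.688436	3.083334	1.870513	3.550	0.070
CB	C	-4.683573	4.202525	2.063426	3.500	0.066
HB1	H	-5.540926	3.833366	2.626246	2.500	0.030
HB2	H	-4.211936	5.017390	2.612656	2.500	0.030
HB3	H	-5.016156	4.564662	1.090624	2.500	0.030
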