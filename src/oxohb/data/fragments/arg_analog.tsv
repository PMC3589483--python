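# fragment template (synthetic idealized geometry)
# kind: ARG_ANALOG
# resname: ARG
# net_charge: 1
# anchors: bidentate_center=CZ; donor_pairs=NH1:HH11,NH2:HH21; collinear_donor=NH1:HH11
# columns: name element x y z sigma epsilon
CZ	C	0.000000	0.000000	0.000000	2.250	0.050
NE	N	-1.330000	0.000000	0.000000	3.250	0.170
HE	H	-1.835000	0.874686	0.000000	0.500	0.010
NH1	N	0.665000	1.151814	0.000000	3.250	0.170
HH11	H	1.675000	1.151814	0.000000	0.500	0.010
HH12	H	0.160000	2.026499	0.000000	0.500	0.010
NH2	N	0.665000	-1.151814	0.000000	3.250	0.170
HH21	H	1.675000	-1.151814	0.000000	0.500	0.010
HH22	H	0.160000	-2.026499	0.000000	0.500	0.010
CD	C	-2.060000	-1.264397	0.000000	3.500	0.066
HD1	H	-1.796662	-1.835951	0.889988	2.500	0.030
HD2	H	-3.131644	-1.065199	0.000000	2.500	0.030
HD3	H	-1.796662	-1.835951	-0.889988	2.500	0.030
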