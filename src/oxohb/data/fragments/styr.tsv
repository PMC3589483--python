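# fragment template (synthetic idealized geometry)
# kind: STYR
# resname: TYS
# net_charge: -1
# anchors: center=S; collinear_oxygen=O1S; bidentate_oxygens=O1S,O2S
# columns: name element x y z sigma epsilon
S	S	0.000000	0.000000	0.000000	3.550	0.250
O1S	O	0.792450	1.220266	0.000000	2.960	0.210
O2S	O	0.792450	-1.220266	0.000000	2.960	0.210
O3S	O	-0.840057	0.000000	-1.187994	2.960	0.210
OH	O	-0.923774	-0.000000	1.306385	2.900	0.140
CZ	C	-1.833237	1.022837	1.482689	3.550	0.070
CE1	C	-3.124185	0.898884	0.982502	3.550	0.070
HE1	H	-3.415471	0.002094	0.455890	2.420	0.030
CE2	C	-1.458341	2.177038	2.160459	3.550	0.070
HE2	H	-0.455301	2.273347	2.549093	2.420	0.030
CD1	C	-4.040238	1.929132	1.160084	3.550	0.070
HD1	H	-5.043277	1.832823	0.771450	2.420	0.030
CD2	C	-2.374393	3.207287	2.338041	3.550	0.070
HD2	H	-2.083107	4.104077	2.864653	2.420	0.030
CG	C	-3.665342	3.083334	1.837854	3.550	0.070
CB	C	-4.660478	4.202525	2.030767	3.500	0.066
HB1	H	-5.517832	3.833366	2.593587	2.500	0.030
HB2	H	-4.188841	5.017390	2.579996	2.500	0.030
HB3	H	-4.993061	4.564662	1.057964	2.500	0.030
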