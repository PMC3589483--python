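# kind: PTYR_M1
# net_charge: -1
# provenance: esp-synthetic
P	1.3000
O1P	-0.8600
O2P	-0.8600
O3P	-0.6000
HOP	0.4400
OH	-0.5600
CZ	0.2600
CE1	-0.1400
HE1	0.1400
CE2	-0.1400
HE2	0.1400
CD1	-0.1200
HD1	0.1200
CD2	-0.1200
HD2	0.1200
CG	-0.1500
CB	-0.1500
HB1	0.0600
HB2	0.0600
HB3	0.0600
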