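# kind: PSER_M1
# net_charge: -1
# provenance: esp-synthetic
P	1.3200
O1P	-0.8800
O2P	-0.8800
O3P	-0.6200
HOP	0.4400
OG	-0.5600
CB	0.0300
HB1	0.0500
HB2	0.0500
HB3	0.0500
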