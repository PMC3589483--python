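# kind: PSER_M2
# net_charge: -2
# provenance: esp-synthetic
P	1.3000
O1P	-0.9500
O2P	-0.9500
O3P	-0.9500
OG	-0.6000
CB	0.0300
HB1	0.0400
HB2	0.0400
HB3	0.0400
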