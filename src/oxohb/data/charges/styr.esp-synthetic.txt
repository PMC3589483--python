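# kind: STYR
# net_charge: -1
# provenance: esp-synthetic
S	1.2500
O1S	-0.6600
O2S	-0.6600
O3S	-0.6600
OH	-0.5000
CZ	0.2600
CE1	-0.1400
HE1	0.1400
CE2	-0.1400
HE2	0.1400
CD1	-0.1200
HD1	0.1200
CD2	-0.1200
HD2	0.1200
CG	-0.0600
CB	-0.1500
HB1	0.0600
HB2	0.0600
HB3	0.0600
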